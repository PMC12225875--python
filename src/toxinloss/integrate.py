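"""Evidence fusion per gene x specimen and the geography association test.

The three evidence layers (venom peptides, venom-gland transcripts,
genomic locus) are combined into one final status with a mechanism note;
loss phenotypes are then tested for association with geographic cohort
(west/east) in a 2x2 table using the continuity-corrected (Yates)
chi-squared statistic with one degree of freedom:

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

The continuity correction is the default; the uncorrected statistic is
available behind a flag.  p-values are reported, never used for automated
decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .locus_evidence import LocusCall, LocusState
from .models import InputError
from .peptide_evidence import ExpressionState
from .transcript_evidence import FinalTranscriptCall


class FinalStatus(str, Enum):
    EXPRESSED = "EXPRESSED"
    LOST_DELETED = "LOST_DELETED"
    LOST_FUSION = "LOST_FUSION"
    LOST_DISRUPTED = "LOST_DISRUPTED"
    SILENCED_UNEXPLAINED = "SILENCED_UNEXPLAINED"
    CONFLICT = "CONFLICT"


#: statuses counted as "low/undetected" in the association table
LOSS_STATUSES = {
    FinalStatus.LOST_DELETED,
    FinalStatus.LOST_FUSION,
    FinalStatus.LOST_DISRUPTED,
    FinalStatus.SILENCED_UNEXPLAINED,
}


@dataclass
class GeneStatus:
    gene_id: str
    specimen_id: str
    expression: Optional[ExpressionState]
    transcript: Optional[FinalTranscriptCall]
    locus: Optional[LocusState]
    final: FinalStatus
    mechanism_note: str


@dataclass
class ContingencyTable:
    """Rows: region (west, east); columns: status (low/undetected, detected)."""

    a: int  # west, low/undetected
    b: int  # west, detected
    c: int  # east, low/undetected
    d: int  # east, detected

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> dict[str, int]:
        return {
            "west": self.a + self.b,
            "east": self.c + self.d,
            "low": self.a + self.c,
            "detected": self.b + self.d,
        }


@dataclass
class ContingencyResult:
    table: ContingencyTable
    chi2: float
    df: int
    p: float
    corrected: bool


def call_gene_status(
    expression: Optional[ExpressionState],
    transcript: Optional[FinalTranscriptCall],
    locus: Optional[LocusState | LocusCall],
    gene_id: str = "",
    specimen_id: str = "",
) -> GeneStatus:
    """Fuse the three per-gene evidence layers into a final status.

    Missing layers are tolerated and recorded in the mechanism note.  A
    heterozygous-deletion carrier with expressed protein is EXPRESSED (the
    carrier note is kept); homozygous deletion with expressed protein is a
    CONFLICT, never EXPRESSED.
    """
    locus_call = locus if isinstance(locus, LocusCall) or locus is None else None
    locus_state = locus.state if isinstance(locus, LocusCall) else locus
    notes = []
    expressed_protein = expression == ExpressionState.EXPRESSED
    absent_protein = expression in (ExpressionState.NOT_DETECTED, ExpressionState.PARTIAL_LOW)
    full_tx = transcript == FinalTranscriptCall.FULL_LENGTH
    for layer, val in (("protein", expression), ("transcript", transcript), ("locus", locus_state)):
        notes.append(f"{layer}={'absent' if val is None else getattr(val, 'value', val)}")

    if expressed_protein and full_tx and locus_state != LocusState.HOM_DELETION:
        if locus_state == LocusState.HET_DELETION:
            notes.append("het deletion carrier")
        if locus_call is not None and (locus_call.disruptions or locus_call.fusions):
            notes.append("mutant allele carrier")
        final = FinalStatus.EXPRESSED
    elif locus_state == LocusState.HOM_DELETION:
        final = FinalStatus.CONFLICT if expressed_protein else FinalStatus.LOST_DELETED
    elif locus_state == LocusState.HET_DELETION and not expressed_protein:
        final = FinalStatus.LOST_DELETED
        notes.append("het deletion with absent expression")
    elif locus_state == LocusState.FUSION:
        final = FinalStatus.LOST_FUSION
    elif locus_state == LocusState.FRAMESHIFT and not expressed_protein:
        final = FinalStatus.LOST_DISRUPTED
    elif absent_protein and transcript == FinalTranscriptCall.NO_FULL_LENGTH and locus_state in (
        LocusState.INTACT,
        LocusState.NO_DATA,
        None,
    ):
        final = FinalStatus.SILENCED_UNEXPLAINED
    else:
        final = FinalStatus.CONFLICT
    return GeneStatus(
        gene_id=gene_id,
        specimen_id=specimen_id,
        expression=expression,
        transcript=transcript,
        locus=locus_state,
        final=final,
        mechanism_note="; ".join(notes),
    )


def yates_chi_squared(
    table: ContingencyTable, corrected: bool = True
) -> ContingencyResult:
    """2x2 chi-squared with (by default) the Yates continuity correction."""
    a, b, c, d = table.a, table.b, table.c, table.d
    for name, margin in table.margins().items():
        if margin == 0:
            raise InputError(f"chi-squared undefined: zero margin '{name}'")
    n = table.n
    diff = abs(a * d - b * c)
    if corrected:
        diff = max(diff - n / 2.0, 0.0)
    m = table.margins()
    chi2 = n * diff**2 / (m["west"] * m["east"] * m["low"] * m["detected"])
    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        df=1,
        p=float(_chi2_dist.sf(chi2, 1)),
        corrected=corrected,
    )


def load_survey_labels() -> pd.DataFrame:
    """Packaged 27-specimen venom survey (region + MPO1 blot phenotype)."""
    with resources.files("toxinloss.data").joinpath("atrox_survey.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def table_from_labels(
    labels: pd.DataFrame,
    loss_values: tuple[str, ...] = ("undetected", "weak"),
    label_col: str = "mpo1_blot",
) -> ContingencyTable:
    """Build the region x status table from categorical blot labels."""
    west = labels[labels["region"] == "west"]
    east = labels[labels["region"] == "east"]
    a = int(west[label_col].isin(loss_values).sum())
    c = int(east[label_col].isin(loss_values).sum())
    return ContingencyTable(a=a, b=len(west) - a, c=c, d=len(east) - c)


def associate_geography(
    statuses: pd.DataFrame,
    specimens: Mapping[str, str] | pd.DataFrame,
    target_gene: str,
    corrected: bool = True,
) -> ContingencyResult:
    """Test association between region and target-gene loss phenotype.

    ``statuses`` is the integrated per gene x specimen table (columns
    gene_id, specimen_id, final); ``specimens`` maps specimen_id to region.
    """
    if isinstance(specimens, pd.DataFrame):
        specimens = dict(zip(specimens["specimen_id"], specimens["region"]))
    sub = statuses[statuses["gene_id"] == target_gene]
    counts = {("west", True): 0, ("west", False): 0, ("east", True): 0, ("east", False): 0}
    for _, row in sub.iterrows():
        sid = row["specimen_id"]
        if sid not in specimens:
            raise InputError(f"specimen {sid} has no region label")
        low = FinalStatus(row["final"]) in LOSS_STATUSES
        counts[(specimens[sid], low)] += 1
    for region in ("west", "east"):
        if counts[(region, True)] + counts[(region, False)] < 2:
            raise InputError(f"fewer than 2 specimens in region '{region}'")
    table = ContingencyTable(
        a=counts[("west", True)],
        b=counts[("west", False)],
        c=counts[("east", True)],
        d=counts[("east", False)],
    )
    return yates_chi_squared(table, corrected=corrected)


def expression_summary(
    counts: pd.DataFrame, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Descriptive per gene x specimen TPM and log2(TPM+1).

    ``counts`` has genes as the index and specimens as columns; counts are
    normalized by transcript length and scaled so each specimen sums to 1e6.
    """
    import warnings

    lens = pd.Series({g: lengths[g] for g in counts.index}, dtype=float)
    if (counts.to_numpy() < 0).any():
        raise InputError("negative counts")
    rate = counts.div(lens, axis=0)
    totals = rate.sum(axis=0)
    tpm = rate * 0.0
    for col in rate.columns:
        if totals[col] == 0:
            warnings.warn(f"specimen {col}: zero total counts; TPM set to 0")
        else:
            tpm[col] = rate[col] / totals[col] * 1e6
    out = tpm.reset_index().melt(id_vars=tpm.index.name or "index",
                                 var_name="specimen_id", value_name="tpm")
    out = out.rename(columns={tpm.index.name or "index": "gene_id"})
    out["log2_tpm1"] = np.log2(out["tpm"] + 1.0)
    return out
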