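"""Proteomic expression state from exclusive-unique peptides.

Within a highly similar gene family, a detected peptide supports a specific
protein only if its sequence occurs in exactly one family member (an
exclusive-unique peptide, EUP).  Expression state per gene x specimen is
classified from (i) the fraction of the metalloproteinase domain covered by
detected EUPs, counted over positions that are assignable at all (covered
by some theoretical EUP of that gene), and (ii) the mean detected EUP
count.  Matching is exact substring matching on identified peptide strings;
missed cleavages, I/L equivalence and modifications are search-engine
territory and deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .models import GeneModel, InputError

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class ExpressionState(str, Enum):
    EXPRESSED = "EXPRESSED"
    PARTIAL_LOW = "PARTIAL_LOW"
    NOT_DETECTED = "NOT_DETECTED"
    INTERMEDIATE = "INTERMEDIATE"


@dataclass
class ProteinStateThresholds:
    """Classification bands.

    The low/high coverage cut-offs bracket the empirically observed bimodal
    regimes (partial coverage well below half the domain vs. near-complete
    coverage above 90%); the regime in between is reported INTERMEDIATE,
    never silently coerced.  Count thresholds are mean detected-EUP counts.
    """

    low_coverage_max: float = 0.50
    high_coverage_min: float = 0.90
    low_count_max: float = 2.0
    high_count_min: float = 5.0

    def __post_init__(self):
        if not self.low_coverage_max < self.high_coverage_min:
            raise InputError("low_coverage_max must be below high_coverage_min")


@dataclass
class PeptideAssignment:
    peptide_seq: str
    matching_gene_ids: set[str]
    positions: dict[str, list[tuple[int, int]]]  # per-gene aa occurrence intervals

    @property
    def exclusive_unique(self) -> bool:
        return len(self.matching_gene_ids) == 1


@dataclass
class DomainCoverageResult:
    gene_id: str
    specimen_id: str
    assignable_positions: set[int]
    covered_positions: set[int]
    n_eups: int
    mean_eup_count: float
    unassessable: bool = False

    @property
    def coverage_fraction(self) -> float:
        if not self.assignable_positions:
            return 0.0
        return len(self.covered_positions) / len(self.assignable_positions)


def tryptic_digest(protein_seq: str, min_length: int = 6, keep_short: bool = False) -> list[str]:
    """In-silico trypsin digest: cleave C-terminal to K/R unless followed by P.

    Peptides shorter than ``min_length`` are dropped unless ``keep_short``;
    with ``keep_short`` the peptides concatenate exactly to the input.
    """
    if not protein_seq:
        raise InputError("empty protein sequence")
    bad = set(protein_seq) - _AMINO_ACIDS
    if bad:
        raise InputError(f"non-amino-acid characters in protein: {sorted(bad)}")
    peptides = []
    start = 0
    for i, aa in enumerate(protein_seq):
        if aa in "KR" and (i + 1 == len(protein_seq) or protein_seq[i + 1] != "P"):
            peptides.append(protein_seq[start : i + 1])
            start = i + 1
    if start < len(protein_seq):
        peptides.append(protein_seq[start:])
    if keep_short:
        return peptides
    return [p for p in peptides if len(p) >= min_length]


def _occurrences(needle: str, haystack: str) -> list[tuple[int, int]]:
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append((i, i + len(needle)))
        i = haystack.find(needle, i + 1)
    return out


def classify_peptides(
    peptides: Iterable[str], proteome: Mapping[str, str]
) -> list[PeptideAssignment]:
    """Assign each peptide to every protein containing it as a substring."""
    if not proteome:
        raise InputError("empty proteome")
    out = []
    for pep in peptides:
        positions = {}
        for gid, prot in proteome.items():
            occ = _occurrences(pep, prot)
            if occ:
                positions[gid] = occ
        out.append(PeptideAssignment(pep, set(positions), positions))
    return out


def theoretical_eups(
    gene: GeneModel | str, proteome: Mapping[str, str], min_length: int = 6
) -> list[PeptideAssignment]:
    """The gene's tryptic peptides that are exclusive-unique in the proteome."""
    gene_id = gene if isinstance(gene, str) else gene.gene_id
    digest = tryptic_digest(proteome[gene_id], min_length=min_length)
    return [
        a
        for a in classify_peptides(sorted(set(digest)), proteome)
        if a.exclusive_unique and next(iter(a.matching_gene_ids)) == gene_id
    ]


def domain_coverage(
    gene: GeneModel,
    proteome: Mapping[str, str],
    detected_counts: Mapping[str, float],
    specimen_id: str = "",
    domain: str = "metalloproteinase",
    min_length: int = 6,
) -> DomainCoverageResult:
    """Domain coverage by detected EUPs over assignable domain positions.

    Assignable positions are those overlapped by at least one theoretical
    EUP of the gene; positions conserved between paralogs generate only
    shared peptides and are therefore excluded from the denominator.
    """
    dom_lo, dom_hi = gene.domain_protein_interval(domain)
    domain_positions = set(range(dom_lo, dom_hi))
    eups = theoretical_eups(gene, proteome, min_length=min_length)
    assignable: set[int] = set()
    for a in eups:
        for s, e in a.positions[gene.gene_id]:
            assignable |= domain_positions & set(range(s, e))
    eup_seqs = {a.peptide_seq: a for a in eups}
    covered: set[int] = set()
    detected = []
    for pep, count in detected_counts.items():
        if count > 0 and pep in eup_seqs:
            detected.append(count)
            for s, e in eup_seqs[pep].positions[gene.gene_id]:
                covered |= assignable & set(range(s, e))
    return DomainCoverageResult(
        gene_id=gene.gene_id,
        specimen_id=specimen_id,
        assignable_positions=assignable,
        covered_positions=covered,
        n_eups=len(detected),
        mean_eup_count=float(sum(detected) / len(detected)) if detected else 0.0,
        unassessable=not assignable,
    )


def protein_expression_state(
    result: DomainCoverageResult, thresholds: ProteinStateThresholds | None = None
) -> ExpressionState:
    t = thresholds or ProteinStateThresholds()
    if result.n_eups == 0:
        return ExpressionState.NOT_DETECTED
    cov = result.coverage_fraction
    if cov < t.low_coverage_max and result.mean_eup_count < t.low_count_max:
        return ExpressionState.PARTIAL_LOW
    if cov > t.high_coverage_min and result.mean_eup_count >= t.high_count_min:
        return ExpressionState.EXPRESSED
    return ExpressionState.INTERMEDIATE


def evaluate_peptides(
    family, specimens, thresholds: ProteinStateThresholds | None = None,
    min_length: int = 6,
):
    """Coverage/state table over all genes x specimens.

    Returns a pandas DataFrame with one row per gene x specimen carrying
    coverage_fraction, n_eups, mean_eup_count and the classified state.
    """
    import pandas as pd

    proteome = family.proteome
    rows = []
    for sid, ev in specimens.items():
        if ev.peptides is None:
            continue
        counts = dict(zip(ev.peptides["peptide_seq"], ev.peptides["count"]))
        for gene in family.genes:
            res = domain_coverage(gene, proteome, counts, specimen_id=sid,
                                  min_length=min_length)
            state = protein_expression_state(res, thresholds)
            rows.append(
                dict(
                    gene_id=gene.gene_id,
                    specimen_id=sid,
                    coverage_fraction=res.coverage_fraction,
                    n_eups=res.n_eups,
                    mean_eup_count=res.mean_eup_count,
                    unassessable=res.unassessable,
                    state=state.value,
                )
            )
    return pd.DataFrame(rows)
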