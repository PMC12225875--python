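"""Genomic state per gene x specimen from capture coverage and contigs.

Copy state comes from mean capture depth over the target gene relative to
the control gene (a paralog never observed to vary); mechanism comes from
annotating assembled contigs against the family's exon library: each contig
segment matching a reference exon is called to its best-scoring gene with
an amino-acid identity and a frame status, and runs of non-target exon
calls flag chimeric fusion genes while frame damage flags disruptions.

Exon location uses edlib infix alignment at the nucleotide level; identity
is then scored on the translated segment with an affine-gap protein
alignment (BLOSUM62).  Exons whose top two gene assignments are within a
small identity margin — exact inter-paralog copies in hard regions — are
reported ambiguous and are neutral for fusion detection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .models import FamilyReference, GeneModel, InputError, Interval


class LocusState(str, Enum):
    INTACT = "INTACT"
    HET_DELETION = "HET_DELETION"
    HOM_DELETION = "HOM_DELETION"
    FUSION = "FUSION"
    FRAMESHIFT = "FRAMESHIFT"
    DIVERGENT_ALLELE = "DIVERGENT_ALLELE"
    AMBIGUOUS_RATIO = "AMBIGUOUS_RATIO"
    NO_DATA = "NO_DATA"


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    PREMATURE_STOP = "premature_stop"


@dataclass
class CopyStateThresholds:
    """Operational copy-ratio bands; values in the gaps are AMBIGUOUS_RATIO."""

    hom_max: float = 0.05
    het_band: tuple[float, float] = (0.30, 0.70)
    intact_min: float = 0.80


@dataclass
class LocusCoverageSummary:
    gene_id: str
    specimen_id: str
    mean_depth_target: float
    mean_depth_control: float

    @property
    def ratio(self) -> Optional[float]:
        if self.mean_depth_control <= 0:
            return None
        return self.mean_depth_target / self.mean_depth_control


@dataclass
class ExonCall:
    contig_id: str
    contig_interval: Interval
    best_gene_id: Optional[str]  # None when ambiguous between paralogs
    candidate_gene_ids: frozenset[str]
    exon_index: int
    aa_identity: float
    frame_status: FrameStatus

    @property
    def ambiguous(self) -> bool:
        return self.best_gene_id is None


@dataclass
class FusionReport:
    contig_id: str
    target_gene_id: str
    donor_gene_id: str
    donor_exons: list[int]
    target_exons: list[int]
    breakpoint: str


@dataclass
class DisruptionReport:
    contig_id: str
    target_gene_id: str
    kind: FrameStatus  # FRAMESHIFT or PREMATURE_STOP
    exon_index: int


@dataclass
class DivergentReport:
    contig_id: str
    target_gene_id: str
    exon_identities: dict[int, float]


@dataclass
class LocusCall:
    gene_id: str
    specimen_id: str
    state: LocusState
    summary: Optional[LocusCoverageSummary]
    exon_calls: list[ExonCall] = field(default_factory=list)
    fusions: list[FusionReport] = field(default_factory=list)
    disruptions: list[DisruptionReport] = field(default_factory=list)
    divergent: list[DivergentReport] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coverage


def summarize_locus_coverage(
    locus_depth: np.ndarray,
    gene: GeneModel,
    control_gene: GeneModel,
    specimen_id: str = "",
) -> LocusCoverageSummary:
    """Mean depth over the target and control gene intervals."""
    ts, te = gene.locus_interval
    cs, ce = control_gene.locus_interval
    return LocusCoverageSummary(
        gene_id=gene.gene_id,
        specimen_id=specimen_id,
        mean_depth_target=float(np.mean(locus_depth[ts:te])),
        mean_depth_control=float(np.mean(locus_depth[cs:ce])),
    )


def call_copy_state(
    summary: LocusCoverageSummary, thresholds: CopyStateThresholds | None = None
) -> LocusState:
    t = thresholds or CopyStateThresholds()
    ratio = summary.ratio
    if ratio is None:
        return LocusState.NO_DATA  # capture failure, not deletion
    if ratio <= t.hom_max:
        return LocusState.HOM_DELETION
    if t.het_band[0] <= ratio <= t.het_band[1]:
        return LocusState.HET_DELETION
    if ratio >= t.intact_min:
        return LocusState.INTACT
    return LocusState.AMBIGUOUS_RATIO


# ---------------------------------------------------------------------------
# contig exon annotation


@dataclass(frozen=True)
class ExonLibraryEntry:
    gene_id: str
    exon_index: int
    nt_seq: str
    aa_seq: str


def build_exon_library(family: FamilyReference) -> list[ExonLibraryEntry]:
    entries = []
    for g in family.genes:
        for e in g.exons:
            ts, te = g.exon_transcript_interval(e.index)
            nt = g.transcript_seq[ts:te]
            entries.append(ExonLibraryEntry(g.gene_id, e.index, nt, g.protein_seq[ts // 3 : te // 3]))
    return entries


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


_ALIGNER = _protein_aligner()


def _aa_identity(ref_aa: str, seg_aa: str) -> float:
    """Identical aligned residues over the reference exon length."""
    if not seg_aa:
        return 0.0
    aln = _ALIGNER.align(ref_aa, seg_aa)[0]
    ident = 0
    for (rs, re), (qs, qe) in zip(*aln.aligned):
        ident += sum(a == b for a, b in zip(ref_aa[rs:re], seg_aa[qs:qe]))
    return ident / len(ref_aa)


def _translate_segment(nt: str) -> str:
    from .family_forge import translate

    return translate(nt[: len(nt) - len(nt) % 3])


@dataclass
class _Candidate:
    entry: ExonLibraryEntry
    interval: Interval
    aa_identity: float
    frame_status: FrameStatus
    nt_divergence: float

    @property
    def score(self) -> float:
        # a frame-damaged exon is attributed by its nucleotide match: the
        # translation downstream of an indel is garbage by construction
        if self.frame_status is FrameStatus.IN_FRAME:
            return self.aa_identity
        return max(self.aa_identity, 1.0 - self.nt_divergence)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _frame_status(cigar: str, seg: str, edge: int = 3) -> tuple[FrameStatus, str]:
    """Frame status of a matched segment from its alignment path.

    Indel runs confined to the outermost ``edge`` alignment columns are
    boundary artifacts (a substituted terminal base can be absorbed as a
    gap by the optimal alignment) and do not count as frame damage; a
    leading artifact instead shifts the translation frame.
    """
    runs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    aln_len = sum(n for n, _ in runs)
    cols = 0
    lead_shift = 0
    internal_net = 0
    for n, op in runs:
        if op in "ID":
            delta = n if op == "D" else -n  # D: extra segment bases
            if cols + n <= edge:
                lead_shift += delta
            elif cols >= aln_len - edge:
                pass  # trailing boundary artifact
            else:
                internal_net += delta
        cols += n
    seg_aa = _translate_segment(seg[lead_shift % 3 :])
    if internal_net % 3 != 0:
        frame = FrameStatus.PREMATURE_STOP if "*" in seg_aa else FrameStatus.FRAMESHIFT
    elif "*" in seg_aa:
        frame = FrameStatus.PREMATURE_STOP
    else:
        frame = FrameStatus.IN_FRAME
    return frame, seg_aa


def _find_candidates(
    contig: str, entry: ExonLibraryEntry, max_nt_divergence: float
) -> list[_Candidate]:
    res = edlib.align(entry.nt_seq, contig, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_nt_divergence * len(entry.nt_seq):
        return []
    nt_div = res["editDistance"] / len(entry.nt_seq)
    out = []
    seen: set[Interval] = set()
    for s, e in res["locations"][:4]:
        iv = (int(s), int(e) + 1)
        if any(_jaccard(iv, prev) > 0.8 for prev in seen):
            continue
        seen.add(iv)
        seg = contig[iv[0] : iv[1]]
        path = edlib.align(entry.nt_seq, seg, mode="NW", task="path")
        frame, seg_aa = _frame_status(path["cigar"] or "", seg)
        ident = _aa_identity(entry.aa_seq, seg_aa.replace("*", "X"))
        out.append(_Candidate(entry, iv, ident, frame, nt_div))
    return out


def _jaccard(a: Interval, b: Interval) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def annotate_contig_exons(
    contig_seq: str,
    library: Sequence[ExonLibraryEntry],
    contig_id: str = "contig",
    min_identity: float = 0.60,
    tie_margin: float = 0.02,
    max_nt_divergence: float = 0.35,
) -> list[ExonCall]:
    """Call reference exons on a contig, best-scoring gene first.

    Overlapping candidates are resolved by highest amino-acid identity, then
    longest alignment; a winner whose runner-up from a different gene scores
    within ``tie_margin`` is reported ambiguous (``best_gene_id=None``).
    """
    if not library:
        raise InputError("empty exon library")
    shortest = min(len(e.nt_seq) for e in library)
    if len(contig_seq) < shortest:
        return []
    candidates: list[_Candidate] = []
    for entry in library:
        candidates.extend(_find_candidates(contig_seq, entry, max_nt_divergence))
    candidates = [c for c in candidates if c.score >= min_identity]
    candidates.sort(key=lambda c: (-c.score,
                                   -(c.interval[1] - c.interval[0]),
                                   c.entry.gene_id, c.entry.exon_index))
    accepted: list[_Candidate] = []
    shadowed: dict[int, list[_Candidate]] = {}
    for c in candidates:
        placed = False
        for i, a in enumerate(accepted):
            if _jaccard(c.interval, a.interval) > 0.5:
                shadowed.setdefault(i, []).append(c)
                placed = True
                break
        if not placed:
            accepted.append(c)
    calls = []
    for i, a in enumerate(accepted):
        rivals = [
            c for c in shadowed.get(i, [])
            if c.entry.gene_id != a.entry.gene_id
            and c.score >= a.score - tie_margin
        ]
        genes = frozenset([a.entry.gene_id] + [c.entry.gene_id for c in rivals])
        calls.append(
            ExonCall(
                contig_id=contig_id,
                contig_interval=a.interval,
                best_gene_id=None if rivals else a.entry.gene_id,
                candidate_gene_ids=genes,
                exon_index=a.entry.exon_index,
                aa_identity=a.aa_identity,
                frame_status=a.frame_status,
            )
        )
    calls.sort(key=lambda c: c.contig_interval)
    return calls


# ---------------------------------------------------------------------------
# mechanism detectors


def detect_fusion(
    exon_calls: Sequence[ExonCall],
    target_gene_id: str,
    min_run: int = 2,
    min_identity: float = 0.90,
) -> Optional[FusionReport]:
    """Chimeric-gene signature on one contig's exon-call chain.

    Requires a maximal run of >= ``min_run`` unambiguous calls to one
    non-target gene, with all member identities >= ``min_identity``,
    adjacent (ambiguous calls are skipped) to a target-gene call or to the
    contig boundary, and at least one target-gene call on the contig.
    """
    calls = [c for c in exon_calls if not c.ambiguous]
    if not any(c.best_gene_id == target_gene_id for c in calls):
        return None
    i = 0
    while i < len(calls):
        gid = calls[i].best_gene_id
        j = i
        while j < len(calls) and calls[j].best_gene_id == gid:
            j += 1
        run = calls[i:j]
        if (
            gid != target_gene_id
            and len(run) >= min_run
            and all(c.aa_identity >= min_identity for c in run)
        ):
            left_ok = i == 0 or calls[i - 1].best_gene_id == target_gene_id
            right_ok = j == len(calls) or calls[j].best_gene_id == target_gene_id
            if left_ok and right_ok:
                donor_exons = [c.exon_index for c in run]
                target_exons = [
                    c.exon_index for c in calls if c.best_gene_id == target_gene_id
                ]
                if j < len(calls):
                    bp = f"between donor exon {run[-1].exon_index} and target exon {calls[j].exon_index}"
                else:
                    bp = f"between target exon {calls[i - 1].exon_index} and donor exon {run[0].exon_index}"
                return FusionReport(
                    contig_id=run[0].contig_id,
                    target_gene_id=target_gene_id,
                    donor_gene_id=gid,
                    donor_exons=donor_exons,
                    target_exons=target_exons,
                    breakpoint=bp,
                )
        i = j
    return None


def detect_disruption(
    exon_calls: Sequence[ExonCall],
    target_gene: GeneModel,
    divergent_band: tuple[float, float] = (0.60, 0.98),
) -> Optional[DisruptionReport | DivergentReport]:
    """Frame damage (or a divergent allele) along the target's exon chain.

    Reports the first frameshift/premature stop among metalloproteinase-
    domain exons before the domain's final exon; failing that, multiple
    substitution-divergent but frame-intact exons are reported as a
    divergent allele.
    """
    domain_exons = target_gene.domain_exon_indices("metalloproteinase")
    calls = [
        c
        for c in exon_calls
        if target_gene.gene_id in c.candidate_gene_ids
    ]
    damaged = [
        c
        for c in calls
        if c.exon_index in domain_exons[:-1] or (
            c.exon_index in domain_exons and c.frame_status == FrameStatus.FRAMESHIFT
        )
    ]
    for c in sorted(damaged, key=lambda c: c.exon_index):
        if c.frame_status != FrameStatus.IN_FRAME:
            return DisruptionReport(
                contig_id=c.contig_id,
                target_gene_id=target_gene.gene_id,
                kind=c.frame_status,
                exon_index=c.exon_index,
            )
    lo, hi = divergent_band
    divergent = {
        c.exon_index: c.aa_identity
        for c in calls
        if lo <= c.aa_identity < hi and c.frame_status == FrameStatus.IN_FRAME
    }
    if len(divergent) >= 2:
        return DivergentReport(
            contig_id=calls[0].contig_id,
            target_gene_id=target_gene.gene_id,
            exon_identities=divergent,
        )
    return None


def _has_intact_chain(
    exon_calls: Sequence[ExonCall], gene: GeneModel, min_identity: float = 0.98
) -> bool:
    found = {
        c.exon_index
        for c in exon_calls
        if gene.gene_id in c.candidate_gene_ids
        and c.frame_status == FrameStatus.IN_FRAME
        and c.aa_identity >= min_identity
    }
    return found >= {e.index for e in gene.exons}


# ---------------------------------------------------------------------------
# per-gene integration


def evaluate_loci(
    family: FamilyReference,
    specimens,
    thresholds: CopyStateThresholds | None = None,
    min_identity: float = 0.60,
) -> dict[tuple[str, str], LocusCall]:
    """LocusCall per gene x specimen from capture depth and contigs.

    Mechanism states (FUSION/FRAMESHIFT/DIVERGENT_ALLELE) are assigned only
    when no contig carries a complete in-frame exon chain for the gene;
    heterozygous carriers therefore keep their copy-ratio state, with the
    mutant-contig reports retained as supporting evidence.
    """
    thresholds = thresholds or CopyStateThresholds()
    library = build_exon_library(family)
    control = family.gene(family.control_gene_id) if family.control_gene_id else None
    out: dict[tuple[str, str], LocusCall] = {}
    for sid, ev in specimens.items():
        contig_calls: dict[str, list[ExonCall]] = {}
        for cid, seq in (ev.contigs or {}).items():
            contig_calls[cid] = annotate_contig_exons(
                seq, library, contig_id=cid, min_identity=min_identity
            )
        for gene in family.genes:
            summary = None
            if ev.locus_depth is not None and control is not None:
                summary = summarize_locus_coverage(ev.locus_depth, gene, control, sid)
            gene_contigs = {
                cid: calls
                for cid, calls in contig_calls.items()
                if any(gene.gene_id in c.candidate_gene_ids for c in calls)
            }
            fusions, disruptions, divergent = [], [], []
            intact_chain = False
            all_calls: list[ExonCall] = []
            for cid, calls in sorted(gene_contigs.items()):
                all_calls.extend(calls)
                if _has_intact_chain(calls, gene):
                    intact_chain = True
                fr = detect_fusion(calls, gene.gene_id)
                if fr:
                    fusions.append(fr)
                dr = detect_disruption(calls, gene)
                if isinstance(dr, DisruptionReport):
                    disruptions.append(dr)
                elif isinstance(dr, DivergentReport):
                    divergent.append(dr)
            if not intact_chain and fusions:
                state = LocusState.FUSION
            elif not intact_chain and disruptions:
                state = LocusState.FRAMESHIFT
            elif not intact_chain and divergent and gene_contigs:
                state = LocusState.DIVERGENT_ALLELE
            elif summary is not None:
                state = call_copy_state(summary, thresholds)
            else:
                state = LocusState.NO_DATA
            out[(gene.gene_id, sid)] = LocusCall(
                gene_id=gene.gene_id,
                specimen_id=sid,
                state=state,
                summary=summary,
                exon_calls=all_calls,
                fusions=fusions,
                disruptions=disruptions,
                divergent=divergent,
            )
    return out
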