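"""Full-length transcript support from coverage gaps, exon tiling and isoforms.

Three votes are combined per gene x specimen:

* short-read vote — maximal zero-coverage runs on the reference transcript,
  screened against a mappability mask built from high-expressing specimens
  (a region where even high expressors show at most marginal unambiguous
  depth cannot support an absence call on its own);
* tiling vote — assembled partial transcripts must overlap every coding
  exon and span every adjacent exon junction;
* isoform vote — clustered long reads (5'/3'/gap criteria of 100/30/10 bp)
  must contain a consensus overlapping every coding exon.

The final call is FULL_LENGTH iff an isoform is present, or the tiling is
complete and the short reads do not positively contradict it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import BlockAlignment, GeneModel, InputError, Interval


class ShortReadVote(str, Enum):
    SUPPORTS_FULL = "SUPPORTS_FULL"
    NO_FULL_LENGTH = "NO_FULL_LENGTH"
    INCONCLUSIVE = "INCONCLUSIVE"


class FinalTranscriptCall(str, Enum):
    FULL_LENGTH = "FULL_LENGTH"
    NO_FULL_LENGTH = "NO_FULL_LENGTH"


@dataclass(frozen=True)
class ZeroRegion:
    interval: Interval  # transcript coordinates
    masked: bool = False


@dataclass(frozen=True)
class ClusteringCriteria:
    """Long-read pair-merge thresholds (strict less-than, in bp)."""

    max_5prime_overhang: int = 100
    max_3prime_overhang: int = 30
    max_gap: int = 10

    def __post_init__(self):
        if min(self.max_5prime_overhang, self.max_3prime_overhang, self.max_gap) <= 0:
            raise InputError("clustering thresholds must be positive")


@dataclass
class TranscriptStatus:
    gene_id: str
    specimen_id: str
    short_read_vote: ShortReadVote
    tiling_vote: bool
    isoform_vote: Optional[bool]
    final: FinalTranscriptCall


def detect_zero_regions(depth: np.ndarray, min_length: int = 10) -> list[ZeroRegion]:
    """Maximal zero-depth runs of at least ``min_length``, sorted by position."""
    depth = np.asarray(depth)
    if depth.ndim != 1:
        raise InputError("coverage track must be one-dimensional")
    is_zero = np.concatenate([[False], depth == 0, [False]])
    edges = np.flatnonzero(np.diff(is_zero.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        ZeroRegion((int(s), int(e)))
        for s, e in zip(starts, ends)
        if e - s >= min_length
    ]


def high_expressors(tracks: dict[str, np.ndarray], min_count: int = 1) -> list[str]:
    """Specimens in the top half of total mapped counts for this transcript."""
    totals = {sid: float(np.sum(t)) for sid, t in tracks.items()}
    order = sorted(totals, key=lambda s: (-totals[s], s))
    n = max(len(order) // 2, min_count)
    return [s for s in order[:n] if totals[s] > 0] or order[:1]


def build_mappability_mask(
    high_expressor_tracks: dict[str, np.ndarray],
    low_depth_threshold: float = 1.0,
) -> np.ndarray:
    """Positions of limited utility for absence calls.

    A position is masked iff in *every* high-expressing specimen its depth
    is at most ``low_depth_threshold`` times that specimen's median
    transcript depth — i.e. even specimens with abundant transcript show at
    best marginal unambiguous coverage there (a hard-to-sequence region or
    a segment nearly identical between paralogs).
    """
    if not high_expressor_tracks:
        raise InputError("mask undefined: no high-expressing specimens available")
    tracks = list(high_expressor_tracks.values())
    length = len(tracks[0])
    mask = np.ones(length, dtype=bool)
    for t in tracks:
        if len(t) != length:
            raise InputError("coverage tracks differ in length")
        mask &= t <= low_depth_threshold * np.median(t)
    return mask


def short_read_vote(
    zero_regions: Sequence[ZeroRegion], mask: Optional[np.ndarray]
) -> ShortReadVote:
    """NO_FULL_LENGTH iff some zero region lies wholly outside the mask."""
    if not zero_regions:
        return ShortReadVote.SUPPORTS_FULL
    if mask is None:
        return ShortReadVote.INCONCLUSIVE
    for zr in zero_regions:
        s, e = zr.interval
        if not mask[s:e].any():  # entirely unmasked: real evidence of absence
            return ShortReadVote.NO_FULL_LENGTH
    # every zero region touches masked territory; call only the fully masked
    # ones inconclusive, partially masked ones still count as evidence
    for zr in zero_regions:
        s, e = zr.interval
        if not mask[s:e].all():
            return ShortReadVote.NO_FULL_LENGTH
    return ShortReadVote.INCONCLUSIVE


def annotate_zero_regions(
    zero_regions: Sequence[ZeroRegion], mask: np.ndarray
) -> list[ZeroRegion]:
    return [
        ZeroRegion(z.interval, masked=bool(mask[z.interval[0] : z.interval[1]].all()))
        for z in zero_regions
    ]


def exon_linkage_complete(
    fragments: Iterable[BlockAlignment], gene: GeneModel
) -> bool:
    """True iff fragments overlap every coding exon and span every junction.

    A junction between exons i and i+1 is spanned when one fragment either
    has consecutive blocks overlapping exon i then exon i+1, or a single
    block overlapping both.
    """
    if not gene.exons:
        raise InputError(f"{gene.gene_id} has no coding exons")
    frags = list(fragments)
    for e in gene.exons:
        if not any(f.overlaps(e.interval) for f in frags):
            return False
    for i in range(1, gene.n_exons):
        left, right = gene.exon(i).interval, gene.exon(i + 1).interval
        linked = False
        for f in frags:
            for j, block in enumerate(f.blocks):
                touches_left = _overlap(block, left)
                if touches_left and _overlap(block, right):
                    linked = True
                    break
                if (
                    touches_left
                    and j + 1 < len(f.blocks)
                    and _overlap(f.blocks[j + 1], right)
                ):
                    linked = True
                    break
            if linked:
                break
        if not linked:
            return False
    return True


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pair_mergeable(a: BlockAlignment, b: BlockAlignment, c: ClusteringCriteria) -> bool:
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) >= c.max_5prime_overhang:
        return False
    if abs(a.end - b.end) >= c.max_3prime_overhang:
        return False
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo >= hi:
        return False
    cov_a = np.zeros(hi - lo, dtype=bool)
    cov_b = np.zeros(hi - lo, dtype=bool)
    for s, e in a.blocks:
        s, e = max(s, lo), min(e, hi)
        if s < e:
            cov_a[s - lo : e - lo] = True
    for s, e in b.blocks:
        s, e = max(s, lo), min(e, hi)
        if s < e:
            cov_b[s - lo : e - lo] = True
    diff = cov_a != cov_b
    if not diff.any():
        return True
    padded = np.concatenate([[False], diff, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = edges[1::2] - edges[::2]
    return bool((runs < c.max_gap).all())


def cluster_long_reads(
    reads: Sequence[BlockAlignment], criteria: ClusteringCriteria | None = None
) -> list[list[BlockAlignment]]:
    """Connected components of the pair-mergeable relation, order-independent.

    Components are returned sorted by genomic position; each cluster's
    member list is sorted with its consensus (the longest member, ties by
    name) first.
    """
    criteria = criteria or ClusteringCriteria()
    reads = list(reads)
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_mergeable(reads[i], reads[j], criteria):
                parent[find(i)] = find(j)

    groups: dict[int, list[BlockAlignment]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(reads[i])
    clusters = []
    for members in groups.values():
        members.sort(key=lambda r: (-(r.end - r.start), r.name))
        clusters.append(members)
    clusters.sort(key=lambda m: (m[0].start, m[0].end, m[0].name))
    return clusters


def cluster_consensus(cluster: list[BlockAlignment]) -> BlockAlignment:
    """Consensus of a cluster: its longest member (no polishing)."""
    return cluster[0]


def full_length_isoform_present(
    clusters: Sequence[list[BlockAlignment]], gene: GeneModel
) -> bool:
    """True iff some cluster consensus overlaps every coding exon of the gene."""
    for cluster in clusters:
        consensus = cluster_consensus(cluster)
        if all(consensus.overlaps(e.interval) for e in gene.exons):
            return True
    return False


def transcript_status(
    gene_id: str,
    specimen_id: str,
    short_vote: ShortReadVote,
    tiling_vote: bool,
    isoform_vote: Optional[bool],
    has_longreads: bool,
) -> TranscriptStatus:
    """Combine the three votes; isoforms can rescue an incomplete tiling."""
    iso = bool(isoform_vote) if has_longreads else False
    if iso or (tiling_vote and short_vote != ShortReadVote.NO_FULL_LENGTH):
        final = FinalTranscriptCall.FULL_LENGTH
    else:
        final = FinalTranscriptCall.NO_FULL_LENGTH
    return TranscriptStatus(
        gene_id=gene_id,
        specimen_id=specimen_id,
        short_read_vote=short_vote,
        tiling_vote=tiling_vote,
        isoform_vote=isoform_vote if has_longreads else None,
        final=final,
    )


def evaluate_transcripts(
    family,
    specimens,
    min_zero_length: int = 10,
    low_depth_threshold: float = 1.0,
    criteria: ClusteringCriteria | None = None,
):
    """Per gene x specimen transcript status table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    statuses: dict[tuple[str, str], TranscriptStatus] = {}
    iso_clusters = {
        sid: cluster_long_reads(ev.isoforms or [], criteria)
        for sid, ev in specimens.items()
        if ev.has_longreads and ev.isoforms is not None
    }
    for gene in family.genes:
        tracks = {
            sid: ev.transcript_tracks[gene.gene_id]
            for sid, ev in specimens.items()
            if ev.transcript_tracks is not None
        }
        mask = None
        if tracks:
            he = high_expressors(tracks)
            mask = build_mappability_mask({s: tracks[s] for s in he},
                                          low_depth_threshold=low_depth_threshold)
        for sid, ev in specimens.items():
            if ev.transcript_tracks is None:
                continue
            zr = detect_zero_regions(tracks[sid], min_length=min_zero_length)
            vote = short_read_vote(zr, mask)
            tiling = exon_linkage_complete(ev.fragments or [], gene)
            has_lr = ev.has_longreads and ev.isoforms is not None
            iso = (
                full_length_isoform_present(iso_clusters[sid], gene) if has_lr else None
            )
            st = transcript_status(gene.gene_id, sid, vote, tiling, iso, has_lr)
            statuses[(gene.gene_id, sid)] = st
            rows.append(
                dict(
                    gene_id=gene.gene_id,
                    specimen_id=sid,
                    short_read_vote=st.short_read_vote.value,
                    tiling_vote=st.tiling_vote,
                    isoform_vote=st.isoform_vote,
                    n_zero_regions=len(zr),
                    final=st.final.value,
                )
            )
    return pd.DataFrame(rows)
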