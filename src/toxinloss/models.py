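"""Shared domain types for the toxin gene-family loss pipeline.

Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based, closed) is converted at the I/O boundary.  All sequences are on
the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

Interval = tuple[int, int]

DOMAIN_LABELS = ("signal", "pro", "metalloproteinase", "disintegrin", "cysteine_rich")

#: exon domain layout of the full (P3 / class III) gene template
TEMPLATE_DOMAINS = (
    "signal",
    "pro",
    "pro",
    "metalloproteinase",
    "metalloproteinase",
    "metalloproteinase",
    "metalloproteinase",
    "metalloproteinase",
    "metalloproteinase",
    "disintegrin",
    "disintegrin",
    "cysteine_rich",
    "cysteine_rich",
)

#: number of exons per structural class (prefix of the template)
CLASS_N_EXONS = {"P1": 9, "P2": 11, "P3": 13}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class InputError(ValueError):
    """Raised on malformed analysis inputs."""


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_length(a: Interval) -> int:
    return a[1] - a[0]


@dataclass(frozen=True)
class Exon:
    index: int  # 1-based, as in figure annotations
    interval: Interval  # genome coordinates on the family reference
    domain_label: str


@dataclass
class GeneModel:
    """One paralog: genomic placement, exon/domain structure and sequences."""

    gene_id: str
    klass: str  # P1 / P2 / P3
    locus_interval: Interval
    exons: list[Exon]
    transcript_seq: str
    protein_seq: str

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(interval_length(e.interval) for e in self.exons)

    def exon(self, index: int) -> Exon:
        return self.exons[index - 1]

    def exon_transcript_interval(self, index: int) -> Interval:
        """Interval of exon ``index`` in transcript coordinates."""
        start = sum(interval_length(e.interval) for e in self.exons[: index - 1])
        return (start, start + interval_length(self.exons[index - 1].interval))

    def domain_exon_indices(self, domain_label: str) -> list[int]:
        return [e.index for e in self.exons if e.domain_label == domain_label]

    def domain_protein_interval(self, domain_label: str) -> Interval:
        """Amino-acid interval of a domain (exons are codon-aligned)."""
        idx = self.domain_exon_indices(domain_label)
        if not idx:
            raise InputError(f"{self.gene_id} has no {domain_label} domain")
        start_nt = self.exon_transcript_interval(idx[0])[0]
        end_nt = self.exon_transcript_interval(idx[-1])[1]
        return (start_nt // 3, end_nt // 3)

    def validate(self) -> None:
        prev_end = self.locus_interval[0] - 1
        for e in self.exons:
            if e.interval[0] <= prev_end:
                raise InputError(f"{self.gene_id}: exons not disjoint/sorted")
            if e.interval[0] < self.locus_interval[0] or e.interval[1] > self.locus_interval[1]:
                raise InputError(f"{self.gene_id}: exon outside locus interval")
            prev_end = e.interval[1] - 1
        if self.klass == "P1":
            for e in self.exons:
                if e.domain_label in ("disintegrin", "cysteine_rich"):
                    raise InputError("P1 genes carry no disintegrin/cysteine-rich exons")
        if "*" in self.protein_seq:
            raise InputError(f"{self.gene_id}: internal stop codon in protein")


@dataclass
class FamilyReference:
    """The paralogous family: one reference contig plus gene and hard-region annotation."""

    reference_name: str
    reference_seq: str
    genes: list[GeneModel]
    hard_regions: list[Interval]
    control_gene_id: Optional[str]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def target_gene(self) -> GeneModel:
        """The single P1 gene (the MPO-like locus whose loss is under study)."""
        p1 = [g for g in self.genes if g.klass == "P1"]
        if len(p1) != 1:
            raise InputError(f"expected exactly one P1 gene, found {len(p1)}")
        return p1[0]

    @property
    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein_seq for g in self.genes}

    def hard_transcript_positions(self, gene: GeneModel) -> np.ndarray:
        """Boolean mask over the gene's transcript marking hard-region positions."""
        mask = np.zeros(gene.transcript_length, dtype=bool)
        for region in self.hard_regions:
            for e in gene.exons:
                if intervals_overlap(region, e.interval):
                    ts, te = gene.exon_transcript_interval(e.index)
                    lo = max(region[0], e.interval[0]) - e.interval[0]
                    hi = min(region[1], e.interval[1]) - e.interval[0]
                    mask[ts + lo : ts + hi] = True
        return mask


@dataclass(frozen=True)
class Allele:
    """One haplotype state of one gene in one specimen."""

    kind: str  # intact | deleted | fusion | frameshift | divergent
    partner_gene_id: Optional[str] = None
    breakpoint_exon: Optional[int] = None
    exon_index: Optional[int] = None
    indel_length: Optional[int] = None
    substitution_rate: Optional[float] = None

    @staticmethod
    def intact() -> "Allele":
        return Allele("intact")

    @staticmethod
    def deleted() -> "Allele":
        return Allele("deleted")

    @staticmethod
    def fusion(partner_gene_id: str, breakpoint_exon: int) -> "Allele":
        return Allele("fusion", partner_gene_id=partner_gene_id, breakpoint_exon=breakpoint_exon)

    @staticmethod
    def frameshift(exon_index: int, indel_length: int = 1) -> "Allele":
        if indel_length % 3 == 0:
            raise ConfigurationError("frameshift indel length must not be a multiple of 3")
        return Allele("frameshift", exon_index=exon_index, indel_length=indel_length)

    @staticmethod
    def divergent(substitution_rate: float) -> "Allele":
        return Allele("divergent", substitution_rate=substitution_rate)

    def validate(self, family: FamilyReference, gene: GeneModel) -> None:
        if self.kind == "fusion":
            partner = family.gene(self.partner_gene_id)  # KeyError if absent
            if not (1 <= self.breakpoint_exon < partner.n_exons):
                raise ConfigurationError("fusion breakpoint outside partner exon range")
            if self.breakpoint_exon >= gene.n_exons:
                raise ConfigurationError("fusion breakpoint at/after target gene end")
        elif self.kind == "frameshift":
            if not (1 <= self.exon_index <= gene.n_exons):
                raise ConfigurationError("frameshift exon outside gene")
        elif self.kind not in ("intact", "deleted", "divergent"):
            raise ConfigurationError(f"unknown allele kind {self.kind!r}")


@dataclass
class GenotypeSpec:
    specimen_id: str
    region: str  # east | west
    alleles: dict[str, tuple[Allele, Allele]]

    def validate(self, family: FamilyReference) -> None:
        if self.region not in ("east", "west"):
            raise ConfigurationError(f"unknown region {self.region!r}")
        for gene_id, pair in self.alleles.items():
            gene = family.gene(gene_id)
            for allele in pair:
                allele.validate(family, gene)
                if gene_id == family.control_gene_id and allele.kind != "intact":
                    raise ConfigurationError("control gene must stay intact")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic family and evidence generator.

    Depth/abundance defaults are chosen so that the desk-scale preset
    reproduces the evidence regimes the analysis distinguishes: saturating
    peptide/transcript evidence for intact expressed genes, a detectable-but-
    low unambiguous depth inside hard regions, and near-zero leakage for
    deleted genes.
    """

    # family structure
    n_genes: int = 8
    exon_length_nt: int = 120
    intron_length: int = 200
    intergenic_length: int = 600
    mean_protein_identity: float = 0.88
    identity_spread: float = 0.06
    hard_exons: tuple[int, int] = (5, 6)  # copied between target and a paralog

    # cohorts and genotypes
    n_west: int = 4
    n_east: int = 4
    genotype_preset: str = "atrox_like"  # atrox_like | all_intact | random
    west_loss_freq: float = 0.7  # random mode: per-allele loss frequency
    east_loss_freq: float = 0.2
    loss_class_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)  # del, fusion, fs
    fusion_breakpoint_exon: int = 6
    frameshift_exon: int = 7
    frameshift_indel_length: int = 1

    # proteomic evidence
    abundance_tpm: float = 1000.0  # per-gene transcript abundance
    abundance_overrides: dict = field(default_factory=dict)
    peptide_yield: float = 20.0  # expected count per tryptic peptide at 1000 TPM, diploid
    min_peptide_length: int = 6
    contamination_rate: float = 0.001

    # transcript evidence
    transcript_depth: float = 200.0  # per-position depth at 1000 TPM, diploid
    hard_depth_factor: float = 0.02
    fusion_expression_factor: float = 0.05
    n_isoform_reads: int = 3
    isoform_start_jitter: int = 30
    isoform_end_jitter: int = 8
    fragment_exon_window: int = 3

    # capture evidence
    capture_depth: float = 40.0
    bait_spacing: int = 125
    capture_bait_cv: float = 0.2
    capture_noise_floor: float = 0.0

    seed: int = 0

    def tpm(self, gene_id: str) -> float:
        return float(self.abundance_overrides.get(gene_id, self.abundance_tpm))

    @property
    def identity_band(self) -> Interval:
        return (
            self.mean_protein_identity - self.identity_spread,
            self.mean_protein_identity + self.identity_spread,
        )

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.exon_length_nt % 3 != 0:
            raise ConfigurationError("exon length must be codon-aligned")
        lo, hi = self.identity_band
        if not (0.0 < lo < hi <= 1.0):
            raise ConfigurationError("infeasible protein identity band")
        for p in (self.contamination_rate, *self.loss_class_probs):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(sum(self.loss_class_probs) - 1.0) > 1e-9:
            raise ConfigurationError("loss class probabilities must sum to 1")
        for v in (self.transcript_depth, self.capture_depth, self.bait_spacing,
                  self.intron_length, self.intergenic_length):
            if v <= 0:
                raise ConfigurationError("depths and spacings must be positive")
        if self.n_west < 0 or self.n_east < 0:
            raise ConfigurationError("cohort sizes must be >= 0")

    @staticmethod
    def atrox_like(**overrides) -> "SimulationConfig":
        """Desk-scale preset emulating the western-range MPO1 loss complex."""
        return replace(SimulationConfig(), genotype_preset="atrox_like", **overrides)

    @staticmethod
    def full_scale(**overrides) -> "SimulationConfig":
        """30-gene preset mirroring the ~1.2 Mb reference complex scale."""
        kwargs = dict(n_genes=30, intergenic_length=2000, n_west=8, n_east=19)
        kwargs.update(overrides)
        return replace(SimulationConfig(), **kwargs)


@dataclass
class BlockAlignment:
    """A spliced alignment (BED12 semantics): ordered blocks on one chrom."""

    chrom: str
    name: str
    blocks: list[Interval]  # absolute genome coordinates, sorted, disjoint

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def covered_positions(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for s, e in self.blocks])

    def overlaps(self, interval: Interval) -> bool:
        return any(intervals_overlap(b, interval) for b in self.blocks)


@dataclass
class SpecimenEvidence:
    """All evidence layers for one specimen. Absent layers are ``None``."""

    specimen_id: str
    region: str
    peptides: Optional[pd.DataFrame] = None  # columns: peptide_seq, count
    transcript_tracks: Optional[dict[str, np.ndarray]] = None  # gene_id -> depth
    fragments: Optional[list[BlockAlignment]] = None
    isoforms: Optional[list[BlockAlignment]] = None
    locus_depth: Optional[np.ndarray] = None  # over the family reference
    contigs: Optional[dict[str, str]] = None
    has_longreads: bool = True
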