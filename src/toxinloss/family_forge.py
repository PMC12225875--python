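"""Synthetic paralogous toxin gene family and per-specimen evidence layers.

The generator emulates a metalloproteinase-like gene complex: a family of
highly similar paralogs in three structural classes (P1 metalloproteinase-
only, P2 +disintegrin, P3 +disintegrin/cysteine-rich) on one reference
contig, with a near-identical "hard region" shared between the single P1
gene and one paralog, per-specimen genotypes carrying whole-gene deletions,
a chimeric fusion allele and a frameshifted allele, and the three evidence
layers the downstream analysis consumes (venom peptide counts, venom-gland
transcript coverage/fragments/isoforms, targeted-capture depth and contigs).

All randomness flows through ``numpy.random.default_rng`` seeded from the
caller's seed plus a fixed per-operation stream constant, so identical
config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq as _Seq

from .models import (
    CLASS_N_EXONS,
    TEMPLATE_DOMAINS,
    Allele,
    BlockAlignment,
    ConfigurationError,
    Exon,
    FamilyReference,
    GeneModel,
    GenotypeSpec,
    Interval,
    SimulationConfig,
)
from .peptide_evidence import tryptic_digest

_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _CODON_TABLE[_b1 + _b2 + _b3] = str(_Seq(_b1 + _b2 + _b3).translate())
_NONSTOP_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in _NONSTOP_CODONS:
    _AA_TO_CODONS.setdefault(_CODON_TABLE[_c], []).append(_c)
_AAS = sorted(_AA_TO_CODONS)

# per-operation seed stream constants
_STREAM_FAMILY = 1
_STREAM_GENOTYPES = 2
_STREAM_PEPTIDES = 3
_STREAM_TRANSCRIPTS = 4
_STREAM_CAPTURE = 5
_STREAM_ALLELE = 6


def _rng(seed: int, stream: int, *keys: str) -> np.random.Generator:
    """Deterministic generator for (seed, stream) plus optional string keys."""
    words = [int(seed), int(stream)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(words)


def translate(nt: str) -> str:
    n = len(nt) - len(nt) % 3
    return "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, n, 3))


def translate_until_stop(nt: str) -> str:
    aa = translate(nt)
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


# ---------------------------------------------------------------------------
# family construction


def _mutate_codons(codons: list[str], n_changes: int, rng: np.random.Generator) -> list[str]:
    out = list(codons)
    positions = rng.choice(len(codons), size=min(n_changes, len(codons)), replace=False)
    for pos in positions:
        old_aa = _CODON_TABLE[out[pos]]
        choices = [a for a in _AAS if a != old_aa]
        new_aa = choices[rng.integers(len(choices))]
        cands = _AA_TO_CODONS[new_aa]
        out[pos] = cands[rng.integers(len(cands))]
    return out


def _core_identity(codons_a: list[str], codons_b: list[str], n_core: int) -> float:
    aa_a = [_CODON_TABLE[c] for c in codons_a[:n_core]]
    aa_b = [_CODON_TABLE[c] for c in codons_b[:n_core]]
    return float(np.mean([x == y for x, y in zip(aa_a, aa_b)]))


def _class_pattern(n_genes: int) -> tuple[list[str], int, int]:
    """Class per gene plus (target_index, control_index)."""
    target_idx = n_genes // 2 if n_genes > 1 else 0
    control_idx = target_idx + 1 if target_idx + 1 < n_genes else target_idx - 1
    classes = []
    for i in range(n_genes):
        classes.append("P2" if i % 3 == 1 else "P3")
    classes[target_idx] = "P1"
    if n_genes > 1:
        classes[control_idx] = "P3"
    return classes, target_idx, control_idx


def _gene_names(classes: list[str], target_idx: int, control_idx: int) -> list[str]:
    names = [""] * len(classes)
    mad = iter(["MAD5a", "MAD3", "MAD1"] + [f"MAD{i}" for i in range(6, 40)])
    mdc = iter(["MDC8", "MDC2", "MDC7"] + [f"MDC{i}" for i in range(9, 40)])
    for i, k in enumerate(classes):
        if i == target_idx:
            names[i] = "MPO1"
        elif i == control_idx and len(classes) > 1:
            names[i] = "MDC4"
        elif k == "P2":
            names[i] = next(mad)
        else:
            names[i] = next(mdc)
    return names


def build_gene_family(config: SimulationConfig, seed: int | None = None) -> FamilyReference:
    """Generate the paralogous family on one reference contig.

    Paralogs diverge from a common full-length (P3) template at a per-gene
    rate tuned so pairwise core protein identities fall inside
    ``config.identity_band``; structural classes keep a class-specific exon
    prefix of the template.  The target P1 gene receives exact copies of one
    paralog's hard exons, creating the near-identical segment where
    unambiguous read mapping fails.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    n = config.n_genes
    exon_aa = config.exon_length_nt // 3
    n_codons = len(TEMPLATE_DOMAINS) * exon_aa
    n_core_aa = CLASS_N_EXONS["P1"] * exon_aa
    classes, target_idx, control_idx = _class_pattern(n)
    names = _gene_names(classes, target_idx, control_idx)
    hard_partner_idx = None
    if n > 1:
        candidates = [i for i, k in enumerate(classes) if k == "P3" and i != target_idx]
        non_control = [i for i in candidates if i != control_idx]
        hard_partner_idx = (non_control or candidates)[0]

    rng = _rng(seed, _STREAM_FAMILY)
    r0 = (1.0 - config.mean_protein_identity) / 2.0
    lo, hi = config.identity_band
    for _attempt in range(25):
        template = [_NONSTOP_CODONS[i] for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons)]
        rates = rng.uniform(0.7 * r0, 1.3 * r0, size=n)
        gene_codons = [
            _mutate_codons(template, int(round(r * n_codons)), rng) for r in rates
        ]
        if hard_partner_idx is not None:
            e0, e1 = config.hard_exons
            s, e = (e0 - 1) * exon_aa, e1 * exon_aa
            gene_codons[target_idx][s:e] = gene_codons[hard_partner_idx][s:e]
        if n == 1:
            break
        idents = [
            _core_identity(gene_codons[i], gene_codons[j], n_core_aa)
            for i, j in itertools.combinations(range(n), 2)
        ]
        if lo <= min(idents) and max(idents) <= hi:
            break
    else:
        raise ConfigurationError("protein identity band infeasible for this configuration")

    # assemble the reference contig
    pieces: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n):
        spacer = "".join(_BASES[b] for b in rng.integers(4, size=config.intergenic_length))
        pieces.append(spacer)
        pos += len(spacer)
        gene_start = pos
        exons: list[Exon] = []
        n_exons = CLASS_N_EXONS[classes[i]]
        for e in range(n_exons):
            if e > 0:
                intron = "".join(_BASES[b] for b in rng.integers(4, size=config.intron_length))
                pieces.append(intron)
                pos += len(intron)
            exon_nt = "".join(gene_codons[i][e * exon_aa : (e + 1) * exon_aa])
            pieces.append(exon_nt)
            exons.append(Exon(e + 1, (pos, pos + len(exon_nt)), TEMPLATE_DOMAINS[e]))
            pos += len(exon_nt)
        transcript = "".join(
            "".join(gene_codons[i][e * exon_aa : (e + 1) * exon_aa]) for e in range(n_exons)
        )
        genes.append(
            GeneModel(
                gene_id=names[i],
                klass=classes[i],
                locus_interval=(gene_start, pos),
                exons=exons,
                transcript_seq=transcript,
                protein_seq=translate(transcript),
            )
        )
    pieces.append("".join(_BASES[b] for b in rng.integers(4, size=config.intergenic_length)))
    reference = "".join(pieces)

    hard_regions: list[Interval] = []
    if hard_partner_idx is not None:
        for gi in (target_idx, hard_partner_idx):
            for e_idx in range(config.hard_exons[0], config.hard_exons[1] + 1):
                hard_regions.append(genes[gi].exon(e_idx).interval)
    hard_regions.sort()

    family = FamilyReference(
        reference_name="MPcomplex",
        reference_seq=reference,
        genes=genes,
        hard_regions=hard_regions,
        control_gene_id=names[control_idx] if n > 1 else None,
    )
    for g in genes:
        g.validate()
    return family


# ---------------------------------------------------------------------------
# genotypes

_ATROX_WEST = ["hom_deletion", "hom_deletion", "fusion", "het_deletion"]
_ATROX_EAST = ["intact", "intact", "frameshift_het", "hom_deletion"]


def _target_alleles(cls: str, config: SimulationConfig, partner_id: str | None) -> tuple[Allele, Allele]:
    if cls == "intact":
        return (Allele.intact(), Allele.intact())
    if cls == "hom_deletion":
        return (Allele.deleted(), Allele.deleted())
    if cls == "het_deletion":
        return (Allele.deleted(), Allele.intact())
    if cls == "fusion":
        if partner_id is None:
            raise ConfigurationError("fusion allele requested but the family has no P2 partner")
        fus = Allele.fusion(partner_id, config.fusion_breakpoint_exon)
        return (fus, fus)
    if cls == "frameshift_het":
        return (Allele.frameshift(config.frameshift_exon, config.frameshift_indel_length),
                Allele.intact())
    raise ConfigurationError(f"unknown mutation class {cls!r}")


def assign_genotypes(
    family: FamilyReference,
    config: SimulationConfig,
    seed: int | None = None,
    loss_gene_id: str | None = None,
) -> list[GenotypeSpec]:
    """Draw per-specimen genotypes for the two cohorts.

    ``atrox_like`` places a fixed mutation inventory (two western and one
    eastern homozygous deletion, one het deletion, one homozygous fusion,
    one het frameshift) on seed-shuffled specimens; ``random`` draws loss
    alleles at the configured per-region frequencies.
    """
    seed = config.seed if seed is None else seed
    target = family.target_gene
    loss_gene_id = loss_gene_id or target.gene_id
    if loss_gene_id == family.control_gene_id:
        raise ConfigurationError("loss alleles may not target the control gene")
    loss_gene = family.gene(loss_gene_id)
    partners = [g.gene_id for g in family.genes if g.klass == "P2"]
    partner_id = partners[0] if partners else None
    rng = _rng(seed, _STREAM_GENOTYPES)

    specs: list[GenotypeSpec] = []
    for region, n_specimens in (("west", config.n_west), ("east", config.n_east)):
        if config.genotype_preset == "all_intact":
            classes = ["intact"] * n_specimens
        elif config.genotype_preset == "atrox_like":
            base = _ATROX_WEST if region == "west" else _ATROX_EAST
            if n_specimens < len(base):
                raise ConfigurationError("atrox_like preset needs >= 4 specimens per region")
            classes = base + ["intact"] * (n_specimens - len(base))
            classes = [classes[i] for i in rng.permutation(len(classes))]
        elif config.genotype_preset == "random":
            freq = config.west_loss_freq if region == "west" else config.east_loss_freq
            classes = []
            for _ in range(n_specimens):
                lost = rng.random(2) < freq
                kinds = []
                for hap_lost in lost:
                    if not hap_lost:
                        kinds.append("intact")
                    else:
                        k = rng.choice(3, p=list(config.loss_class_probs))
                        kinds.append(["deleted", "fusion", "frameshift"][k])
                classes.append(tuple(kinds))
        else:
            raise ConfigurationError(f"unknown genotype preset {config.genotype_preset!r}")

        for i, cls in enumerate(classes):
            sid = f"{region}_{i + 1}"
            alleles = {g.gene_id: (Allele.intact(), Allele.intact()) for g in family.genes}
            if isinstance(cls, tuple):  # random mode: explicit per-haplotype kinds
                pair = []
                for kind in cls:
                    if kind == "intact":
                        pair.append(Allele.intact())
                    elif kind == "deleted":
                        pair.append(Allele.deleted())
                    elif kind == "fusion":
                        if partner_id is None:
                            raise ConfigurationError("no P2 partner for fusion allele")
                        pair.append(Allele.fusion(partner_id, config.fusion_breakpoint_exon))
                    else:
                        pair.append(Allele.frameshift(config.frameshift_exon,
                                                      config.frameshift_indel_length))
                alleles[loss_gene.gene_id] = (pair[0], pair[1])
            else:
                alleles[loss_gene.gene_id] = _target_alleles(cls, config, partner_id)
            spec = GenotypeSpec(specimen_id=sid, region=region, alleles=alleles)
            spec.validate(family)
            specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# allele realization


@dataclass
class AlleleRealization:
    """Concrete molecular consequences of one allele of one gene."""

    kind: str
    abundance_factor: float  # transcript output relative to an intact allele
    transcript_cover: np.ndarray  # bool over the gene's reference transcript
    protein_seq: str | None
    contig_seq: str | None
    genome_intervals: list[Interval]  # reference segments present on this haplotype


def realize_allele(
    family: FamilyReference,
    gene: GeneModel,
    allele: Allele,
    config: SimulationConfig,
    specimen_id: str,
    seed: int,
) -> AlleleRealization:
    ref = family.reference_seq
    L = gene.transcript_length
    locus = gene.locus_interval
    if allele.kind == "intact":
        return AlleleRealization(
            "intact", 1.0, np.ones(L, bool), gene.protein_seq,
            ref[locus[0] : locus[1]], [locus],
        )
    if allele.kind == "deleted":
        return AlleleRealization("deleted", 0.0, np.zeros(L, bool), None, None, [])
    if allele.kind == "frameshift":
        exon = gene.exon(allele.exon_index)
        ins = ("ACGTT" * allele.indel_length)[: allele.indel_length]
        mid_genome = (exon.interval[0] + exon.interval[1]) // 2
        contig = (
            ref[locus[0] : mid_genome] + ins + ref[mid_genome : locus[1]]
        )
        ts, te = gene.exon_transcript_interval(allele.exon_index)
        mid_tx = ts + (mid_genome - exon.interval[0])
        transcript = gene.transcript_seq[:mid_tx] + ins + gene.transcript_seq[mid_tx:]
        return AlleleRealization(
            "frameshift", 1.0, np.ones(L, bool), translate_until_stop(transcript),
            contig, [locus],
        )
    if allele.kind == "fusion":
        partner = family.gene(allele.partner_gene_id)
        b = allele.breakpoint_exon
        p_end = partner.exon(b).interval[1]
        g_resume = gene.exon(b).interval[1]
        contig = ref[partner.locus_interval[0] : p_end] + ref[g_resume : locus[1]]
        tx = "".join(
            partner.transcript_seq[slice(*partner.exon_transcript_interval(e))]
            for e in range(1, b + 1)
        ) + "".join(
            gene.transcript_seq[slice(*gene.exon_transcript_interval(e))]
            for e in range(b + 1, gene.n_exons + 1)
        )
        cover = np.zeros(L, bool)
        cover[gene.exon_transcript_interval(b + 1)[0] :] = True
        return AlleleRealization(
            "fusion", config.fusion_expression_factor, cover,
            translate_until_stop(tx), contig,
            [(partner.locus_interval[0], p_end), (g_resume, locus[1])],
        )
    if allele.kind == "divergent":
        rng = _rng(seed, _STREAM_ALLELE, specimen_id, gene.gene_id)
        codons = [gene.transcript_seq[i : i + 3] for i in range(0, L, 3)]
        n_changes = int(round(allele.substitution_rate * len(codons)))
        codons = _mutate_codons(codons, n_changes, rng)
        transcript = "".join(codons)
        contig = list(ref[locus[0] : locus[1]])
        for e in gene.exons:
            ts, te = gene.exon_transcript_interval(e.index)
            off = e.interval[0] - locus[0]
            contig[off : off + (te - ts)] = transcript[ts:te]
        return AlleleRealization(
            "divergent", 1.0, np.ones(L, bool), translate_until_stop(transcript),
            "".join(contig), [locus],
        )
    raise ConfigurationError(f"unknown allele kind {allele.kind!r}")


def _realizations(family, genotypes, config, seed):
    out: dict[tuple[str, str], list[AlleleRealization]] = {}
    for gt in genotypes:
        for gene in family.genes:
            out[(gt.specimen_id, gene.gene_id)] = [
                realize_allele(family, gene, a, config, gt.specimen_id, seed)
                for a in gt.alleles[gene.gene_id]
            ]
    return out


# ---------------------------------------------------------------------------
# peptide evidence


def expected_peptide_intensities(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """Per-specimen expected peptide counts, including cross-specimen leakage.

    Expectation per peptide occurrence is
    ``peptide_yield * (TPM/1000) * allele_factor / 2``; contamination adds
    ``contamination_rate`` times every other specimen's expectation.
    """
    seed = config.seed if seed is None else seed
    real = _realizations(family, genotypes, config, seed)
    raw: dict[str, dict[str, float]] = {}
    for gt in genotypes:
        lam: dict[str, float] = {}
        for gene in family.genes:
            scale = config.peptide_yield * config.tpm(gene.gene_id) / 1000.0 / 2.0
            for r in real[(gt.specimen_id, gene.gene_id)]:
                if r.protein_seq is None or r.abundance_factor == 0:
                    continue
                for pep in tryptic_digest(r.protein_seq, min_length=config.min_peptide_length):
                    lam[pep] = lam.get(pep, 0.0) + scale * r.abundance_factor
        raw[gt.specimen_id] = lam
    totals: dict[str, float] = {}
    for lam in raw.values():
        for pep, v in lam.items():
            totals[pep] = totals.get(pep, 0.0) + v
    contaminated = {}
    for sid, lam in raw.items():
        out = dict(lam)
        if config.contamination_rate > 0:
            for pep, tot in totals.items():
                leak = config.contamination_rate * (tot - lam.get(pep, 0.0))
                if leak > 0:
                    out[pep] = out.get(pep, 0.0) + leak
        contaminated[sid] = out
    return contaminated


def simulate_peptide_table(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson-sampled detected-peptide table (specimen_id, peptide_seq, count)."""
    seed = config.seed if seed is None else seed
    lam = expected_peptide_intensities(family, genotypes, config, seed)
    rng = _rng(seed, _STREAM_PEPTIDES)
    rows = []
    for gt in genotypes:
        peps = sorted(lam[gt.specimen_id])
        counts = rng.poisson([lam[gt.specimen_id][p] for p in peps]) if peps else []
        for pep, c in zip(peps, counts):
            if c > 0:
                rows.append((gt.specimen_id, pep, int(c)))
    return pd.DataFrame(rows, columns=["specimen_id", "peptide_seq", "count"])


# ---------------------------------------------------------------------------
# transcript evidence


def expected_transcript_depth(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Expected unambiguous per-position depth on each gene's reference transcript."""
    seed = config.seed if seed is None else seed
    real = _realizations(family, genotypes, config, seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for gt in genotypes:
        tracks = {}
        for gene in family.genes:
            lam = np.zeros(gene.transcript_length)
            base = config.transcript_depth * config.tpm(gene.gene_id) / 1000.0 / 2.0
            for r in real[(gt.specimen_id, gene.gene_id)]:
                lam[r.transcript_cover] += base * r.abundance_factor
            lam[family.hard_transcript_positions(gene)] *= config.hard_depth_factor
            tracks[gene.gene_id] = lam
        out[gt.specimen_id] = tracks
    return out


def _exon_window_fragments(gene: GeneModel, window: int, chrom: str, sid: str):
    frags = []
    n = gene.n_exons
    w = min(window, n)
    for start in range(1, n - w + 2):
        blocks = [gene.exon(e).interval for e in range(start, start + w)]
        frags.append(BlockAlignment(chrom, f"{sid}.{gene.gene_id}.frag{start}", blocks))
    return frags


def simulate_transcript_evidence(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, dict]:
    """Per-specimen coverage tracks, assembled-fragment and isoform alignments.

    Full-length alleles (intact, frameshift, divergent) yield a sliding
    window of partial transcripts linking every adjacent exon pair plus
    jittered full-length isoform reads; fusion alleles yield one chimeric
    fragment/read; deleted alleles yield nothing.
    """
    seed = config.seed if seed is None else seed
    lam_all = expected_transcript_depth(family, genotypes, config, seed)
    real = _realizations(family, genotypes, config, seed)
    rng = _rng(seed, _STREAM_TRANSCRIPTS)
    chrom = family.reference_name
    out: dict[str, dict] = {}
    for gt in genotypes:
        sid = gt.specimen_id
        tracks = {
            gid: rng.poisson(lam).astype(np.int64) for gid, lam in lam_all[sid].items()
        }
        fragments: list[BlockAlignment] = []
        isoforms: list[BlockAlignment] = []
        seen_frag_keys: set[tuple] = set()
        for gene in family.genes:
            full = [r for r in real[(sid, gene.gene_id)]
                    if r.abundance_factor >= 0.5 and r.kind != "deleted"]
            fusions = [r for r in real[(sid, gene.gene_id)] if r.kind == "fusion"]
            if full:
                for frag in _exon_window_fragments(gene, config.fragment_exon_window,
                                                   chrom, sid):
                    key = tuple(map(tuple, frag.blocks))
                    if key not in seen_frag_keys:
                        seen_frag_keys.add(key)
                        fragments.append(frag)
                blocks = [e.interval for e in gene.exons]
                for k in range(config.n_isoform_reads):
                    js = int(rng.integers(0, config.isoform_start_jitter + 1))
                    je = int(rng.integers(0, config.isoform_end_jitter + 1))
                    jb = [list(map(int, b)) for b in blocks]
                    jb[0][0] += min(js, jb[0][1] - jb[0][0] - 1)
                    jb[-1][1] -= min(je, jb[-1][1] - jb[-1][0] - 1)
                    isoforms.append(
                        BlockAlignment(chrom, f"{sid}.{gene.gene_id}.iso{k}",
                                       [tuple(b) for b in jb])
                    )
            for fi, r in enumerate(fusions):
                partner = family.gene(gt.alleles[gene.gene_id][fi].partner_gene_id)
                b = gt.alleles[gene.gene_id][fi].breakpoint_exon
                blocks = [partner.exon(e).interval for e in range(1, b + 1)] + [
                    gene.exon(e).interval for e in range(b + 1, gene.n_exons + 1)
                ]
                key = tuple(map(tuple, blocks))
                if key not in seen_frag_keys:
                    seen_frag_keys.add(key)
                    fragments.append(
                        BlockAlignment(chrom, f"{sid}.{gene.gene_id}.chimera", blocks)
                    )
                    isoforms.append(
                        BlockAlignment(chrom, f"{sid}.{gene.gene_id}.chimera_iso", blocks)
                    )
        fragments.sort(key=lambda f: (f.start, f.end, f.name))
        isoforms.sort(key=lambda f: (f.start, f.end, f.name))
        out[sid] = {"tracks": tracks, "fragments": fragments, "isoforms": isoforms}
    return out


# ---------------------------------------------------------------------------
# capture evidence


def expected_locus_copies(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-position haplotype copy number over the family reference."""
    seed = config.seed if seed is None else seed
    real = _realizations(family, genotypes, config, seed)
    L = len(family.reference_seq)
    out = {}
    for gt in genotypes:
        copies = np.full(L, 2.0)
        for gene in family.genes:
            s, e = gene.locus_interval
            copies[s:e] -= 2.0
            for r in real[(gt.specimen_id, gene.gene_id)]:
                for iv in r.genome_intervals:
                    copies[iv[0] : iv[1]] += 1.0
        out[gt.specimen_id] = copies
    return out


def simulate_capture_evidence(
    family: FamilyReference,
    genotypes: list[GenotypeSpec],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, dict]:
    """Per-specimen capture depth over the reference plus haplotype contigs.

    Depth is Poisson around ``capture_depth * copies / 2`` modulated by a
    per-bait-tile Gamma efficiency (tile size = bait_spacing), so coverage
    noise is spatially correlated at the bait scale.
    """
    seed = config.seed if seed is None else seed
    copies_all = expected_locus_copies(family, genotypes, config, seed)
    real = _realizations(family, genotypes, config, seed)
    rng = _rng(seed, _STREAM_CAPTURE)
    L = len(family.reference_seq)
    n_tiles = L // config.bait_spacing + 1
    out = {}
    for gt in genotypes:
        sid = gt.specimen_id
        if config.capture_bait_cv > 0:
            shape = 1.0 / config.capture_bait_cv**2
            eff = rng.gamma(shape, 1.0 / shape, size=n_tiles)
        else:
            eff = np.ones(n_tiles)
        eff_per_pos = np.repeat(eff, config.bait_spacing)[:L]
        lam = config.capture_depth * copies_all[sid] / 2.0 * eff_per_pos
        lam += config.capture_noise_floor
        depth = rng.poisson(lam).astype(np.int64)
        contigs: dict[str, str] = {}
        for gene in family.genes:
            seen: dict[str, str] = {}
            for hap, r in enumerate(real[(sid, gene.gene_id)]):
                if r.contig_seq is None:
                    continue
                if r.contig_seq in seen.values():
                    continue  # identical haplotypes assemble into one contig
                seen[f"{sid}.{gene.gene_id}.h{hap + 1}"] = r.contig_seq
            contigs.update(seen)
        out[sid] = {"locus_depth": depth, "contigs": contigs}
    return out


# ---------------------------------------------------------------------------
# truth


def expected_final_status(family: FamilyReference, genotype: GenotypeSpec) -> dict[str, str]:
    """Ground-truth final status per gene implied by the genotype.

    Carriers of one functional allele (het deletion, het frameshift) are
    EXPRESSED; homozygous loss maps to the mechanism of the surviving
    evidence (deletion < fusion < disruption precedence mirrors the
    integration rules).
    """
    out = {}
    for gene in family.genes:
        kinds = sorted(a.kind for a in genotype.alleles[gene.gene_id])
        if any(k in ("intact", "divergent") for k in kinds):
            out[gene.gene_id] = "EXPRESSED"
        elif "frameshift" in kinds:
            out[gene.gene_id] = "LOST_DISRUPTED"
        elif "fusion" in kinds:
            out[gene.gene_id] = "LOST_FUSION"
        else:
            out[gene.gene_id] = "LOST_DELETED"
    return out
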