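"""Generator: family structure, genotype draws, evidence statistics, round trips."""

import filecmp
from dataclasses import replace

import numpy as np
import pytest
from Bio import Align
from scipy import stats

from toxinloss import SimulationConfig, family_forge, io, pipeline
from toxinloss.models import Allele, ConfigurationError, GenotypeSpec


def _aligned_identity(a: str, b: str) -> float:
    """Independent oracle: near-ungapped global alignment identity."""
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    ident = sum(
        x == y
        for (rs, re), (qs, qe) in zip(*aln.aligned)
        for x, y in zip(a[rs:re], b[qs:qe])
    )
    return ident / max(len(a), len(b))


class TestBuildGeneFamily:
    def test_single_gene_family_has_no_hard_regions(self):
        cfg = replace(SimulationConfig(), n_genes=1)
        fam = family_forge.build_gene_family(cfg, seed=3)
        assert len(fam.genes) == 1
        assert fam.hard_regions == []

    def test_full_scale_preset_reaches_thirty_genes(self):
        cfg = SimulationConfig.full_scale()
        fam = family_forge.build_gene_family(cfg, seed=2)
        assert len(fam.genes) == 30
        assert sum(g.klass == "P1" for g in fam.genes) == 1
        assert fam.control_gene_id is not None

    def test_structure_invariants(self, family):
        assert sum(g.klass == "P1" for g in family.genes) == 1
        control = family.gene(family.control_gene_id)
        assert control.klass == "P3"
        for g in family.genes:
            g.validate()  # disjoint sorted exons, no internal stops, P1 domains
        assert len(family.hard_regions) >= 1

    def test_pairwise_core_identities_within_band_by_alignment_oracle(self, family, config):
        lo, hi = config.identity_band
        core_len = 9 * config.exon_length_nt // 3
        cores = [g.protein_seq[:core_len] for g in family.genes]
        idents = [
            _aligned_identity(cores[i], cores[j])
            for i in range(len(cores))
            for j in range(i + 1, len(cores))
        ]
        assert lo <= min(idents) and max(idents) <= hi

    def test_hard_region_exons_near_identical_between_paralogs(self, family):
        for region in family.hard_regions:
            copies = []
            for g in family.genes:
                for e in g.exons:
                    if e.interval == region:
                        s, t = g.exon_transcript_interval(e.index)
                        copies.append((e.index, g.transcript_seq[s:t]))
            assert len(copies) == 1
            idx, seq = copies[0]
            twins = [
                g.transcript_seq[slice(*g.exon_transcript_interval(idx))]
                for g in family.genes
                if g.exon(idx).interval != region and idx <= g.n_exons
            ]
            best = max(np.mean([a == b for a, b in zip(seq, t)]) for t in twins)
            assert best >= 0.98


class TestAssignGenotypes:
    def test_all_intact_preset(self, family, config):
        cfg = replace(config, genotype_preset="all_intact")
        for gt in family_forge.assign_genotypes(family, cfg, seed=5):
            assert all(
                a.kind == b.kind == "intact" for a, b in gt.alleles.values()
            )

    def test_atrox_like_mutation_inventory_is_exact(self, family, genotypes):
        target = family.target_gene.gene_id
        kinds = sorted(
            tuple(sorted(a.kind for a in gt.alleles[target])) for gt in genotypes
        )
        assert kinds.count(("deleted", "deleted")) == 3
        assert kinds.count(("deleted", "intact")) == 1
        assert kinds.count(("fusion", "fusion")) == 1
        assert kinds.count(("frameshift", "intact")) == 1
        assert kinds.count(("intact", "intact")) == 2
        west_loss = sum(
            any(a.kind != "intact" for a in gt.alleles[target])
            for gt in genotypes
            if gt.region == "west"
        )
        assert west_loss == 4  # west cohort enriched for loss
        control = family.control_gene_id
        assert all(
            a.kind == "intact"
            for gt in genotypes
            for a in gt.alleles[control]
        )

    def test_control_gene_loss_request_rejected(self, family, config):
        with pytest.raises(ConfigurationError):
            family_forge.assign_genotypes(
                family, config, seed=1, loss_gene_id=family.control_gene_id
            )

    def test_random_mode_allele_frequency_within_binomial_interval(self, family, config):
        cfg = replace(config, genotype_preset="random", west_loss_freq=0.6,
                      n_west=2, n_east=0)
        target = family.target_gene.gene_id
        n_seeds = 400
        losses = 0
        for seed in range(n_seeds):
            for gt in family_forge.assign_genotypes(family, cfg, seed=seed):
                losses += sum(a.kind != "intact" for a in gt.alleles[target])
        n_alleles = n_seeds * 2 * 2
        lo = stats.binom.ppf(0.005, n_alleles, 0.6)
        hi = stats.binom.ppf(0.995, n_alleles, 0.6)
        assert lo <= losses <= hi


class TestPeptideSimulation:
    def test_zero_abundance_zero_contamination_yields_no_rows(self, family, config):
        cfg = replace(
            config,
            genotype_preset="all_intact",
            n_west=1,
            n_east=1,
            contamination_rate=0.0,
            abundance_overrides={family.target_gene.gene_id: 0.0},
        )
        gts = family_forge.assign_genotypes(family, cfg, seed=2)
        pep = family_forge.simulate_peptide_table(family, gts, cfg, seed=2)
        target_peps = set(
            family_forge.tryptic_digest(family.target_gene.protein_seq)
        ) - set().union(
            *(
                set(family_forge.tryptic_digest(g.protein_seq))
                for g in family.genes
                if g.gene_id != family.target_gene.gene_id
            )
        )
        assert not set(pep["peptide_seq"]) & target_peps

    def test_hom_deletion_emits_no_unique_peptide_tiling(self, family, config):
        target = family.target_gene
        cfg = replace(config, n_west=1, n_east=1, genotype_preset="all_intact")
        gts = family_forge.assign_genotypes(family, cfg, seed=3)
        gts[0].alleles[target.gene_id] = (Allele.deleted(), Allele.deleted())
        lam = family_forge.expected_peptide_intensities(family, gts, cfg, seed=3)
        unique = set(family_forge.tryptic_digest(target.protein_seq)) - set().union(
            *(
                set(family_forge.tryptic_digest(g.protein_seq))
                for g in family.genes
                if g.gene_id != target.gene_id
            )
        )
        deleted_sid = gts[0].specimen_id
        leak = [lam[deleted_sid].get(p, 0.0) for p in unique]
        # only contamination-level expectation, far below one detection each
        assert max(leak) <= cfg.contamination_rate * cfg.peptide_yield * 1.01
        cfg0 = replace(cfg, contamination_rate=0.0)
        lam0 = family_forge.expected_peptide_intensities(family, gts, cfg0, seed=3)
        assert all(lam0[deleted_sid].get(p, 0.0) == 0.0 for p in unique)

    def test_abundance_ratio_recovered_within_poisson_band(self, family, config):
        g1, g2 = family.genes[0].gene_id, family.genes[2].gene_id
        cfg = replace(
            config,
            genotype_preset="all_intact",
            n_west=1,
            n_east=0,
            contamination_rate=0.0,
            abundance_overrides={g1: 4000.0, g2: 1000.0},
        )
        gts = family_forge.assign_genotypes(family, cfg, seed=4)
        lam = family_forge.expected_peptide_intensities(family, gts, cfg, seed=4)
        pep = family_forge.simulate_peptide_table(family, gts, cfg, seed=4)
        counts = dict(zip(pep["peptide_seq"], pep["count"]))
        unique = {}
        for gid in (g1, g2):
            prot = family.gene(gid).protein_seq
            others = [g.protein_seq for g in family.genes if g.gene_id != gid]
            unique[gid] = [
                p
                for p in family_forge.tryptic_digest(prot)
                if not any(p in o for o in others)
            ]
        tot1 = sum(counts.get(p, 0) for p in unique[g1])
        tot2 = sum(counts.get(p, 0) for p in unique[g2])
        mu1 = sum(lam[gts[0].specimen_id][p] for p in unique[g1])
        mu2 = sum(lam[gts[0].specimen_id][p] for p in unique[g2])
        assert mu1 / mu2 == pytest.approx(4.0, rel=0.05)
        assert stats.poisson.ppf(0.005, mu1) <= tot1 <= stats.poisson.ppf(0.995, mu1)
        assert stats.poisson.ppf(0.005, mu2) <= tot2 <= stats.poisson.ppf(0.995, mu2)


class TestTranscriptSimulation:
    def test_expressed_gene_covered_everywhere_outside_hard_regions(
        self, family, genotypes, config
    ):
        tx = family_forge.simulate_transcript_evidence(family, genotypes, config, seed=1)
        target = family.target_gene
        expressed = next(
            gt for gt in genotypes
            if all(a.kind == "intact" for a in gt.alleles[target.gene_id])
        )
        depth = tx[expressed.specimen_id]["tracks"][target.gene_id]
        hard = family.hard_transcript_positions(target)
        assert (depth[~hard] > 0).all()

    def test_hom_deleted_gene_has_zero_unique_coverage(self, family, genotypes, config):
        tx = family_forge.simulate_transcript_evidence(family, genotypes, config, seed=1)
        target = family.target_gene
        deleted = next(
            gt for gt in genotypes
            if all(a.kind == "deleted" for a in gt.alleles[target.gene_id])
        )
        assert (tx[deleted.specimen_id]["tracks"][target.gene_id] == 0).all()

    def test_frameshift_allele_transcribes_like_intact(self, family, genotypes, config):
        lam = family_forge.expected_transcript_depth(family, genotypes, config, seed=1)
        target = family.target_gene.gene_id
        carrier = next(
            gt for gt in genotypes
            if any(a.kind == "frameshift" for a in gt.alleles[target])
        )
        intact = next(
            gt for gt in genotypes
            if all(a.kind == "intact" for a in gt.alleles[target])
        )
        np.testing.assert_allclose(
            lam[carrier.specimen_id][target], lam[intact.specimen_id][target]
        )


class TestCaptureSimulation:
    def test_hom_deletion_depth_zero_with_normal_control(self, family, genotypes, config):
        cap = family_forge.simulate_capture_evidence(family, genotypes, config, seed=1)
        target = family.target_gene
        control = family.gene(family.control_gene_id)
        deleted = next(
            gt for gt in genotypes
            if all(a.kind == "deleted" for a in gt.alleles[target.gene_id])
        )
        depth = cap[deleted.specimen_id]["locus_depth"]
        assert depth[slice(*target.locus_interval)].sum() == 0
        assert depth[slice(*control.locus_interval)].mean() > 0.5 * config.capture_depth

    def test_het_deletion_mean_ratio_near_half_over_seeds(self, family, config):
        target = family.target_gene
        control = family.gene(family.control_gene_id)
        cfg = replace(config, n_west=1, n_east=0, genotype_preset="all_intact")
        ratios = []
        for seed in range(100):
            gts = family_forge.assign_genotypes(family, cfg, seed=seed)
            gts[0].alleles[target.gene_id] = (Allele.deleted(), Allele.intact())
            cap = family_forge.simulate_capture_evidence(family, gts, cfg, seed=seed)
            depth = cap[gts[0].specimen_id]["locus_depth"]
            ratios.append(
                depth[slice(*target.locus_interval)].mean()
                / depth[slice(*control.locus_interval)].mean()
            )
        assert 0.45 <= np.mean(ratios) <= 0.55

    def test_fusion_contig_switches_exon_content_at_breakpoint(self, family, config):
        target = family.target_gene
        partner = next(g for g in family.genes if g.klass == "P2")
        allele = Allele.fusion(partner.gene_id, config.fusion_breakpoint_exon)
        real = family_forge.realize_allele(family, target, allele, config, "s", seed=1)
        b = config.fusion_breakpoint_exon
        contig = real.contig_seq
        for e in range(1, b + 1):
            s, t = partner.exon_transcript_interval(e)
            assert partner.transcript_seq[s:t] in contig
        for e in range(b + 1, target.n_exons + 1):
            s, t = target.exon_transcript_interval(e)
            assert target.transcript_seq[s:t] in contig
        # the target's own pre-breakpoint exons are gone unless shared
        s, t = target.exon_transcript_interval(1)
        assert target.transcript_seq[s:t] not in contig


class TestDeterminismAndRoundTrip:
    def test_identical_config_and_seed_give_byte_identical_outputs(self, tmp_path, config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        pipeline.simulate(config, 7, d1)
        pipeline.simulate(config, 7, d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_simulation_round_trip_reparses_to_generating_structures(
        self, tmp_path, family, genotypes, config
    ):
        pipeline.simulate(config, 1, tmp_path / "sim")
        fam2, specimens, truth = io.load_simulation(tmp_path / "sim")
        assert fam2.reference_seq == family.reference_seq
        assert fam2.gene_ids == family.gene_ids
        assert fam2.hard_regions == family.hard_regions
        assert fam2.control_gene_id == family.control_gene_id
        for g1 in family.genes:
            g2 = fam2.gene(g1.gene_id)
            assert g2.protein_seq == g1.protein_seq
            assert [e.interval for e in g2.exons] == [e.interval for e in g1.exons]
        tx = family_forge.simulate_transcript_evidence(family, genotypes, config, seed=1)
        cap = family_forge.simulate_capture_evidence(family, genotypes, config, seed=1)
        for gt in genotypes:
            sid = gt.specimen_id
            for gid, track in tx[sid]["tracks"].items():
                np.testing.assert_array_equal(specimens[sid].transcript_tracks[gid], track)
            np.testing.assert_array_equal(
                specimens[sid].locus_depth, cap[sid]["locus_depth"]
            )
            assert specimens[sid].contigs == cap[sid]["contigs"]
            got = {(f.name, tuple(f.blocks)) for f in specimens[sid].fragments}
            want = {(f.name, tuple(f.blocks)) for f in tx[sid]["fragments"]}
            assert got == want
        gts2, expected = truth
        assert [g.specimen_id for g in gts2] == [g.specimen_id for g in genotypes]
        for a, b in zip(gts2, genotypes):
            assert a.alleles == b.alleles

    def test_dosage_monotonicity_of_expectations(self, family, config):
        target = family.target_gene
        cfg = replace(config, n_west=1, n_east=0, genotype_preset="all_intact",
                      contamination_rate=0.0, capture_bait_cv=0.0)
        dosages = [
            (Allele.deleted(), Allele.deleted()),
            (Allele.deleted(), Allele.intact()),
            (Allele.intact(), Allele.intact()),
        ]
        pep_totals, tx_totals, locus_means = [], [], []
        unique = set(family_forge.tryptic_digest(target.protein_seq)) - set().union(
            *(
                set(family_forge.tryptic_digest(g.protein_seq))
                for g in family.genes
                if g.gene_id != target.gene_id
            )
        )
        for pair in dosages:
            gts = family_forge.assign_genotypes(family, cfg, seed=0)
            gts[0].alleles[target.gene_id] = pair
            sid = gts[0].specimen_id
            lam = family_forge.expected_peptide_intensities(family, gts, cfg, seed=0)
            pep_totals.append(sum(lam[sid].get(p, 0.0) for p in unique))
            tx = family_forge.expected_transcript_depth(family, gts, cfg, seed=0)
            tx_totals.append(tx[sid][target.gene_id].sum())
            copies = family_forge.expected_locus_copies(family, gts, cfg, seed=0)
            locus_means.append(copies[sid][slice(*target.locus_interval)].mean())
        for series in (pep_totals, tx_totals, locus_means):
            assert series == sorted(series)
            assert series[0] < series[-1]
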