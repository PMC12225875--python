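"""End-to-end orchestration: simulate, analyse each layer, integrate, test.

``simulate`` writes a complete synthetic study to disk; ``analyze`` runs the
three evidence modules and the integration on loaded evidence; ``run_pipeline``
chains both (or starts from an existing input directory), writes the report
bundle and returns it.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import family_forge, io
from .integrate import (
    ContingencyResult,
    associate_geography,
    call_gene_status,
    expression_summary,
)
from .locus_evidence import LocusCall, LocusState, evaluate_loci
from .models import FamilyReference, InputError, SimulationConfig, SpecimenEvidence
from .peptide_evidence import ExpressionState, evaluate_peptides
from .transcript_evidence import FinalTranscriptCall, evaluate_transcripts

logger = logging.getLogger("toxinloss")

READ_LENGTH = 150  # nt, used only for descriptive count summaries


@dataclass
class ReportBundle:
    family: FamilyReference
    statuses: pd.DataFrame
    locus_calls: dict[tuple[str, str], LocusCall]
    expression: pd.DataFrame
    transcripts: pd.DataFrame
    tpm: pd.DataFrame
    association: Optional[ContingencyResult]
    truth: Optional[tuple]


def simulate(config: SimulationConfig, seed: int, outdir: str | Path) -> Path:
    """Generate a synthetic study and write every evidence layer to outdir."""
    family = family_forge.build_gene_family(config, seed)
    genotypes = family_forge.assign_genotypes(family, config, seed)
    if not genotypes:
        raise InputError("empty specimen table: no cohorts configured")
    peptides = family_forge.simulate_peptide_table(family, genotypes, config, seed)
    transcripts = family_forge.simulate_transcript_evidence(family, genotypes, config, seed)
    capture = family_forge.simulate_capture_evidence(family, genotypes, config, seed)
    expected = {
        g.specimen_id: family_forge.expected_final_status(family, g) for g in genotypes
    }
    outdir = Path(outdir)
    io.write_simulation(outdir, family, genotypes, peptides, transcripts, capture, expected)
    logger.info("simulated %d genes x %d specimens into %s",
                config.n_genes, len(genotypes), outdir)
    return outdir


def evidence_from_sim(family, genotypes, peptides, transcripts, capture):
    """Assemble in-memory SpecimenEvidence from simulator outputs."""
    specimens = {}
    for g in genotypes:
        sid = g.specimen_id
        pep = peptides[peptides["specimen_id"] == sid][["peptide_seq", "count"]]
        specimens[sid] = SpecimenEvidence(
            specimen_id=sid,
            region=g.region,
            peptides=pep.reset_index(drop=True),
            transcript_tracks=transcripts[sid]["tracks"],
            fragments=transcripts[sid]["fragments"],
            isoforms=transcripts[sid]["isoforms"],
            locus_depth=capture[sid]["locus_depth"],
            contigs=capture[sid]["contigs"],
        )
    return specimens


def analyze(
    family: FamilyReference,
    specimens: dict[str, SpecimenEvidence],
    truth=None,
    corrected: bool = True,
) -> ReportBundle:
    """Run the three evidence layers and integrate them per gene x specimen."""
    if not specimens:
        raise InputError("empty specimen table")
    expression = evaluate_peptides(family, specimens)
    transcripts = evaluate_transcripts(family, specimens)
    locus_calls = evaluate_loci(family, specimens)

    exp_lookup = {
        (r.gene_id, r.specimen_id): ExpressionState(r.state)
        for r in expression.itertuples()
    }
    tx_lookup = {
        (r.gene_id, r.specimen_id): FinalTranscriptCall(r.final)
        for r in transcripts.itertuples()
    }
    rows = []
    for gene in family.genes:
        for sid in specimens:
            key = (gene.gene_id, sid)
            status = call_gene_status(
                exp_lookup.get(key),
                tx_lookup.get(key),
                locus_calls.get(key),
                gene_id=gene.gene_id,
                specimen_id=sid,
            )
            logger.info("status %s x %s -> %s (%s)", gene.gene_id, sid,
                        status.final.value, status.mechanism_note)
            rows.append(
                dict(
                    gene_id=gene.gene_id,
                    specimen_id=sid,
                    expression="absent" if status.expression is None else status.expression.value,
                    transcript="absent" if status.transcript is None else status.transcript.value,
                    locus="absent" if status.locus is None else status.locus.value,
                    final=status.final.value,
                    mechanism_note=status.mechanism_note,
                )
            )
    statuses = pd.DataFrame(rows)

    counts = pd.DataFrame(
        {
            sid: {
                gid: float(np.sum(ev.transcript_tracks[gid])) / READ_LENGTH
                for gid in (ev.transcript_tracks or {})
            }
            for sid, ev in specimens.items()
            if ev.transcript_tracks is not None
        }
    )
    counts.index.name = "gene_id"
    lengths = {g.gene_id: g.transcript_length for g in family.genes}
    tpm = expression_summary(counts, lengths) if len(counts) else pd.DataFrame()

    regions = {sid: ev.region for sid, ev in specimens.items()}
    association = None
    try:
        association = associate_geography(
            statuses, regions, family.target_gene.gene_id, corrected=corrected
        )
    except InputError as exc:
        logger.warning("association not computed: %s", exc)

    return ReportBundle(
        family=family,
        statuses=statuses,
        locus_calls=locus_calls,
        expression=expression,
        transcripts=transcripts,
        tpm=tpm,
        association=association,
        truth=truth,
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(bundle.statuses, outdir / "statuses.tsv")
    io.write_tsv(bundle.expression, outdir / "expression_states.tsv")
    io.write_tsv(bundle.transcripts, outdir / "transcript_status.tsv")
    if len(bundle.tpm):
        io.write_tsv(bundle.tpm, outdir / "expression_tpm.tsv")
    locus_rows = []
    detail = {}
    for (gid, sid), call in sorted(bundle.locus_calls.items()):
        ratio = call.summary.ratio if call.summary else None
        locus_rows.append(
            dict(gene_id=gid, specimen_id=sid, state=call.state.value,
                 ratio=None if ratio is None else round(ratio, 4))
        )
        detail[f"{gid}|{sid}"] = {
            "state": call.state.value,
            "fusions": [vars(f) for f in call.fusions],
            "disruptions": [
                {**vars(d), "kind": d.kind.value} for d in call.disruptions
            ],
            "exon_calls": [
                {
                    "contig_id": c.contig_id,
                    "interval": list(c.contig_interval),
                    "best_gene_id": c.best_gene_id,
                    "exon_index": c.exon_index,
                    "aa_identity": round(c.aa_identity, 4),
                    "frame_status": c.frame_status.value,
                }
                for c in call.exon_calls
            ],
        }
    io.write_tsv(pd.DataFrame(locus_rows), outdir / "locus_calls.tsv")
    (outdir / "locus_detail.json").write_text(json.dumps(detail, indent=1, sort_keys=True))
    if bundle.association is not None:
        t = bundle.association.table
        payload = {
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "chi2": bundle.association.chi2,
            "df": bundle.association.df,
            "p": bundle.association.p,
            "corrected": bundle.association.corrected,
        }
        (outdir / "association.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline(
    seed: int,
    outdir: str | Path,
    config: SimulationConfig | None = None,
    input_dir: str | Path | None = None,
    corrected: bool = True,
) -> ReportBundle:
    """Simulate (or load) a study, analyse it and write the report bundle."""
    outdir = Path(outdir)
    if config is not None:
        sim_dir = simulate(config, seed, outdir / "sim")
    elif input_dir is not None:
        sim_dir = Path(input_dir)
    else:
        raise InputError("run_pipeline needs a simulation config or an input directory")
    family, specimens, truth = io.load_simulation(sim_dir)
    bundle = analyze(family, specimens, truth=truth, corrected=corrected)
    write_report(bundle, outdir)
    return bundle


def status_accuracy(bundle: ReportBundle) -> float:
    """Fraction of gene x specimen final statuses matching the truth labels."""
    if bundle.truth is None:
        raise InputError("no truth labels available")
    _, expected = bundle.truth
    hits = total = 0
    for row in bundle.statuses.itertuples():
        want = expected[row.specimen_id][row.gene_id]
        total += 1
        hits += row.final == want
    return hits / total if total else float("nan")
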