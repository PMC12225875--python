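"""Readers and writers for the package's on-disk formats.

Internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted here and nowhere else.  bedGraph tracks are run-length encoded
with zero runs omitted; BED12 carries spliced alignments.  All writers
emit deterministically ordered text so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Allele,
    BlockAlignment,
    Exon,
    FamilyReference,
    GeneModel,
    GenotypeSpec,
    SpecimenEvidence,
)

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(family: FamilyReference, path: str | Path) -> None:
    """Gene/exon features with class, control and domain_label attributes."""
    lines = ["##gff-version 3"]
    chrom = family.reference_name
    lines.append(f"##sequence-region {chrom} 1 {len(family.reference_seq)}")
    for g in family.genes:
        attrs = f"ID={g.gene_id};klass={g.klass}"
        if g.gene_id == family.control_gene_id:
            attrs += ";control=true"
        s, e = g.locus_interval
        lines.append(
            "\t".join([chrom, "toxinloss", "gene", str(s + 1), str(e), ".", "+", ".", attrs])
        )
        for ex in g.exons:
            es, ee = ex.interval
            lines.append(
                "\t".join(
                    [
                        chrom,
                        "toxinloss",
                        "exon",
                        str(es + 1),
                        str(ee),
                        ".",
                        "+",
                        "0",
                        f"ID={g.gene_id}.exon{ex.index};Parent={g.gene_id};"
                        f"exon_index={ex.index};domain_label={ex.domain_label}",
                    ]
                )
            )
    for i, (s, e) in enumerate(family.hard_regions, 1):
        lines.append(
            "\t".join(
                [chrom, "toxinloss", "hard_region", str(s + 1), str(e), ".", "+", ".",
                 f"ID=hard_region{i}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_family(fasta_path: str | Path, gff3_path: str | Path) -> FamilyReference:
    """Rebuild a FamilyReference from its FASTA + GFF3 representation."""
    from .family_forge import translate

    seqs = read_fasta(fasta_path)
    (chrom, reference_seq), = seqs.items()
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    control_gene_id = None
    for gf in db.features_of_type("gene", order_by="start"):
        gene_id = gf.attributes["ID"][0]
        if gf.attributes.get("control", ["false"])[0] == "true":
            control_gene_id = gene_id
        exons = []
        for ef in db.children(gf, featuretype="exon", order_by="start"):
            exons.append(
                Exon(
                    index=int(ef.attributes["exon_index"][0]),
                    interval=(ef.start - 1, ef.end),
                    domain_label=ef.attributes["domain_label"][0],
                )
            )
        transcript = "".join(reference_seq[s:e] for s, e in (x.interval for x in exons))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                klass=gf.attributes["klass"][0],
                locus_interval=(gf.start - 1, gf.end),
                exons=exons,
                transcript_seq=transcript,
                protein_seq=translate(transcript),
            )
        )
    hard_regions = [
        (hf.start - 1, hf.end) for hf in db.features_of_type("hard_region", order_by="start")
    ]
    return FamilyReference(
        reference_name=chrom,
        reference_seq=reference_seq,
        genes=genes,
        hard_regions=sorted(hard_regions),
        control_gene_id=control_gene_id,
    )


# ---------------------------------------------------------------------------
# bedGraph


def _rle(values: np.ndarray):
    values = np.asarray(values)
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return [(int(s), int(e), values[s]) for s, e in zip(starts, ends)]


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """One chrom per track; zero runs are omitted (bedGraph convention)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            for s, e, v in _rle(tracks[chrom]):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    tracks = {chrom: np.zeros(n, dtype=np.int64) for chrom, n in lengths.items()}
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str})
    if len(df):
        for chrom, sub in df.groupby("chrom"):
            arr = tracks[chrom]
            for s, e, v in zip(sub["start"], sub["end"], sub["depth"]):
                arr[s:e] = v
    return tracks


# ---------------------------------------------------------------------------
# BED12


def write_bed12(alignments: Iterable[BlockAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            sizes = ",".join(str(e - s) for s, e in a.blocks) + ","
            starts = ",".join(str(s - a.start) for s, _ in a.blocks) + ","
            fh.write(
                "\t".join(
                    [
                        a.chrom, str(a.start), str(a.end), a.name, "0", "+",
                        str(a.start), str(a.end), "0,0,0",
                        str(len(a.blocks)), sizes, starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[BlockAlignment]:
    out = []
    text = Path(path).read_text()
    for line in text.splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        chrom, start, name = f[0], int(f[1]), f[3]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        out.append(BlockAlignment(chrom=chrom, name=name, blocks=blocks))
    return out


# ---------------------------------------------------------------------------
# tables and truth


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _allele_to_dict(a: Allele) -> dict:
    return {k: v for k, v in asdict(a).items() if v is not None}


def _allele_from_dict(d: dict) -> Allele:
    return Allele(**d)


def write_truth(
    genotypes: list[GenotypeSpec],
    expected_status: Mapping[str, Mapping[str, str]],
    path: str | Path,
) -> None:
    payload = {
        "genotypes": [
            {
                "specimen_id": g.specimen_id,
                "region": g.region,
                "alleles": {
                    gid: [_allele_to_dict(a) for a in pair]
                    for gid, pair in sorted(g.alleles.items())
                },
            }
            for g in genotypes
        ],
        "expected_status": {s: dict(v) for s, v in sorted(expected_status.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> tuple[list[GenotypeSpec], dict[str, dict[str, str]]]:
    payload = json.loads(Path(path).read_text())
    genotypes = [
        GenotypeSpec(
            specimen_id=g["specimen_id"],
            region=g["region"],
            alleles={
                gid: (_allele_from_dict(pair[0]), _allele_from_dict(pair[1]))
                for gid, pair in g["alleles"].items()
            },
        )
        for g in payload["genotypes"]
    ]
    return genotypes, payload["expected_status"]


# ---------------------------------------------------------------------------
# whole-simulation round trip


def write_simulation(outdir: str | Path, family, genotypes, peptides, transcripts,
                     capture, expected_status) -> None:
    outdir = Path(outdir)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    (outdir / "capture").mkdir(exist_ok=True)
    write_fasta({family.reference_name: family.reference_seq}, outdir / "reference.fasta")
    write_gff3(family, outdir / "genes.gff3")
    write_tsv(peptides, outdir / "peptides.tsv")
    write_tsv(
        pd.DataFrame(
            [(g.specimen_id, g.region) for g in genotypes],
            columns=["specimen_id", "region"],
        ),
        outdir / "specimens.tsv",
    )
    for g in genotypes:
        sid = g.specimen_id
        tr = transcripts[sid]
        write_bedgraph(tr["tracks"], outdir / "transcripts" / f"{sid}.coverage.bedgraph")
        write_bed12(tr["fragments"], outdir / "transcripts" / f"{sid}.fragments.bed")
        write_bed12(tr["isoforms"], outdir / "transcripts" / f"{sid}.isoforms.bed")
        cap = capture[sid]
        write_bedgraph(
            {family.reference_name: cap["locus_depth"]},
            outdir / "capture" / f"{sid}.coverage.bedgraph",
        )
        write_fasta(cap["contigs"], outdir / "capture" / f"{sid}.contigs.fasta")
    write_truth(genotypes, expected_status, outdir / "truth.json")


def load_simulation(outdir: str | Path):
    """Load a simulation directory back into analysis-ready structures."""
    outdir = Path(outdir)
    family = read_family(outdir / "reference.fasta", outdir / "genes.gff3")
    specimens_df = read_tsv(outdir / "specimens.tsv")
    peptides = read_tsv(outdir / "peptides.tsv")
    tx_lengths = {g.gene_id: g.transcript_length for g in family.genes}
    specimens: dict[str, SpecimenEvidence] = {}
    for _, row in specimens_df.iterrows():
        sid = row["specimen_id"]
        pep = peptides[peptides["specimen_id"] == sid][["peptide_seq", "count"]]
        specimens[sid] = SpecimenEvidence(
            specimen_id=sid,
            region=row["region"],
            peptides=pep.reset_index(drop=True),
            transcript_tracks=read_bedgraph(
                outdir / "transcripts" / f"{sid}.coverage.bedgraph", tx_lengths
            ),
            fragments=read_bed12(outdir / "transcripts" / f"{sid}.fragments.bed"),
            isoforms=read_bed12(outdir / "transcripts" / f"{sid}.isoforms.bed"),
            locus_depth=read_bedgraph(
                outdir / "capture" / f"{sid}.coverage.bedgraph",
                {family.reference_name: len(family.reference_seq)},
            )[family.reference_name],
            contigs=read_fasta(outdir / "capture" / f"{sid}.contigs.fasta"),
        )
    truth = None
    if (outdir / "truth.json").exists():
        truth = read_truth(outdir / "truth.json")
    return family, specimens, truth
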