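"""Call genomic mechanism per specimen: deletion dosage, fusion, frameshift.

Capture depth over the target gene relative to the control paralog gives
copy state (ratio ~0 homozygous deletion, ~0.5 heterozygous, ~1 intact);
annotating assembled contigs against the family exon library reveals
chimeric fusion genes (runs of donor-gene exons) and frame-disrupting
indels.
"""

from toxinloss import SimulationConfig, family_forge, pipeline
from toxinloss.locus_evidence import evaluate_loci

config = SimulationConfig.atrox_like()
family = family_forge.build_gene_family(config, seed=1)
genotypes = family_forge.assign_genotypes(family, config, seed=1)
peptides = family_forge.simulate_peptide_table(family, genotypes, config, seed=1)
tx = family_forge.simulate_transcript_evidence(family, genotypes, config, seed=1)
cap = family_forge.simulate_capture_evidence(family, genotypes, config, seed=1)
specimens = pipeline.evidence_from_sim(family, genotypes, peptides, tx, cap)

calls = evaluate_loci(family, specimens)
target = family.target_gene.gene_id
print(f"genomic state of {target}:\n")
for gt in genotypes:
    call = calls[(target, gt.specimen_id)]
    ratio = call.summary.ratio if call.summary else None
    line = f"{gt.specimen_id:9} ratio={ratio:5.2f}  {call.state.value}"
    for f in call.fusions:
        line += f"  [chimera: {f.donor_gene_id} exons {f.donor_exons}, {f.breakpoint}]"
    for d in call.disruptions:
        line += f"  [{d.kind.value} in exon {d.exon_index}]"
    print(line)
print("\nHet carriers keep an intact contig chain, so their state stays at the")
print("copy-ratio call while the mutant-contig report is kept as evidence.")
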