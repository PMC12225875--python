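"""Decide full-length transcript support from three independent votes.

Short-read coverage gaps are screened against a mappability mask built from
high-expressing specimens (a zero region where even high expressors show
marginal depth cannot prove absence); assembled fragments must tile and
link every exon junction; clustered long reads must contain a full-span
isoform.  Isoforms can rescue an incomplete tiling, but a positive
short-read contradiction vetoes tiling alone.
"""

from toxinloss import SimulationConfig, family_forge, pipeline
from toxinloss.transcript_evidence import evaluate_transcripts

config = SimulationConfig.atrox_like()
family = family_forge.build_gene_family(config, seed=1)
genotypes = family_forge.assign_genotypes(family, config, seed=1)
peptides = family_forge.simulate_peptide_table(family, genotypes, config, seed=1)
tx = family_forge.simulate_transcript_evidence(family, genotypes, config, seed=1)
cap = family_forge.simulate_capture_evidence(family, genotypes, config, seed=1)
specimens = pipeline.evidence_from_sim(family, genotypes, peptides, tx, cap)

table = evaluate_transcripts(family, specimens)
target = family.target_gene.gene_id
print(f"transcript status of {target}:\n")
print(table[table.gene_id == target][
    ["specimen_id", "short_read_vote", "tiling_vote", "isoform_vote",
     "n_zero_regions", "final"]
].to_string(index=False))
print("\nDeleted specimens show multiple unmasked zero regions, no tiling and no")
print("isoform; the fusion specimen keeps only the exons retained in the chimera.")
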