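import numpy as np
import pytest

from toxinloss import SimulationConfig, family_forge
from toxinloss.models import Exon, FamilyReference, GeneModel


@pytest.fixture(scope="session")
def config():
    return SimulationConfig.atrox_like()


@pytest.fixture(scope="session")
def family(config):
    return family_forge.build_gene_family(config, seed=1)


@pytest.fixture(scope="session")
def genotypes(family, config):
    return family_forge.assign_genotypes(family, config, seed=1)


def reverse_translate(protein: str) -> str:
    """One fixed codon per amino acid (test helper)."""
    codon = {aa: cods[0] for aa, cods in family_forge._AA_TO_CODONS.items()}
    return "".join(codon[aa] for aa in protein)


def make_single_domain_gene(gene_id: str, protein: str, offset: int = 0) -> GeneModel:
    """A one-exon gene whose whole protein is the metalloproteinase domain."""
    nt = reverse_translate(protein)
    return GeneModel(
        gene_id=gene_id,
        klass="P1",
        locus_interval=(offset, offset + len(nt)),
        exons=[Exon(1, (offset, offset + len(nt)), "metalloproteinase")],
        transcript_seq=nt,
        protein_seq=protein,
    )


def make_family(genes: list[GeneModel], control: str | None = None) -> FamilyReference:
    ref_len = max(g.locus_interval[1] for g in genes)
    return FamilyReference(
        reference_name="toy",
        reference_seq="A" * ref_len,
        genes=genes,
        hard_regions=[],
        control_gene_id=control,
    )
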