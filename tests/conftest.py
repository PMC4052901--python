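import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from regulonkit.core_model import Gene, Genome
from regulonkit.motif import SiteInstance
from regulonkit.operons import Operon
from regulonkit.reconstruction import Regulon, RegulonMember
from regulonkit.synthetic_data import SimulationConfig, simulate_pangenome


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def toy_genome() -> Genome:
    """Three genes on one 5-kb contig: two co-directional, one opposite."""
    rng = np.random.default_rng(42)
    return Genome(
        genome_id="toy",
        contigs={"chr": random_sequence(5000, rng)},
        genes=[
            Gene("geneA", "chr", 600, 1500, "+", "tagA", "glycolysis", False),
            Gene("geneB", "chr", 1550, 2450, "+", "tagB", "glycolysis", False),
            Gene("geneC", "chr", 2900, 3800, "-", "tagC", "regulation", True),
        ],
        proteins={"geneA": "MKLV" * 50, "geneB": "MAAR" * 50, "geneC": "MHTW" * 50},
    )


@pytest.fixture(scope="session")
def default_clade():
    """One default simulated clade shared by read-only tests."""
    return simulate_pangenome(SimulationConfig(seed=7))


def make_member(genome_id: str, operon_id: str, gene_ids: list[str],
                n_sites: int = 1, strand: str = "+") -> RegulonMember:
    op = Operon(
        operon_id=operon_id, genome_id=genome_id, contig_id="chr",
        strand=strand, gene_ids=gene_ids, first_gene_id=gene_ids[0],
    )
    sites = [
        SiteInstance(
            contig_id="chr", interval=(100 + 30 * k, 118 + 30 * k), strand=strand,
            sequence="A" * 18, score=10.0, offset_center=-85.0, offset_end=-76,
            anchor_operon_id=operon_id, genome_id=genome_id,
        )
        for k in range(n_sites)
    ]
    return RegulonMember(operon=op, sites=sites)


def make_regulon(genome_id: str, n_operons: int, genes_per_operon: int,
                 pathways: list[str], tf_gene_id: str = "tf") -> Regulon:
    members = []
    functions = {}
    for i in range(n_operons):
        gene_ids = [f"{genome_id}_g{i}_{j}" for j in range(genes_per_operon)]
        members.append(make_member(genome_id, f"{genome_id}:op{i}", gene_ids))
        label = pathways[i % len(pathways)] if pathways else ""
        for g in gene_ids:
            functions[g] = label
    return Regulon(
        tf_gene_id=tf_gene_id, genome_id=genome_id, members=members,
        gene_functions=functions,
    )
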