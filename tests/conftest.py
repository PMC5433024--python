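import os

import pytest

from guidepeak import GuideSpec
from guidepeak.simulate import PlantSpec, SimConfig, make_genome, plant_sites, \
    simulate_reads, write_fasta

#: SpCas9 VEGFA-site-2 style 20-mer used throughout the fixtures
GUIDE_SEQ = "GACCCCCTCCACCCCGCCTC"


@pytest.fixture(scope="session")
def guide_spec() -> GuideSpec:
    return GuideSpec(guide_seq=GUIDE_SEQ)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A seeded 120-kb genome with planted sites of varying abundance and
    one hotspot, simulated through to SAM + UMI files (sample + control)."""
    root = tmp_path_factory.mktemp("simdata")
    guide = GuideSpec(guide_seq=GUIDE_SEQ)
    cfg = SimConfig(seed=11, genome_length=120_000, hotspot_loci=(100_000,))
    genome = make_genome(cfg)
    plants = [
        PlantSpec(locus=10_000, abundance=20, label="on_target"),
        PlantSpec(locus=30_000, mismatch_positions=(2, 9), abundance=9, label="ot2"),
        PlantSpec(locus=50_000, mismatch_positions=(1, 5, 11, 16), strand="-",
                  abundance=6, label="ot4_minus"),
        PlantSpec(locus=70_000, mismatch_positions=(4,), abundance=2, label="weak"),
    ]
    genome, truth = plant_sites(genome, guide, plants)
    fasta = os.path.join(root, "genome.fa")
    write_fasta(genome, fasta)
    guide_fa = os.path.join(root, "guide.fa")
    with open(guide_fa, "w") as fh:
        fh.write(f">guide\n{GUIDE_SEQ}\n")
    out = simulate_reads(genome, truth, cfg, str(root))
    return {
        "root": str(root), "guide": guide, "cfg": cfg, "genome": genome,
        "truth": truth, "fasta": fasta, "guide_fa": guide_fa, "sim": out,
        "plants": plants,
    }
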