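import random

import pytest

from panrescue.pipeline import PipelineConfig, run_pipeline
from panrescue.simdata import SimConfig, simulate
from panrescue.svref import SVRecord, build_sv_reference


def random_genome(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def toy_ref():
    """A 3 kb single-contig genome used by unit tests."""
    return {"c": random_genome(3000, seed=123)}


@pytest.fixture(scope="session")
def toy_svref(toy_ref):
    """One DEL and one INS anchor over the toy genome."""
    rng = random.Random(7)
    ins_allele = "".join(rng.choice("ACGT") for _ in range(120))
    svs = [
        SVRecord("d0", "c", 1000, 1200, "DEL", 200),
        SVRecord("i0", "c", 2200, 2200, "INS", 120, ins_allele),
    ]
    return build_sv_reference(svs, toy_ref, flank=250, min_anchor_len=150)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A 40 kb simulated world (4 SVs, 30x) for pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("sim_small")
    cfg = SimConfig(seed=11, genome_length=40_000, n_svs=4,
                    sv_len_range=(60, 400), depth=30.0)
    return simulate(cfg, outdir)


@pytest.fixture(scope="session")
def small_result(small_world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("out_small")
    return run_pipeline(
        small_world.paths["ref"], small_world.paths["panel"],
        small_world.paths["sam"], outdir, PipelineConfig(seed=5),
    )


@pytest.fixture(scope="session")
def full_world(tmp_path_factory):
    """The stated evaluation world: 200 kb genome, 20 SVs of 60-1000 bp,
    30x 150 bp reads, panel with <=10 bp jitter and 2% divergence."""
    outdir = tmp_path_factory.mktemp("sim_full")
    return simulate(SimConfig(seed=42), outdir)


@pytest.fixture(scope="session")
def full_result(full_world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("out_full")
    return run_pipeline(
        full_world.paths["ref"], full_world.paths["panel"],
        full_world.paths["sam"], outdir, PipelineConfig(seed=7),
    )
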