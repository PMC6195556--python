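"""Shared fixtures: one moderate end-to-end synthetic study, reused across
test modules, plus small helpers for crafting reads."""

import numpy as np
import pytest

from venomgland import simulate as sim
from venomgland.reads import MergedRead, SequencingRead
from venomgland.report import run_pipeline


def make_read(seq, qual=38, rid="r1", sample="S1", lane="L1", mate=1):
    q = tuple([qual] * len(seq)) if isinstance(qual, int) else tuple(qual)
    return SequencingRead(id=rid, sequence=seq, quality=q, sample_id=sample,
                          lane_id=lane, mate=mate)


def make_merged(seq, rid="m1", sample="S1", qual=38):
    q = tuple([qual] * len(seq)) if isinstance(qual, int) else tuple(qual)
    return MergedRead(id=rid, sequence=seq, quality=q, sample_id=sample)


def random_dna(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def e2e_config():
    return sim.SimulationConfig(
        seed=5, n_individuals=8, n_toxins=12, n_nontoxins=6,
        family_sizes={"SVMP": 5, "CTL": 4, "PLA2": 2, "MYO": 1},
        depth_per_transcript=250, error_rate=0.001,
        fragment_mean=250, fragment_sd=60, absence_rate=0.1,
        chimera_count=1, expression_sigma=0.6, toxin_abundance_multiplier=3.0,
        toxin_length_range=(450, 900), nontoxin_length_range=(500, 900),
        de_effects=[sim.DEEffect("SVMP-1", "nontoxin_lineage", "Sonora", 3.0)],
    )


@pytest.fixture(scope="session")
def e2e_result(e2e_config):
    """Full pipeline run on the moderate synthetic study (shared; ~80 s)."""
    return run_pipeline(e2e_config, overlap=60, n_seeds=500, k_permutations=99)
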