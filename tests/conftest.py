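"""Shared fixtures: a small synthetic library processed end to end.

Session-scoped so the simulation and pipeline run once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from blhic.contacts import cluster_pets
from blhic.linker import LinkerSet, process_library
from blhic.simulate import SimConfig, simulate

SMALL_SEED = 2026


def small_config(**overrides) -> SimConfig:
    base = dict(
        genome_length=200_000,
        n_chroms=2,
        n_sites=40,
        n_loops=8,
        loop_dist_min=5_000,
        loop_dist_max=30_000,
        pairs_signal=2_700,
        pairs_noise=300,
        seed=SMALL_SEED,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    pets, stats, aligned = process_library(
        small_sim.read_pairs, LinkerSet(), small_sim.genome
    )
    return {"sim": small_sim, "pets": pets, "stats": stats, "aligned": aligned}


@pytest.fixture(scope="session")
def small_loops(small_pipeline):
    return cluster_pets(small_pipeline["pets"], anchor_extension=2500, min_count=5)


def loop_matches_truth(loop, truth_loop, tol=2500) -> bool:
    """A recovered loop matches a planted loop when each recovered anchor is
    within ``tol`` of the corresponding planted site (either pairing)."""

    def near(anchor, site):
        return anchor.chrom == site.chrom and (
            anchor.start - tol <= site.center <= anchor.end + tol
        )

    a1, a2 = loop.anchor1, loop.anchor2
    s1, s2 = truth_loop.anchor1, truth_loop.anchor2
    return (near(a1, s1) and near(a2, s2)) or (near(a1, s2) and near(a2, s1))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
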