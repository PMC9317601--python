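"""Shared fixtures: hand-sized deterministic campaigns and matrices."""

import numpy as np
import pytest

from efoscreen import GeneratorConfig, ScreeningMatrix, generate_campaign
from efoscreen.channels import ChannelKey
from efoscreen.synthetic import generate_fixture_instance


@pytest.fixture(scope="session")
def tiny_separable():
    return generate_fixture_instance("tiny-separable")


@pytest.fixture(scope="session")
def complementary():
    return generate_fixture_instance("two-complementary-channels")


@pytest.fixture(scope="session")
def heavy_failures():
    return generate_fixture_instance("heavy-failures")


@pytest.fixture(scope="session")
def small_campaign():
    """One mid-sized seeded campaign reused across read-only tests."""
    cfg = GeneratorConfig(n_ligands=300, n_actives=6,
                          frame_times=tuple(range(100, 1101, 200)), seed=5)
    return generate_campaign(cfg)


def make_matrix(values, is_active, frame_ns=100, monomer_cycle="ABCD",
                score_cycle=("PS", "CS", "CSOPT")):
    """Build a ScreeningMatrix directly from a value array (ligands x
    channels) with synthetic channel keys and neutral ligand ids."""
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    ids = np.array([f"L{str(i).zfill(4)}" for i in range(n)], dtype=object)
    channels = []
    for j in range(c):
        channels.append(ChannelKey(
            frame_ns=frame_ns + 25 * (j // (len(monomer_cycle) *
                                            len(score_cycle))),
            monomer=monomer_cycle[j % len(monomer_cycle)],
            score_type=score_cycle[(j // len(monomer_cycle)) %
                                   len(score_cycle)],
            aggregation="BEST" if j % 2 == 0 else "MEAN"))
    # keys must be unique; the cycling above guarantees it for c <= 24
    assert len(set(channels)) == c
    return ScreeningMatrix(ligand_ids=ids,
                           is_active=np.asarray(is_active, dtype=bool),
                           channels=channels, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
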