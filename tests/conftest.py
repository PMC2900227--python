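"""Shared fixtures: tiny hand-built networks and small synthetic datasets."""

import logging

import numpy as np
import pytest

from wgdnet.collapse import AncestralNetwork
from wgdnet.net_io import AgeClass, ParalogTable, RegulatoryNetwork
from wgdnet.spinmodel import SpinParams
from wgdnet.synthgen import SyntheticSpec, generate_dataset

logging.getLogger("wgdnet").setLevel(logging.ERROR)


@pytest.fixture
def tiny_net() -> RegulatoryNetwork:
    """a regulates b and c; b regulates c."""
    return RegulatoryNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def seven_edge_anc() -> AncestralNetwork:
    """Small ancestral graph exercising every neighbor relation.

    Contains a 2-cycle (a<->b), a fan-out from a, a fan-in on e and a
    chain to f — 7 edges, enumerable exactly (3^7 spin configurations).
    """
    edges = [("a", "b"), ("b", "a"), ("a", "c"), ("a", "d"),
             ("c", "e"), ("d", "e"), ("e", "f")]
    return AncestralNetwork.trivial(RegulatoryNetwork.from_edges(edges))


@pytest.fixture
def small_dataset():
    """A ground-truthed synthetic dataset at desk scale (no age mixing)."""
    spec = SyntheticSpec(
        n_tf=12, n_target=50, core_backedges=4, age_mix={}, seed=11
    )
    return generate_dataset(spec)


@pytest.fixture
def wgd_pairs_table() -> ParalogTable:
    return ParalogTable.from_records(
        [("a1", "a2", AgeClass.WGD), ("b1", "b2", AgeClass.WGD),
         ("c1", "c2", AgeClass.POST_1)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
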