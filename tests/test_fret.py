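"""Orientation factor, transfer rates and network construction."""

import numpy as np
import pytest

from chlorofret.fret import (
    FretParameters,
    PairExcludedError,
    brute_force_network,
    build_network,
    compare_networks,
    fret_rate,
    kappa_squared,
    mg_distance,
)
from chlorofret.synthetic import random_rotation

from helpers import make_chl


def random_chl(rng, box=40.0, kind="chl_a", site=None):
    return make_chl(rng.uniform(-box, box, 3), rng.normal(size=3), kind=kind, site=site)


def test_mg_distance():
    a = make_chl((0, 0, 0), (0, 0, 1))
    b = make_chl((0, 0, 15), (0, 0, 1), site=("Y", 2, "CLA"))
    assert mg_distance(a, b) == pytest.approx(15.0)
    with pytest.raises(ValueError):
        mg_distance(a, a)


@pytest.mark.parametrize(
    "dipole_d, dipole_a, expected",
    [
        ((0, 0, 1), (0, 0, 1), 1.0),  # parallel dipoles ⊥ separation
        ((1, 0, 0), (1, 0, 0), 4.0),  # collinear head-to-tail
        ((1, 0, 0), (0, 1, 0), 0.0),  # orthogonal, one along R
    ],
)
def test_kappa_squared_reference_geometries(dipole_d, dipole_a, expected):
    d = make_chl((0, 0, 0), dipole_d)
    a = make_chl((10, 0, 0), dipole_a, site=("Y", 2, "CLA"))
    assert kappa_squared(d, a) == pytest.approx(expected, abs=1e-12)


def test_kappa_squared_sign_and_exchange_invariance(rng):
    for _ in range(200):
        d, a = random_chl(rng), random_chl(rng)
        k2 = kappa_squared(d, a)
        assert 0.0 <= k2 <= 4.0
        flipped = make_chl(d.mg, d.nb - d.nd, site=d.site_id)  # dipole sign flip
        assert kappa_squared(flipped, a) == pytest.approx(k2, abs=1e-9)
        assert kappa_squared(a, d) == pytest.approx(k2, abs=1e-9)


def test_kappa_squared_isotropic_average(rng):
    """Over random orientation pairs ⟨κ²⟩ → 2/3 (bounds hold exactly)."""
    vals = np.array(
        [
            kappa_squared(
                make_chl((0, 0, 0), rng.normal(size=3)),
                make_chl((12, 0, 0), rng.normal(size=3), site=("Y", 2, "CLA")),
            )
            for _ in range(10_000)
        ]
    )
    assert vals.min() >= 0.0 and vals.max() <= 4.0
    assert vals.mean() == pytest.approx(2.0 / 3.0, abs=0.03)


def test_fret_rate_hand_arithmetic():
    # κ²=1, R=20 Å (2.0 nm), C=32.26, n=1.55 → 32.26/(5.77200625 · 64)
    d = make_chl((0, 0, 0), (0, 0, 1))
    a = make_chl((20, 0, 0), (0, 0, 1), site=("Y", 2, "CLA"))
    assert kappa_squared(d, a) == pytest.approx(1.0)
    assert fret_rate(d, a) == pytest.approx(32.26 / (5.77200625 * 64), rel=1e-9)


def test_rate_inverse_sixth_power_scaling():
    d = make_chl((0, 0, 0), (0, 0, 1))
    near = make_chl((8, 0, 0), (0, 0, 1), site=("Y", 2, "CLA"))
    far = make_chl((16, 0, 0), (0, 0, 1), site=("Z", 3, "CLA"))
    assert fret_rate(d, near) / fret_rate(d, far) == pytest.approx(64.0, rel=1e-9)


def test_zero_kappa_zero_rate():
    d = make_chl((0, 0, 0), (1, 0, 0))
    a = make_chl((10, 0, 0), (0, 1, 0), site=("Y", 2, "CLA"))
    assert fret_rate(d, a) == 0.0


def test_pair_rule_exclusion_is_explicit():
    d = make_chl((0, 0, 0), (0, 0, 1))
    c = make_chl((10, 0, 0), (0, 0, 1), kind="chl_c", site=("Y", 2, "KC2"))
    with pytest.raises(PairExcludedError):
        fret_rate(d, c)
    # extensible rule: user-supplied constant for the mixed pair
    params = FretParameters(pair_rule="custom", pair_c={frozenset({"chl_a", "chl_c"}): 10.0})
    assert fret_rate(d, c, params) > 0


def test_rate_invariant_under_rigid_transform(rng):
    params = FretParameters()
    for _ in range(50):
        d, a = random_chl(rng), random_chl(rng)
        if mg_distance(d, a) > params.cutoff:
            continue
        rate = fret_rate(d, a, params)
        rot, t = random_rotation(rng), rng.uniform(-30, 30, 3)

        def move(c):
            return make_chl(rot @ c.mg + t, rot @ (c.nd - c.nb), site=c.site_id)

        assert fret_rate(move(d), move(a), params) == pytest.approx(rate, rel=1e-9)


def test_network_cutoff_rules():
    p = FretParameters()
    at = lambda x, site: make_chl((x, 0, 0), (0, 0, 1), site=site)
    assert len(build_network([at(0, ("A", 1, "CLA")), at(19, ("A", 2, "CLA"))], p).edges) == 1
    assert len(build_network([at(0, ("A", 1, "CLA")), at(21, ("A", 2, "CLA"))], p).edges) == 0
    # inclusive boundary
    assert len(build_network([at(0, ("A", 1, "CLA")), at(20, ("A", 2, "CLA"))], p).edges) == 1
    # chl c stays an unconnected node under the default rule
    mixed = [at(0, ("A", 1, "CLA")),
             make_chl((10, 0, 0), (0, 0, 1), kind="chl_c", site=("A", 2, "KC2"))]
    net = build_network(mixed, p)
    assert len(net.edges) == 0 and len(net.nodes) == 2


def test_complete_graph_edge_count(rng):
    """n chl a all mutually within cutoff → n(n−1)/2 edges."""
    chls = [
        make_chl(rng.uniform(-5, 5, 3), rng.normal(size=3), site=("A", i, "CLA"))
        for i in range(12)
    ]
    assert len(build_network(chls).edges) == 12 * 11 // 2


def test_network_equals_brute_force(rng):
    chls = [random_chl(rng, box=35.0, site=("A", i, "CLA")) for i in range(50)]
    fast = build_network(chls)
    slow = brute_force_network(chls)
    assert [e.key for e in fast.edges] == [e.key for e in slow.edges]
    for ef, es in zip(fast.edges, slow.edges):
        assert ef.rate == pytest.approx(es.rate, rel=1e-12)
        assert ef.separation == pytest.approx(es.separation, rel=1e-12)


def test_compare_networks_identity_and_missing_edge():
    chls = [make_chl((12 * i, 0, 0), (0, 0, 1), site=("A", i, "CLA")) for i in range(4)]
    net = build_network(chls)
    ident = {c.site_id: c.site_id for c in chls}
    cmp_same = compare_networks(net, net, ident)
    assert len(cmp_same.matched) == len(net.edges)
    assert all(m.status == "equal" for m in cmp_same.matched)
    # remove one chlorophyll from B: its edges fall into only_in_A
    net_b = build_network(chls[:-1])
    cmp_miss = compare_networks(net, net_b, ident)
    assert len(cmp_miss.only_in_a) == 1
    assert cmp_miss.only_in_a[0].key[1] == ("A", 3, "CLA")


def test_compare_networks_rate_ratio_from_r6_law():
    """Scaling one pair's separation by 2^(1/6) halves its rate."""
    a1 = make_chl((0, 0, 0), (0, 0, 1), site=("A", 1, "CLA"))
    a2 = make_chl((10, 0, 0), (0, 0, 1), site=("A", 2, "CLA"))
    b2 = make_chl((10 * 2 ** (1 / 6), 0, 0), (0, 0, 1), site=("A", 2, "CLA"))
    net_a = build_network([a1, a2])
    net_b = build_network([a1, b2])
    cmp = compare_networks(net_a, net_b, {c.site_id: c.site_id for c in (a1, a2)})
    assert len(cmp.matched) == 1
    assert cmp.matched[0].rate_ratio == pytest.approx(0.5, rel=1e-9)
    assert cmp.matched[0].status == "decreased"


def test_compare_networks_rejects_non_injective():
    a1 = make_chl((0, 0, 0), (0, 0, 1), site=("A", 1, "CLA"))
    a2 = make_chl((10, 0, 0), (0, 0, 1), site=("A", 2, "CLA"))
    net = build_network([a1, a2])
    with pytest.raises(ValueError, match="injective"):
        compare_networks(net, net, {a1.site_id: a1.site_id, a2.site_id: a1.site_id})


def test_network_exports(tmp_path):
    chls = [make_chl((12 * i, 0, 0), (0, 0, 1), site=("A", i, "CLA")) for i in range(3)]
    net = build_network(chls, model_id="toy")
    df = net.to_frame()
    assert list(df["separation_A"]) == pytest.approx([12.0, 12.0])
    net.to_graphml(tmp_path / "n.graphml")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "n.graphml")
    assert g.number_of_edges() == 2
    net.to_adjacency_tsv(tmp_path / "adj.tsv")
    assert (tmp_path / "adj.tsv").read_text().count("\n") == 4  # header + 3 nodes
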