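"""Toy generators, synthetic data round-trips, and the brute-force oracles."""

import numpy as np
import pytest

from relatch import (
    estimate_reference,
    read_expression_table,
    read_mfa_table,
    read_physiology,
)
from relatch.fixtures import (
    TOY_KINDS,
    make_synthetic_reference_data,
    make_toy_network,
    qp_oracle,
)
from relatch.model import load_model


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown toy kind"):
        make_toy_network("moebius")


def test_diamond_topology():
    m = make_toy_network("diamond")
    assert m.n_reactions == 4
    assert m.associations["R1"].enzymes == (frozenset({"gR1"}),)
    assert m.associations["R2"].enzymes == (frozenset({"gR2"}),)


def test_isozyme_split_topology():
    m = make_toy_network("isozyme_split")
    assert m.associations["R"].enzymes == (frozenset({"g1"}), frozenset({"g2"}))


def test_latent_branch_is_inactive_in_the_reference(toy_references):
    ref = toy_references["latent_branch"]
    j_act = ref.active_reactions
    assert "L1" not in j_act and "L2" not in j_act
    n_act = ref.active_enzymes
    assert n_act.get("L1", frozenset()) == frozenset()
    assert n_act.get("L2", frozenset()) == frozenset()


def test_planted_fluxes_satisfy_steady_state(toy_scenarios):
    for kind, sc in toy_scenarios.items():
        w = np.array([sc.planted_w[r] for r in sc.model.reaction_ids])
        np.testing.assert_array_equal(sc.model.S @ w, 0.0)


def test_same_seed_is_bit_identical():
    m = make_toy_network("diamond")
    a = make_synthetic_reference_data(m, seed=7, noise_sigma=0.3)
    b = make_synthetic_reference_data(m, seed=7, noise_sigma=0.3)
    assert [x.value for x in a.mfa] == [x.value for x in b.mfa]
    c = make_synthetic_reference_data(m, seed=8, noise_sigma=0.3)
    assert [x.value for x in a.mfa] != [x.value for x in c.mfa]


@pytest.mark.parametrize("kind", TOY_KINDS)
def test_fixture_tables_round_trip_through_the_readers(kind, tmp_path, toy_scenarios):
    sc = toy_scenarios[kind]
    paths = sc.write(tmp_path / kind)
    model = load_model(paths["model"], dialect="tabular")
    assert model.reaction_ids == sc.model.reaction_ids
    assert model.biomass_id == sc.model.biomass_id
    np.testing.assert_array_equal(model.S, sc.model.S)
    mfa = read_mfa_table(paths["mfa"], model)
    assert [m.value for m in mfa] == [m.value for m in sc.mfa]
    assert [m.mapping for m in mfa] == [m.mapping for m in sc.mfa]
    expr = read_expression_table(paths["expression"])
    assert expr.values == sc.expression.values
    phys = read_physiology(paths["physiology"])
    assert phys.exchanges == sc.physiology.exchanges


def test_noiseless_scenarios_recover_planted_state(toy_scenarios, toy_references):
    for kind, ref in toy_references.items():
        sc = toy_scenarios[kind]
        for rid, w in sc.planted_w.items():
            assert ref.flux[rid] == pytest.approx(w, abs=1e-6), (kind, rid)
        for pair, W in sc.planted_contrib.items():
            assert ref.contributions[pair] == pytest.approx(W, abs=1e-6), (kind, pair)


def test_noisy_estimates_are_unbiased(toy_scenarios):
    """Weighted least squares under zero-mean noise: the mean recovered flux
    over many draws stays within 3 sigma/sqrt(n) of the planted value."""
    sigma, n_seeds = 0.1, 200
    model = make_toy_network("diamond")
    planted = toy_scenarios["diamond"].planted_w
    sums = {r: 0.0 for r in model.reaction_ids}
    for seed in range(n_seeds):
        sc = make_synthetic_reference_data(model, seed=seed, noise_sigma=sigma)
        ref = estimate_reference(sc.model, sc.mfa, sc.expression, sc.physiology)
        assert ref.ok
        for r in model.reaction_ids:
            sums[r] += ref.flux[r]
    tol = 3 * sigma / np.sqrt(n_seeds)
    for r in model.reaction_ids:
        assert sums[r] / n_seeds == pytest.approx(planted[r], abs=tol), r


# -- oracle --------------------------------------------------------------

def test_oracle_proportional_split_closed_form():
    # min W1^2/3 + W2^2 subject to W1 + W2 >= 4, W >= 0  ->  (3, 1), obj 4
    P = np.diag([2 / 3, 2.0])
    x, obj = qp_oracle(P, np.zeros(2), A_ub=[[-1.0, -1.0]], b_ub=[-4.0],
                       lb=[0.0, 0.0])
    np.testing.assert_allclose(x, [3.0, 1.0], atol=1e-8)
    assert obj == pytest.approx(4.0, abs=1e-10)


def test_oracle_unconstrained_quadratic():
    # (f - 1)^2
    x, obj = qp_oracle(np.array([[2.0]]), np.array([-2.0]), const=1.0)
    assert x[0] == pytest.approx(1.0, abs=1e-10)
    assert obj == pytest.approx(0.0, abs=1e-12)


def test_oracle_rejects_non_convex():
    with pytest.raises(ValueError, match="convex"):
        qp_oracle(np.array([[-2.0]]), np.array([0.0]))


def test_oracle_respects_equalities():
    # min x^2 + y^2 s.t. x + y = 2  ->  (1, 1)
    x, obj = qp_oracle(2 * np.eye(2), np.zeros(2), A_eq=[[1.0, 1.0]], b_eq=[2.0])
    np.testing.assert_allclose(x, [1.0, 1.0], atol=1e-10)
    assert obj == pytest.approx(2.0, abs=1e-10)
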