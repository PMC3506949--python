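"""Relative-change prediction: worked examples, parameter laws, FVA."""

import math

import numpy as np
import pytest

from relatch import (
    PerturbationSpec,
    RelatchParams,
    predict,
    prediction_fva,
    select_params,
)
from relatch.fixtures import grid_oracle

KO_R1 = PerturbationSpec(knockouts={"gR1"})


def test_select_params_regimes():
    tight = select_params("non_adapted")
    assert (tight.alpha, tight.gamma) == (10.0, 1.1)
    relaxed = select_params("adapted")
    assert relaxed.alpha == 1.0 and math.isinf(relaxed.gamma)
    override = select_params("non_adapted", alpha=2.5)
    assert override.alpha == 2.5 and override.gamma == 1.1
    with pytest.raises(ValueError):
        select_params("sort_of_adapted")


@pytest.mark.parametrize("alpha,gamma", [(-1.0, 1.1), (1.0, 0.5)])
def test_invalid_params_rejected(alpha, gamma):
    with pytest.raises(ValueError):
        RelatchParams(alpha=alpha, gamma=gamma)


def test_diamond_knockout_tight_hits_the_capacity_cap(diamond):
    """With gamma = 1.1 the rerouted branch is capped at 1.1 x its reference
    contribution of 2, below the unconstrained optimum 70/27."""
    model, _, ref = diamond
    pred = predict(model, ref, KO_R1, select_params("non_adapted"))
    assert pred.ok
    assert pred.flux["R2"] == pytest.approx(2.2, abs=1e-6)
    assert pred.flux["U"] == pytest.approx(2.2, abs=1e-6)
    assert pred.flux["R3"] == pytest.approx(2.2, abs=1e-6)
    assert pred.flux["R1"] == pytest.approx(0.0, abs=1e-9)
    expected_obj = 1.0 + 2 * (1 - 0.22) ** 2 + (1 - 1.1) ** 2
    assert pred.objective == pytest.approx(expected_obj, abs=1e-6)


def test_diamond_knockout_relaxed_reaches_the_stationary_point(diamond):
    model, _, ref = diamond
    pred = predict(model, ref, KO_R1, select_params("adapted"))
    assert pred.flux["R2"] == pytest.approx(70 / 27, abs=1e-6)
    # independent 1-D check: rerouted flux f minimizing the relative changes
    f, _ = grid_oracle(lambda f: 1 + 2 * (1 - f / 10) ** 2 + (1 - f / 2) ** 2, 0, 10)
    assert pred.flux["R2"] == pytest.approx(f, abs=1e-4)


def test_empty_perturbation_returns_the_reference(toy_scenarios, toy_references):
    relaxed = select_params("adapted")
    for kind, ref in toy_references.items():
        model = toy_scenarios[kind].model
        pred = predict(model, ref, PerturbationSpec(), relaxed)
        assert pred.ok
        assert pred.objective == pytest.approx(0.0, abs=1e-8)
        for rid in model.reaction_ids:
            assert pred.flux[rid] == pytest.approx(ref.flux[rid], abs=1e-6), (kind, rid)


def test_knocked_out_enzymes_carry_zero_contribution(diamond):
    model, _, ref = diamond
    pred = predict(model, ref, KO_R1, select_params("non_adapted"))
    assert pred.contributions[("R1", 0)] == 0.0


def test_latent_growth_monotone_in_alpha_and_suppressed_at_high_penalty(
        toy_scenarios, toy_references):
    sc = toy_scenarios["latent_branch"]
    ref = toy_references["latent_branch"]
    spec = PerturbationSpec(knockouts={"g1"})
    growths = []
    for alpha in (0.01, 0.05, 0.1, 0.5, 1.0, 10.0, 1e6):
        pred = predict(sc.model, ref, spec, RelatchParams(alpha=alpha, gamma=math.inf))
        assert pred.ok
        growths.append(pred.growth)
    assert all(a >= b - 1e-6 for a, b in zip(growths, growths[1:]))
    assert growths[-1] < 1e-6
    # closed form for this topology: growth = max(0, 10 (1 - 5 alpha))
    assert growths[1] == pytest.approx(10 * (1 - 5 * 0.05), abs=1e-4)


def test_relative_change_term_monotone_in_gamma(diamond):
    model, _, ref = diamond
    terms = []
    for gamma in (1.0, 1.1, 2.0, math.inf):
        pred = predict(model, ref, KO_R1, RelatchParams(alpha=10.0, gamma=gamma))
        assert pred.ok
        terms.append(pred.relative_change_term)
    assert all(a >= b - 1e-8 for a, b in zip(terms, terms[1:]))


def test_latent_total_monotone_in_alpha(toy_scenarios, toy_references):
    # informative on the latent-branch topology; trivially flat on the
    # diamond (its knockout activates no latent enzymes)
    for kind, ko in [("latent_branch", {"g1"}), ("diamond", {"gR1"})]:
        sc = toy_scenarios[kind]
        ref = toy_references[kind]
        totals = []
        for alpha in (0.1, 1.0, 10.0, 100.0):
            pred = predict(sc.model, ref, PerturbationSpec(knockouts=ko),
                           RelatchParams(alpha=alpha, gamma=math.inf))
            totals.append(pred.latent_term / alpha)  # total latent contribution
        assert all(a >= b - 1e-6 for a, b in zip(totals, totals[1:])), kind


def test_objective_is_nonnegative_and_zero_only_at_reference(diamond):
    model, _, ref = diamond
    pred = predict(model, ref, KO_R1, select_params("adapted"))
    assert pred.objective > 0
    idle = predict(model, ref, PerturbationSpec(), select_params("adapted"))
    assert idle.objective == pytest.approx(0.0, abs=1e-8)


def test_chemostat_growth_equality(toy_scenarios, toy_references):
    sc = toy_scenarios["diamond"]
    ref = toy_references["diamond"]
    pred = predict(sc.model, ref, PerturbationSpec(fixed_growth=0.2),
                   select_params("adapted"))
    assert pred.ok
    assert pred.growth == pytest.approx(0.2, abs=1e-9)


def test_lethal_knockout_reports_zero_growth_not_infeasible(
        toy_scenarios, toy_references):
    sc = toy_scenarios["latent_branch"]
    ref = toy_references["latent_branch"]
    # removing both routes to biomass still admits the all-zero steady state
    pred = predict(sc.model, ref, PerturbationSpec(knockouts={"g1", "g2"}),
                   select_params("non_adapted"))
    assert pred.ok
    assert pred.growth == pytest.approx(0.0, abs=1e-9)


def test_forced_growth_with_lethal_knockout_is_infeasible(
        toy_scenarios, toy_references):
    sc = toy_scenarios["latent_branch"]
    ref = toy_references["latent_branch"]
    pred = predict(sc.model, ref,
                   PerturbationSpec(knockouts={"g1", "g2"}, fixed_growth=5.0),
                   select_params("non_adapted"))
    assert pred.status == "infeasible"


def test_steady_state_and_capacity_hold_in_predictions(diamond):
    model, _, ref = diamond
    for params in (select_params("non_adapted"), select_params("adapted")):
        pred = predict(model, ref, KO_R1, params)
        np.testing.assert_allclose(model.S @ pred.v, 0.0, atol=1e-7)
        sums = {}
        for (rid, _), V in zip(pred.pairs, pred.V):
            assert V >= -1e-9
            sums[rid] = sums.get(rid, 0.0) + V
        for rid, total in sums.items():
            assert abs(pred.flux[rid]) <= total + 1e-7


# -- variability ---------------------------------------------------------

def test_diamond_knockout_prediction_is_determined(diamond):
    model, _, ref = diamond
    params = select_params("non_adapted")
    pred = predict(model, ref, KO_R1, params)
    fva = prediction_fva(model, ref, KO_R1, params, pred)
    for rid, (lo, hi) in fva.items():
        assert hi - lo < 1e-3, rid


def test_latent_duplicated_pair_is_degenerate(toy_scenarios, toy_references):
    """After the main-route knockout, rerouted flux may split arbitrarily
    between the two identical latent reactions: wide ranges there, none
    elsewhere."""
    sc = toy_scenarios["duplicated_path"]
    ref = toy_references["duplicated_path"]
    spec = PerturbationSpec(knockouts={"gm"})
    params = RelatchParams(alpha=0.1, gamma=math.inf)
    pred = predict(sc.model, ref, spec, params)
    assert pred.flux["D1"] + pred.flux["D2"] == pytest.approx(7.5, abs=1e-5)
    fva = prediction_fva(sc.model, ref, spec, params, pred)
    for rid in ("D1", "D2"):
        lo, hi = fva[rid]
        assert lo == pytest.approx(0.0, abs=1e-3)
        assert hi == pytest.approx(7.5, abs=1e-3)
    for rid in ("U", "UX", "Rm", "BM"):
        lo, hi = fva[rid]
        assert hi - lo < 1e-3, rid
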