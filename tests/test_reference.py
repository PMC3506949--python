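"""Reference-state estimation: worked examples, KKT laws, variability."""

import numpy as np
import pandas as pd
import pytest

from relatch import (
    Physiology,
    active_sets,
    estimate_reference,
    make_expression_profile,
    mfa_from_records,
    reference_fva,
)
from relatch.fixtures import grid_oracle, make_toy_network, qp_oracle
from relatch.model import model_from_table
from relatch.reference import build_reference_qp


def _tab(rows):
    return model_from_table(
        pd.DataFrame(rows, columns=["id", "equation", "lower_bound",
                                    "upper_bound", "gpr"]))


def test_consistent_diamond_data_fit_exactly(diamond):
    model, sc, ref = diamond
    expected = {"U": 10.0, "R1": 8.0, "R2": 2.0, "R3": 10.0}
    for rid, w in expected.items():
        assert ref.flux[rid] == pytest.approx(w, abs=1e-6)
    # the MFA term vanishes: the whole objective is the enzyme term
    enzyme_term = sum(W**2 / E for W, E in zip(ref.W, ref.enzyme_expression))
    assert ref.objective == pytest.approx(enzyme_term, abs=1e-6)
    assert ref.contributions[("R1", 0)] == pytest.approx(8.0, abs=1e-6)
    assert ref.contributions[("R2", 0)] == pytest.approx(2.0, abs=1e-6)


def test_isozyme_contributions_follow_proportional_split(toy_scenarios):
    """At fixed |w|, min sum W_n^2/E_n with sum W_n >= |w| gives W_n ~ E_n."""
    sc = toy_scenarios["isozyme_split"]
    ref = estimate_reference(sc.model, sc.mfa, sc.expression, sc.physiology)
    assert ref.flux["R"] == pytest.approx(4.0, abs=1e-8)
    assert ref.contributions[("R", 0)] == pytest.approx(3.0, abs=1e-6)
    assert ref.contributions[("R", 1)] == pytest.approx(1.0, abs=1e-6)
    # cross-check against the exhaustive KKT oracle
    x, obj = qp_oracle(*_qp_of(sc))
    assert ref.objective == pytest.approx(obj, rel=1e-8)


def _qp_of(sc):
    P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, _, _ = build_reference_qp(
        sc.model, sc.mfa, sc.expression, sc.physiology)
    return P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub


def test_inconsistent_chain_measurements_compromise():
    """Conflicting MFA values on a flux-coupled chain meet at the weighted mean."""
    model = _tab([("U", "-> A", 0.0, 20.0, ""),
                  ("R1", "A -> B", 0.0, 100.0, ""),
                  ("R3", "B ->", 0.0, 100.0, "")])
    mfa = mfa_from_records([("r1", "R1", 8.0, 0.1), ("r3", "R3", 6.0, 0.1)], model)
    ref = estimate_reference(model, mfa, make_expression_profile({}), Physiology())
    assert ref.flux["R1"] == pytest.approx(7.0, abs=1e-6)
    assert ref.flux["R3"] == pytest.approx(7.0, abs=1e-6)
    # 1-D independent check: chain flux f minimizing the weighted SSE
    f, obj = grid_oracle(lambda f: ((8 - f) / 0.1) ** 2 + ((6 - f) / 0.1) ** 2, 0, 20)
    assert ref.flux["R1"] == pytest.approx(f, abs=1e-4)
    assert ref.objective == pytest.approx(obj, rel=1e-6)


def test_equal_expression_gives_equal_splits():
    model = _tab([("U", "-> A", 0.0, 6.0, ""),
                  ("R", "A -> B", 0.0, 100.0, "g1 or g2 or g3"),
                  ("X", "B ->", 0.0, 100.0, "")])
    mfa = mfa_from_records([("r", "R", 6.0, 0.1)], model)
    expr = make_expression_profile({"g1": 4.0, "g2": 4.0, "g3": 4.0})
    ref = estimate_reference(model, mfa, expr, Physiology(exchanges={"U": (6.0, 0.0)}))
    for n in range(3):
        assert ref.contributions[("R", n)] == pytest.approx(2.0, abs=1e-6)


def test_removing_measurements_never_raises_the_mfa_term(toy_scenarios):
    """Nested least squares: fewer residuals can only fit better."""
    sc = toy_scenarios["diamond"]
    full = estimate_reference(sc.model, sc.mfa, sc.expression, sc.physiology)

    def mfa_term(ref, mfa):
        flux = ref.flux
        return sum(((m.value - m.evaluate(flux)) / m.ci) ** 2 for m in mfa)

    from relatch.datasets import MFADataset
    subset = MFADataset(sc.mfa.measurements[:2])
    small = estimate_reference(sc.model, subset, sc.expression, sc.physiology)
    assert mfa_term(small, subset) <= mfa_term(full, sc.mfa) + 1e-9


def test_steady_state_and_capacity_invariants(toy_references, toy_scenarios):
    for kind, ref in toy_references.items():
        model = toy_scenarios[kind].model
        np.testing.assert_allclose(model.S @ ref.w, 0.0, atol=1e-7)
        assert np.all(ref.W >= -1e-9)
        sums = {}
        for (rid, _), W in zip(ref.pairs, ref.W):
            sums[rid] = sums.get(rid, 0.0) + W
        for rid, total in sums.items():
            assert abs(ref.flux[rid]) <= total + 1e-7


def test_active_sets_thresholding(diamond):
    _, _, ref = diamond
    j_act, n_act = active_sets(ref, threshold=1e-6)
    assert j_act == {"U", "R1", "R2", "R3"}
    assert n_act["R1"] == {0} and n_act["R2"] == {0}
    # a coarse threshold drops the small branch
    j_act_coarse, _ = active_sets(ref, threshold=5.0)
    assert j_act_coarse == {"U", "R1", "R3"}
    with pytest.raises(ValueError):
        ref.with_threshold(0.0)


def test_infeasible_physiology_is_reported():
    model = _tab([("U", "-> A", 0.0, 10.0, ""), ("X", "A ->", 0.0, 5.0, "")])
    mfa = mfa_from_records([("u", "U", 9.0, 0.1)], model)
    phys = Physiology(exchanges={"U": (9.0, 0.0)})  # X cannot carry 9
    ref = estimate_reference(model, mfa, make_expression_profile({}), phys)
    assert ref.status == "infeasible"


# -- variability ---------------------------------------------------------

def test_fully_determined_diamond_has_no_variability(diamond):
    model, sc, ref = diamond
    fva = reference_fva(model, sc.mfa, sc.expression, sc.physiology, ref)
    for rid, (lo, hi) in fva.items():
        assert hi - lo < 1e-4, rid


def test_duplicated_gpr_free_pair_shares_a_fixed_sum():
    """Only the lumped sum of two identical reactions is measured, so each
    ranges over [0, sum] among alternative optima while the sum is pinned."""
    model = _tab([("U", "-> A", 0.0, 10.0, ""),
                  ("Rm", "A -> B", 0.0, 100.0, ""),
                  ("D1", "A -> B", 0.0, 100.0, ""),
                  ("D2", "A -> B", 0.0, 100.0, ""),
                  ("X", "B ->", 0.0, 100.0, "")])
    mfa = mfa_from_records([("u", "U", 10.0, 0.1), ("rm", "Rm", 8.0, 0.1),
                            ("dup", "D1+D2", 2.0, 0.1)], model)
    phys = Physiology(exchanges={"U": (10.0, 0.0)})
    ref = estimate_reference(model, mfa, make_expression_profile({}), phys)
    fva = reference_fva(model, mfa, make_expression_profile({}), phys, ref)
    for rid in ("D1", "D2"):
        lo, hi = fva[rid]
        assert lo == pytest.approx(0.0, abs=1e-4)
        assert hi == pytest.approx(2.0, abs=1e-4)
    lo, hi = fva["Rm"]
    assert hi - lo < 1e-4
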