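"""FBA, MOMA, and ROOM comparators over a shared reference state.

These are the standard alternatives the relative-change predictor is
evaluated against.  All three receive the same perturbation handling: a
gene knockout removes a reaction only when *every* enzyme in its GPR is
disabled (the comparators have no notion of partial isozyme loss), and
medium edits / fixed growth are applied as bound edits.

* FBA maximizes biomass flux; ties among alternate optima are resolved by
  a secondary minimization of sum(v^2) at the fixed optimal growth so the
  reported flux vector is deterministic.
* MOMA minimizes the Euclidean distance sum_j (w_j - v_j)^2 to the
  reference fluxes over all reactions.
* ROOM minimizes the number of significant flux changes: a MILP with one
  binary per reaction, where reaction j is "unchanged" when
  v_j lies in [w_j - delta |w_j| - eps, w_j + delta |w_j| + eps]
  (delta = 0.03, eps = 0.001 by default, the thresholds published with
  the method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .gpr import apply_knockout
from .model import MetabolicModel, PerturbationSpec, apply_environment
from .qp import solve_lp, solve_qp
from .reference import ReferenceState

ROOM_DELTA = 0.03
ROOM_EPSILON = 0.001


@dataclass(frozen=True)
class ComparatorResult:
    method: str
    reaction_ids: tuple[str, ...]
    v: np.ndarray
    objective: float
    status: str
    growth: float | None
    extra: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    @property
    def flux(self) -> dict[str, float]:
        return {r: float(x) for r, x in zip(self.reaction_ids, self.v)}


def perturbed_model(model: MetabolicModel, spec: PerturbationSpec) -> MetabolicModel:
    """Apply medium edits, fixed growth, and reaction-level knockouts."""
    out = apply_environment(model, spec)
    if spec.knockouts:
        assoc = apply_knockout(model.associations, set(spec.knockouts),
                               known_genes=set(model.genes))
        for rid, a in assoc.items():
            if a.is_dead():
                out = out.with_bounds(rid, 0.0, 0.0)
    return out


def fba(model: MetabolicModel, spec: PerturbationSpec | None = None,
        objective_id: str | None = None) -> ComparatorResult:
    """Flux balance analysis: maximize biomass under steady state and bounds."""
    spec = spec or PerturbationSpec()
    pm = perturbed_model(model, spec)
    target = objective_id or model.biomass_id
    if target is None:
        raise ValueError("FBA needs a biomass/objective reaction id")
    n = pm.n_reactions
    c = np.zeros(n)
    c[pm.reaction_index[target]] = 1.0
    lp = solve_lp(c, A_eq=pm.S, b_eq=np.zeros(pm.S.shape[0]),
                  lb=pm.lower_bounds, ub=pm.upper_bounds, maximize=True)
    if not lp.ok:
        return ComparatorResult("FBA", pm.reaction_ids, lp.x, lp.objective,
                                lp.status, None)
    # deterministic tie-break: minimum-norm flux vector at the optimum
    A_eq = np.vstack([pm.S, c])
    b_eq = np.concatenate([np.zeros(pm.S.shape[0]), [lp.objective]])
    qp = solve_qp(2.0 * np.eye(n), np.zeros(n), 0.0, A_eq, b_eq,
                  lb=pm.lower_bounds, ub=pm.upper_bounds, x0=lp.x)
    v = qp.x if qp.ok else lp.x
    return ComparatorResult(
        "FBA", pm.reaction_ids, v, float(lp.objective), "optimal",
        float(v[pm.reaction_index[target]]),
        extra={"tie_break": "min sum v^2 at fixed optimum"},
    )


def moma(model: MetabolicModel, ref: ReferenceState,
         spec: PerturbationSpec | None = None) -> ComparatorResult:
    """Minimization of metabolic adjustment from the reference fluxes."""
    spec = spec or PerturbationSpec()
    pm = perturbed_model(model, spec)
    w = np.asarray([ref.flux[r] for r in pm.reaction_ids])
    n = pm.n_reactions
    qp = solve_qp(
        2.0 * np.eye(n), -2.0 * w, float(w @ w),
        A_eq=pm.S, b_eq=np.zeros(pm.S.shape[0]),
        lb=pm.lower_bounds, ub=pm.upper_bounds, x0=np.clip(w, pm.lower_bounds, pm.upper_bounds),
    )
    growth = (float(qp.x[pm.reaction_index[pm.biomass_id]])
              if pm.biomass_id and qp.ok else None)
    return ComparatorResult("MOMA", pm.reaction_ids, qp.x, qp.objective,
                            qp.status, growth)


def room(model: MetabolicModel, ref: ReferenceState,
         spec: PerturbationSpec | None = None,
         delta: float = ROOM_DELTA, epsilon: float = ROOM_EPSILON,
         time_limit: float | None = None) -> ComparatorResult:
    """Regulatory on/off minimization: fewest significant flux changes.

    MILP formulation with binary y_j = 1 when reaction j leaves its
    tolerance window around the reference flux.  Windows falling entirely
    outside the (possibly knocked-out) bounds force y_j = 1.
    """
    spec = spec or PerturbationSpec()
    pm = perturbed_model(model, spec)
    w = np.asarray([ref.flux[r] for r in pm.reaction_ids])
    n = pm.n_reactions
    lbs, ubs = pm.lower_bounds, pm.upper_bounds

    w_hi = np.minimum(w + delta * np.abs(w) + epsilon, ubs)
    w_lo = np.maximum(w - delta * np.abs(w) - epsilon, lbs)
    forced = w_lo > w_hi  # window incompatible with the bounds

    # variables: [v (n), y (n binary)]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    constraints = [LinearConstraint(
        np.hstack([pm.S, np.zeros((pm.S.shape[0], n))]), 0.0, 0.0)]
    rows, lo_r, hi_r = [], [], []
    for j in range(n):
        if forced[j]:
            continue
        # v_j - (ub_j - w_hi_j) y_j <= w_hi_j
        row = np.zeros(2 * n)
        row[j] = 1.0
        row[n + j] = -(ubs[j] - w_hi[j])
        rows.append(row); lo_r.append(-np.inf); hi_r.append(w_hi[j])
        # v_j + (w_lo_j - lb_j) y_j >= w_lo_j
        row = np.zeros(2 * n)
        row[j] = 1.0
        row[n + j] = w_lo[j] - lbs[j]
        rows.append(row); lo_r.append(w_lo[j]); hi_r.append(np.inf)
    if rows:
        constraints.append(LinearConstraint(np.vstack(rows), lo_r, hi_r))

    y_lb = np.where(forced, 1.0, 0.0)
    bounds = Bounds(np.concatenate([lbs, y_lb]),
                    np.concatenate([ubs, np.ones(n)]))
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    options = {"time_limit": time_limit} if time_limit else {}
    res = milp(c=c, constraints=constraints, bounds=bounds,
               integrality=integrality, options=options)
    if res.status == 2:
        return ComparatorResult("ROOM", pm.reaction_ids, np.full(n, np.nan),
                                np.nan, "infeasible", None)
    if res.x is None:
        return ComparatorResult("ROOM", pm.reaction_ids, np.full(n, np.nan),
                                np.nan, "failed", None, extra={"message": res.message})
    v = np.asarray(res.x[:n])
    y = np.round(res.x[n:]).astype(int)
    status = "optimal" if res.status == 0 else "feasible"
    growth = float(v[pm.reaction_index[pm.biomass_id]]) if pm.biomass_id else None
    return ComparatorResult(
        "ROOM", pm.reaction_ids, v, float(np.sum(y)), status, growth,
        extra={"y": y, "delta": delta, "epsilon": epsilon,
               "mip_gap": getattr(res, "mip_gap", None)},
    )
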