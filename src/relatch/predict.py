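"""Perturbed-state flux prediction by relative-change minimization.

Given a solved reference state (fluxes ``w``, contributions ``W``, active
sets J_act / N_act), the perturbed flux distribution ``v`` and perturbed
contributions ``V`` are predicted by the convex program

    minimize   sum_{j in J_act} ((w_j - v_j) / w_j)^2
             + alpha * sum_{j in J_GPR} sum_{n not in N_act(j)} V_{j,n}

    subject to S v = 0, model bounds (after medium edits)
               -sum_n V_{j,n} <= v_j <= sum_n V_{j,n}   for j in J_GPR
               V_{j,n} <= gamma * W_{j,n}   for n in N_act(j)  (gamma finite)
               V >= 0;  V_{j,n} = 0 for enzymes disabled by the knockout

The first term preserves the relative flux pattern of the reference; the
second penalizes activating latent pathways (enzymes inactive in the
reference) at rate ``alpha`` per unit of contribution.  ``gamma`` caps how
much an already-active enzyme's contribution may grow; at gamma = infinity
the cap is omitted entirely.  Exchange fluxes are never fixed to measured
perturbed values — they are predicted — except for a chemostat growth rate
known a priori, which is imposed as an equality on biomass.

Two published parameter regimes are provided: tight (alpha = 10,
gamma = 1.1) for perturbations the cells are not adapted to, and relaxed
(alpha = 1, gamma = infinity) for adapted conditions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .gpr import apply_knockout
from .model import MetabolicModel, PerturbationSpec, apply_environment
from .qp import optimize_linear_under_quadratic_cap, solve_qp
from .reference import DEFAULT_ACTIVITY_THRESHOLD, ReferenceState

TIGHT = {"alpha": 10.0, "gamma": 1.1}
RELAXED = {"alpha": 1.0, "gamma": math.inf}


@dataclass(frozen=True)
class RelatchParams:
    """Latent-activation penalty and active-enzyme capacity limit.

    alpha >= 0 is dimensionless per mmol/gDW/h of latent contribution;
    gamma >= 1 (or infinite) multiplies the reference contribution of each
    active enzyme to cap its perturbed contribution.
    """

    alpha: float
    gamma: float
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not (self.gamma >= 1.0):
            raise ValueError("gamma must be >= 1 or infinite")
        if self.threshold <= 0:
            raise ValueError("activity threshold must be positive")


def select_params(adapted: str, **overrides) -> RelatchParams:
    """Published parameter regimes by adaptation status.

    ``"non_adapted"`` (recent knockouts, unfamiliar media) gives the tight
    regime alpha=10, gamma=1.1; ``"adapted"`` (evolved strains, familiar
    conditions, chemostat) gives the relaxed regime alpha=1, gamma=inf.
    Keyword overrides replace individual fields.
    """
    if adapted == "non_adapted":
        base = RelatchParams(**TIGHT)
    elif adapted == "adapted":
        base = RelatchParams(**RELAXED)
    else:
        raise ValueError(f"adapted must be 'adapted' or 'non_adapted', got {adapted!r}")
    return _dc_replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class FluxPrediction:
    """Predicted perturbed-state fluxes and enzyme contributions."""

    reaction_ids: tuple[str, ...]
    v: np.ndarray
    pairs: tuple[tuple[str, int], ...]
    V: np.ndarray
    objective: float
    relative_change_term: float
    latent_term: float
    status: str
    growth: float | None
    params: RelatchParams

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    @property
    def flux(self) -> dict[str, float]:
        return {r: float(x) for r, x in zip(self.reaction_ids, self.v)}

    @property
    def contributions(self) -> dict[tuple[str, int], float]:
        return {p: float(x) for p, x in zip(self.pairs, self.V)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "reaction_ids": list(self.reaction_ids),
                "v": [float(x) for x in self.v],
                "pairs": [[r, n] for r, n in self.pairs],
                "V": [float(x) for x in self.V],
                "objective": self.objective,
                "relative_change_term": self.relative_change_term,
                "latent_term": self.latent_term,
                "status": self.status,
                "growth": self.growth,
                "params": {"alpha": self.params.alpha,
                           "gamma": None if math.isinf(self.params.gamma) else self.params.gamma,
                           "threshold": self.params.threshold},
            },
            indent=1,
        )


def build_prediction_qp(
    model: MetabolicModel,
    ref: ReferenceState,
    spec: PerturbationSpec,
    params: RelatchParams,
):
    """Assemble the prediction QP; returns canonical matrices plus metadata.

    Variable order: reaction fluxes v, then contributions V per
    (reaction, enzyme) pair (same pair order as the reference state).
    """
    if tuple(ref.reaction_ids) != tuple(model.reaction_ids):
        raise ValueError("reference state does not match the model's reactions")

    pmodel = apply_environment(model, spec)
    assoc = apply_knockout(model.associations, set(spec.knockouts),
                           known_genes=set(model.genes))

    n_r = model.n_reactions
    idx = model.reaction_index
    pairs = model.enzyme_pairs
    n_p = len(pairs)
    n = n_r + n_p

    ref_state = ref.with_threshold(params.threshold)
    j_act = ref_state.active_reactions
    n_act = ref_state.active_enzymes
    w = dict(zip(ref.reaction_ids, ref.w))
    W = dict(zip(ref.pairs, ref.W))

    P = np.zeros((n, n))
    q = np.zeros(n)
    const = 0.0
    for rid in j_act:
        j = idx[rid]
        P[j, j] += 2.0 / w[rid] ** 2
        q[j] += -2.0 / w[rid]
        const += 1.0

    latent_mask = np.zeros(n_p, dtype=bool)
    zeroed_mask = np.zeros(n_p, dtype=bool)
    for k, (rid, nz) in enumerate(pairs):
        zeroed_mask[k] = assoc[rid].zeroed[nz]
        latent_mask[k] = nz not in n_act.get(rid, frozenset())
    q[n_r:][latent_mask] += params.alpha

    A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], n_p))])
    b_eq = np.zeros(model.S.shape[0])

    pair_cols: dict[str, list[int]] = {}
    for k, (rid, _) in enumerate(pairs):
        pair_cols.setdefault(rid, []).append(n_r + k)
    rows, rhs = [], []
    for rid, cols in pair_cols.items():
        for sgn in (1.0, -1.0):
            row = np.zeros(n)
            row[idx[rid]] = sgn
            row[cols] = -1.0
            rows.append(row)
            rhs.append(0.0)
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.asarray(rhs) if rows else None

    lb = np.concatenate([pmodel.lower_bounds, np.zeros(n_p)])
    ub = np.concatenate([pmodel.upper_bounds, np.full(n_p, np.inf)])
    for k, (rid, nz) in enumerate(pairs):
        if zeroed_mask[k]:
            ub[n_r + k] = 0.0  # knocked-out enzyme carries no contribution
        elif np.isfinite(params.gamma) and nz in n_act.get(rid, frozenset()):
            ub[n_r + k] = params.gamma * W[(rid, nz)]  # contribution cap

    meta = {"pairs": pairs, "j_act": j_act, "latent_mask": latent_mask,
            "zeroed_mask": zeroed_mask, "w": w}
    return P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, meta


def _split_terms(x, P, q, const, n_r, latent_mask, alpha):
    rel = float(0.5 * x[:n_r] @ P[:n_r, :n_r] @ x[:n_r] + q[:n_r] @ x[:n_r] + const)
    latent = float(alpha * np.sum(x[n_r:][latent_mask]))
    return rel, latent


def predict(
    model: MetabolicModel,
    ref: ReferenceState,
    spec: PerturbationSpec,
    params: RelatchParams,
) -> FluxPrediction:
    """Predict the perturbed-state flux distribution.

    On an infeasible constraint set the status is ``"infeasible"``; when
    only a fixed growth rate blocks feasibility (the network admits a
    steady state at lower growth) the message distinguishes the two, and a
    lethal knockout without a growth constraint reports growth 0 rather
    than infeasibility.
    """
    P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, meta = build_prediction_qp(
        model, ref, spec, params
    )
    n_r = model.n_reactions
    x0 = _warm_start(model, ref, lb, ub)
    res = solve_qp(P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, x0=x0)

    status = res.status
    message = res.message
    if status == "infeasible" and spec.fixed_growth is not None and model.biomass_id:
        # diagnose: is the set feasible once the growth equality is dropped?
        j = model.reaction_index[model.biomass_id]
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[j], ub2[j] = 0.0, spec.fixed_growth
        from .qp import find_feasible_point

        if find_feasible_point(len(q), A_eq, b_eq, A_ub, b_ub, lb2, ub2) is not None:
            message = ("infeasible at the fixed growth rate; the network is "
                       "feasible at lower growth (zero-growth diagnosis)")

    if status == "optimal":
        # knocked-out enzymes are constrained to [0, 0]; snap any numerical
        # residue so they carry exactly zero contribution
        res.x[n_r:][meta["zeroed_mask"]] = 0.0
        rel, latent = _split_terms(res.x, P, q, const, n_r, meta["latent_mask"],
                                   params.alpha)
        growth = (float(res.x[model.reaction_index[model.biomass_id]])
                  if model.biomass_id else None)
    else:
        rel = latent = float("nan")
        growth = None
    return FluxPrediction(
        reaction_ids=model.reaction_ids,
        v=res.x[:n_r],
        pairs=meta["pairs"],
        V=res.x[n_r:],
        objective=res.objective,
        relative_change_term=rel,
        latent_term=latent,
        status=status,
        growth=growth,
        params=params,
    )


def _warm_start(model, ref, lb, ub):
    """Feasible-ish start near the reference solution."""
    n_r = model.n_reactions
    x0 = np.concatenate([ref.w, ref.W])
    return np.clip(x0, lb, ub)


def prediction_fva(
    model: MetabolicModel,
    ref: ReferenceState,
    spec: PerturbationSpec,
    params: RelatchParams,
    pred: FluxPrediction,
    objective_tol: float = 1e-9,
    reactions: tuple[str, ...] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux ranges among alternative prediction optima at the fixed objective."""
    if not pred.ok:
        raise ValueError("prediction was not solved to optimality")
    P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, _ = build_prediction_qp(
        model, ref, spec, params
    )
    cap = pred.objective * (1.0 + objective_tol) + 1e-9
    x0 = np.concatenate([pred.v, pred.V])
    idx = model.reaction_index
    out: dict[str, tuple[float, float]] = {}
    for rid in reactions or model.reaction_ids:
        c = np.zeros(len(q))
        c[idx[rid]] = 1.0
        lo = optimize_linear_under_quadratic_cap(
            c, P, q, const, cap, A_eq, b_eq, A_ub, b_ub, lb, ub, x0=x0)
        hi = optimize_linear_under_quadratic_cap(
            c, P, q, const, cap, A_eq, b_eq, A_ub, b_ub, lb, ub, x0=x0, maximize=True)
        if lo.ok and hi.ok:
            out[rid] = (min(lo.objective, pred.v[idx[rid]]),
                        max(hi.objective, pred.v[idx[rid]]))
    return out
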