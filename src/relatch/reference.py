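"""Reference-state estimation: fluxes and per-isozyme enzyme contributions.

The reference state of a strain is estimated from three data sources: MFA
flux measurements with confidence intervals, gene expression, and
physiological rates.  The estimator solves one convex QP over the flux
vector ``w`` and nonnegative per-(reaction, enzyme) contributions ``W``:

    minimize   sum_m ((w_exp_m - map_m(w)) / w_conf_m)^2
             + sum_{j in J_GPR} sum_{n in N(j)} W_{j,n}^2 / E_n

    subject to S w = 0                         (steady state)
               lb <= w <= ub                   (model bounds)
               -sum_n W_{j,n} <= w_j <= sum_n W_{j,n}   for j in J_GPR
               W >= 0
               physiology intervals on exchanges / growth

The first term pulls mapped fluxes toward the MFA estimates, weighted by
the reciprocal confidence half-widths; the second spreads each reaction's
capacity across its isozymes in proportion to their expression (at a fixed
|w_j| the optimum is the proportional split W_n = |w_j| E_n / sum E).
Physiological measurements enter as hard intervals [value - ci, value + ci]
intersected with the model bounds; a chemostat dilution rate is an equality
on the biomass flux.

Active sets derived from the solution drive the perturbed-state
prediction: J_act collects reactions with |w_j| above a small threshold,
N_act(j) the enzymes with contribution above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .datasets import ExpressionProfile, MFADataset, Physiology, enzyme_expression
from .model import MetabolicModel
from .qp import optimize_linear_under_quadratic_cap, solve_qp

DEFAULT_ACTIVITY_THRESHOLD = 1e-6  # mmol/gDW/h, solver-noise scale
DEFAULT_FVA_OBJECTIVE_TOL = 1e-9   # relative slack on the fixed optimum


@dataclass(frozen=True)
class ReferenceState:
    """Estimated reference fluxes and enzyme contributions."""

    reaction_ids: tuple[str, ...]
    w: np.ndarray
    pairs: tuple[tuple[str, int], ...]  # (reaction id, enzyme index)
    W: np.ndarray
    enzyme_expression: np.ndarray  # E_n per pair, same order
    objective: float
    status: str
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    @property
    def flux(self) -> dict[str, float]:
        return {r: float(v) for r, v in zip(self.reaction_ids, self.w)}

    @property
    def contributions(self) -> dict[tuple[str, int], float]:
        return {p: float(v) for p, v in zip(self.pairs, self.W)}

    @property
    def active_reactions(self) -> frozenset[str]:
        """J_act: reactions with |w_j| above the activity threshold."""
        return frozenset(
            r for r, v in zip(self.reaction_ids, self.w) if abs(v) > self.threshold
        )

    @property
    def active_enzymes(self) -> dict[str, frozenset[int]]:
        """N_act(j): enzyme indices with contribution above the threshold."""
        out: dict[str, set[int]] = {}
        for (rid, n), val in zip(self.pairs, self.W):
            out.setdefault(rid, set())
            if val > self.threshold:
                out[rid].add(n)
        return {r: frozenset(s) for r, s in out.items()}

    def with_threshold(self, threshold: float) -> "ReferenceState":
        if threshold <= 0:
            raise ValueError("activity threshold must be positive")
        return replace(self, threshold=threshold)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "reaction_ids": list(self.reaction_ids),
                "w": [float(x) for x in self.w],
                "pairs": [[r, n] for r, n in self.pairs],
                "W": [float(x) for x in self.W],
                "enzyme_expression": [float(x) for x in self.enzyme_expression],
                "objective": self.objective,
                "status": self.status,
                "threshold": self.threshold,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceState":
        d = json.loads(text)
        return cls(
            reaction_ids=tuple(d["reaction_ids"]),
            w=np.asarray(d["w"], float),
            pairs=tuple((r, int(n)) for r, n in d["pairs"]),
            W=np.asarray(d["W"], float),
            enzyme_expression=np.asarray(d["enzyme_expression"], float),
            objective=float(d["objective"]),
            status=d["status"],
            threshold=float(d["threshold"]),
        )


def active_sets(ref: ReferenceState, threshold: float | None = None):
    """Deterministic thresholding into (J_act, N_act).

    Returns the active reaction set and the per-reaction active enzyme
    index sets at ``threshold`` (defaults to the threshold recorded on the
    state).
    """
    if threshold is not None:
        ref = ref.with_threshold(threshold)
    return ref.active_reactions, ref.active_enzymes


def build_reference_qp(
    model: MetabolicModel,
    mfa: MFADataset,
    expr: ExpressionProfile,
    phys: Physiology,
):
    """Assemble the reference QP in canonical matrix form.

    Returns (P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, pairs, E).
    Variable order: all reaction fluxes, then one contribution per
    (reaction, enzyme) pair in model order.
    """
    n_r = model.n_reactions
    idx = model.reaction_index
    pairs = model.enzyme_pairs
    n_p = len(pairs)
    n = n_r + n_p

    # expression weights per pair
    E = np.empty(n_p)
    per_rxn = {
        rid: enzyme_expression(expr, model.associations[rid])
        for rid in model.gpr_reactions
    }
    for k, (rid, nz) in enumerate(pairs):
        E[k] = per_rxn[rid][nz]

    # objective
    P = np.zeros((n, n))
    q = np.zeros(n)
    const = 0.0
    for meas in mfa:
        c = np.zeros(n_r)
        for rid, coef in meas.mapping.items():
            c[idx[rid]] += coef
        wgt = 1.0 / meas.ci**2
        P[:n_r, :n_r] += 2.0 * wgt * np.outer(c, c)
        q[:n_r] += -2.0 * wgt * meas.value * c
        const += wgt * meas.value**2
    P[n_r:, n_r:] = np.diag(2.0 / E)

    # steady state
    A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], n_p))])
    b_eq = np.zeros(model.S.shape[0])

    # enzyme-capacity coupling: +-w_j <= sum_n W_{j,n}
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

    # bounds: model bounds intersected with physiology intervals
    lb = np.concatenate([model.lower_bounds, np.zeros(n_p)])
    ub = np.concatenate([model.upper_bounds, np.full(n_p, np.inf)])
    exchanges = model.exchange_ids
    for rid, (val, ci) in phys.exchanges.items():
        if rid not in idx:
            raise KeyError(f"physiology refers to unknown reaction {rid!r}")
        if rid not in exchanges:
            raise ValueError(f"physiology measurement on non-exchange reaction {rid!r}")
        j = idx[rid]
        lb[j] = max(lb[j], val - ci)
        ub[j] = min(ub[j], val + ci)
    if phys.growth is not None or phys.dilution_rate is not None:
        if model.biomass_id is None:
            raise ValueError("growth/dilution measurement but model has no biomass reaction")
        j = idx[model.biomass_id]
        if phys.dilution_rate is not None:
            lb[j] = ub[j] = phys.dilution_rate
        else:
            val, ci = phys.growth
            lb[j] = max(lb[j], val - ci)
            ub[j] = min(ub[j], val + ci)

    return P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, pairs, E


def estimate_reference(
    model: MetabolicModel,
    mfa: MFADataset,
    expr: ExpressionProfile,
    phys: Physiology,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> ReferenceState:
    """Estimate the reference flux distribution and enzyme contributions.

    Returns a :class:`ReferenceState`; ``status`` is ``"infeasible"`` when
    the model bounds, steady state and physiology intervals admit no flux
    vector (fluxes are NaN in that case).
    """
    P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, pairs, E = build_reference_qp(
        model, mfa, expr, phys
    )
    res = solve_qp(P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub)
    n_r = model.n_reactions
    return ReferenceState(
        reaction_ids=model.reaction_ids,
        w=res.x[:n_r],
        pairs=pairs,
        W=res.x[n_r:],
        enzyme_expression=E,
        objective=res.objective,
        status=res.status,
        threshold=threshold,
    )


def reference_fva(
    model: MetabolicModel,
    mfa: MFADataset,
    expr: ExpressionProfile,
    phys: Physiology,
    ref: ReferenceState,
    objective_tol: float = DEFAULT_FVA_OBJECTIVE_TOL,
    reactions: tuple[str, ...] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux ranges among alternative reference optima.

    Minimizes and maximizes each flux while the reference objective is held
    at its optimum (relative slack ``objective_tol``); the range width
    measures how much the data leave that flux undetermined.
    """
    if not ref.ok:
        raise ValueError("reference state was not solved to optimality")
    P, q, const, A_eq, b_eq, A_ub, b_ub, lb, ub, pairs, _ = build_reference_qp(
        model, mfa, expr, phys
    )
    cap = ref.objective * (1.0 + objective_tol) + 1e-9
    x0 = np.concatenate([ref.w, ref.W])
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
            out[rid] = (min(lo.objective, ref.w[idx[rid]]),
                        max(hi.objective, ref.w[idx[rid]]))
    return out
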