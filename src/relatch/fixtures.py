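"""Toy networks, synthetic reference datasets, and brute-force oracles.

Every solver-backed operation in the package is testable without external
downloads: this module builds 4–8 reaction networks with known ground
truth, emits the standard TSV inputs for them, and provides exhaustive
optimization oracles (active-set/KKT enumeration for convex QPs, vertex
enumeration for LPs, on/off-pattern enumeration for the significant-change
MILP) that are independent of the iterative solvers used by the package.

Toy topologies
--------------
``chain``
    U -> A -> B -> C -> export; one gene per internal reaction.
``diamond``
    Two parallel routes A -> B with distinct single-gene enzymes; the
    canonical worked example splits flux 8/2 between them.
``latent_branch``
    A main route plus a latent bypass requiring a co-substrate whose
    uptake the reference physiology pins to zero, so the bypass carries
    exactly zero reference flux; after the main-route knockout it is the
    only path to biomass.
``isozyme_split``
    One internal reaction catalyzed by two isozymes ("g1 or g2"), used for
    the proportional-split law.
``duplicated_path``
    A latent *pair* of identical bypass reactions; after the main-route
    knockout any split of rerouted flux between the two is optimal, giving
    genuinely degenerate alternative optima for variability analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    ExpressionProfile,
    MFADataset,
    Physiology,
    make_expression_profile,
    mfa_from_records,
)
from .model import MetabolicModel, model_from_table

TOY_KINDS = ("chain", "diamond", "latent_branch", "isozyme_split", "duplicated_path")

_TOY_TABLES = {
    "chain": [
        ("U", "-> A", 0.0, 10.0, ""),
        ("R1", "A -> B", -100.0, 100.0, "g1"),
        ("R2", "B -> C", -100.0, 100.0, "g2"),
        ("X", "C ->", 0.0, 100.0, ""),
    ],
    "diamond": [
        ("U", "-> A", 0.0, 10.0, ""),
        ("R1", "A -> B", 0.0, 100.0, "gR1"),
        ("R2", "A -> B", 0.0, 100.0, "gR2"),
        ("R3", "B ->", 0.0, 100.0, ""),
    ],
    "latent_branch": [
        ("U", "-> A", 0.0, 10.0, ""),
        ("UX", "-> X", 0.0, 10.0, ""),
        ("R1", "A -> B", 0.0, 100.0, "g1"),
        ("L1", "A + X -> C", 0.0, 100.0, "g2"),
        ("L2", "C -> B", 0.0, 100.0, "g3"),
        ("BM", "B ->", 0.0, 100.0, ""),
    ],
    "isozyme_split": [
        ("U", "-> A", 0.0, 4.0, ""),
        ("R", "A -> B", 0.0, 100.0, "g1 or g2"),
        ("X", "B ->", 0.0, 100.0, ""),
    ],
    "duplicated_path": [
        ("U", "-> A", 0.0, 10.0, ""),
        ("UX", "-> X", 0.0, 10.0, ""),
        ("Rm", "A -> B", 0.0, 100.0, "gm"),
        ("D1", "A + X -> B", 0.0, 100.0, "gd1"),
        ("D2", "A + X -> B", 0.0, 100.0, "gd2"),
        ("BM", "B ->", 0.0, 100.0, ""),
    ],
}

_BIOMASS = {"chain": "X", "diamond": "R3", "latent_branch": "BM",
            "isozyme_split": "X", "duplicated_path": "BM"}

#: planted steady-state reference fluxes per topology (mmol/gDW/h)
_PLANTED_W = {
    "chain": {"U": 10.0, "R1": 10.0, "R2": 10.0, "X": 10.0},
    "diamond": {"U": 10.0, "R1": 8.0, "R2": 2.0, "R3": 10.0},
    "latent_branch": {"U": 10.0, "UX": 0.0, "R1": 10.0, "L1": 0.0,
                      "L2": 0.0, "BM": 10.0},
    "isozyme_split": {"U": 4.0, "R": 4.0, "X": 4.0},
    "duplicated_path": {"U": 10.0, "UX": 0.0, "Rm": 10.0, "D1": 0.0,
                        "D2": 0.0, "BM": 10.0},
}

#: planted per-(reaction, enzyme-index) contributions
_PLANTED_CONTRIB = {
    "chain": {("R1", 0): 10.0, ("R2", 0): 10.0},
    "diamond": {("R1", 0): 8.0, ("R2", 0): 2.0},
    "latent_branch": {("R1", 0): 10.0, ("L1", 0): 0.0, ("L2", 0): 0.0},
    "isozyme_split": {("R", 0): 3.0, ("R", 1): 1.0},
    "duplicated_path": {("Rm", 0): 10.0, ("D1", 0): 0.0, ("D2", 0): 0.0},
}

#: gene expression consistent with the planted contributions (latent
#: enzymes get a small positive value so reciprocal weights stay finite)
_PLANTED_EXPR = {
    "chain": {"g1": 10.0, "g2": 10.0},
    "diamond": {"gR1": 8.0, "gR2": 2.0},
    "latent_branch": {"g1": 10.0, "g2": 0.5, "g3": 0.5},
    "isozyme_split": {"g1": 3.0, "g2": 1.0},
    "duplicated_path": {"gm": 10.0, "gd1": 0.5, "gd2": 0.5},
}

#: exchanges pinned by the reference physiology (half-width 0)
_PINNED_EXCHANGES = {
    "chain": {"U": 10.0},
    "diamond": {"U": 10.0},
    "latent_branch": {"U": 10.0, "UX": 0.0},
    "isozyme_split": {"U": 4.0},
    "duplicated_path": {"U": 10.0, "UX": 0.0},
}

MFA_CONFIDENCE = 0.1  # default half-width, mmol/gDW/h


def make_toy_network(kind: str) -> MetabolicModel:
    """Construct one of the named toy topologies (see module docstring)."""
    if kind not in _TOY_TABLES:
        raise ValueError(f"unknown toy kind {kind!r}; choose from {TOY_KINDS}")
    df = pd.DataFrame(
        _TOY_TABLES[kind],
        columns=["id", "equation", "lower_bound", "upper_bound", "gpr"],
    )
    return model_from_table(df, biomass_id=_BIOMASS[kind], name=kind)


@dataclass(frozen=True)
class ToyScenario:
    """A toy model plus synthetic data with known ground truth."""

    model: MetabolicModel
    planted_w: dict[str, float]
    planted_contrib: dict[tuple[str, int], float]
    mfa: MFADataset
    expression: ExpressionProfile
    physiology: Physiology
    seed: int
    noise_sigma: float

    def write(self, directory) -> dict[str, Path]:
        """Serialize model and data tables as TSV files; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}

        rows = [
            (*row, 1 if row[0] == self.model.biomass_id else 0)
            for row in _TOY_TABLES[self.model.name]
        ]
        paths["model"] = directory / "model.tsv"
        pd.DataFrame(rows, columns=["id", "equation", "lower_bound",
                                    "upper_bound", "gpr", "objective"]).to_csv(
            paths["model"], sep="\t", index=False)

        paths["mfa"] = directory / "mfa.tsv"
        pd.DataFrame(
            [(m.measurement_id,
              "+".join(f"{c}*{r}" if c != 1.0 else r
                       for r, c in m.mapping.items()),
              m.value, m.ci) for m in self.mfa],
            columns=["measurement_id", "mapping", "flux", "ci"],
        ).to_csv(paths["mfa"], sep="\t", index=False)

        paths["expression"] = directory / "expression.tsv"
        pd.DataFrame(sorted(self.expression.values.items()),
                     columns=["gene_id", "value"]).to_csv(
            paths["expression"], sep="\t", index=False)

        paths["physiology"] = directory / "physiology.tsv"
        rows = [(rid, val, ci) for rid, (val, ci) in self.physiology.exchanges.items()]
        if self.physiology.growth is not None:
            rows.append(("growth", *self.physiology.growth))
        if self.physiology.dilution_rate is not None:
            rows.append(("dilution_rate", self.physiology.dilution_rate, 0.0))
        pd.DataFrame(rows, columns=["quantity", "value", "ci"]).to_csv(
            paths["physiology"], sep="\t", index=False)
        return paths


def make_synthetic_reference_data(
    model: MetabolicModel, seed: int = 0, noise_sigma: float = 0.0
) -> ToyScenario:
    """Generate MFA/expression/physiology tables from planted ground truth.

    The planted flux vector satisfies S w = 0 exactly.  MFA values are the
    planted fluxes plus zero-mean Gaussian noise of the stated sigma
    (measured individually for every reaction, lumped over the duplicated
    pair in ``duplicated_path``); expression is proportional to the planted
    contributions, and the physiology pins the uptake exchanges with zero
    half-width.  With ``noise_sigma=0`` the reference estimator recovers
    the planted state exactly.  Regeneration with the same seed is
    bit-identical.
    """
    kind = model.name
    if kind not in _PLANTED_W:
        raise ValueError(f"no planted ground truth for model {model.name!r}")
    rng = np.random.default_rng(seed)
    w = dict(_PLANTED_W[kind])

    records = []
    measured = [r for r in model.reaction_ids
                if r not in _PINNED_EXCHANGES[kind]]
    if kind == "duplicated_path":
        measured = [r for r in measured if r not in ("D1", "D2")]
    for rid in measured:
        noise = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        records.append((rid.lower(), rid, w[rid] + noise, MFA_CONFIDENCE))
    if kind == "duplicated_path":
        noise = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        records.append(("dup", "D1+D2", 0.0 + noise, MFA_CONFIDENCE))
    mfa = mfa_from_records(records, model)

    expression = make_expression_profile(dict(_PLANTED_EXPR[kind]))
    physiology = Physiology(
        exchanges={rid: (val, 0.0) for rid, val in _PINNED_EXCHANGES[kind].items()}
    )
    return ToyScenario(
        model=model,
        planted_w=w,
        planted_contrib=dict(_PLANTED_CONTRIB[kind]),
        mfa=mfa,
        expression=expression,
        physiology=physiology,
        seed=seed,
        noise_sigma=noise_sigma,
    )


# ---------------------------------------------------------------------
# brute-force optimization oracles
# ---------------------------------------------------------------------

def _nullspace(A, tol=1e-10):
    if A.size == 0:
        return np.eye(A.shape[1] if A.ndim == 2 else 0)
    u, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > tol * max(A.shape)))
    return vt[rank:].T


def qp_oracle(P, q, const=0.0, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
              lb=None, ub=None, feas_tol=1e-8):
    """Exhaustive convex-QP oracle: active-set enumeration of KKT systems.

    Equality constraints are eliminated through a null-space basis; every
    subset of inequality constraints (including finite bounds) of size up
    to the reduced dimension is treated as active and its KKT system
    solved exactly.  The best primal-feasible candidate is the global
    optimum of a convex instance.  Intended for small fixtures only
    (reduced dimension <= 8); non-convex P is rejected.

    Returns (x, objective) or (None, inf) when no candidate is feasible.
    """
    P = np.asarray(P, float)
    q = np.asarray(q, float)
    n = q.shape[0]
    eigs = np.linalg.eigvalsh((P + P.T) / 2.0)
    if eigs[0] < -1e-9 * max(1.0, abs(eigs[-1])):
        raise ValueError("qp_oracle requires a convex (PSD) objective")

    from .qp import _as_arrays, _stacked_inequalities

    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    G, h = _stacked_inequalities(A_ub, b_ub, lb, ub)

    # particular solution and null-space basis of the equalities
    if A_eq.size:
        x_part, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
        if np.max(np.abs(A_eq @ x_part - b_eq)) > 1e-7:
            return None, np.inf
        Z = _nullspace(A_eq)
    else:
        x_part = np.zeros(n)
        Z = np.eye(n)
    dim = Z.shape[1]
    if dim > 8:
        raise ValueError(f"oracle limited to <= 8 reduced dimensions, got {dim}")

    Pz = Z.T @ P @ Z
    qz = Z.T @ (P @ x_part + q)
    cz = const + 0.5 * x_part @ P @ x_part + q @ x_part
    Gz = G @ Z
    hz = h - G @ x_part
    scale = 1.0 + np.abs(hz)

    best_x, best_obj = None, np.inf
    m = Gz.shape[0]
    for k in range(0, dim + 1):
        for subset in itertools.combinations(range(m), k):
            idx = list(subset)
            A_act = Gz[idx]
            K = np.zeros((dim + k, dim + k))
            K[:dim, :dim] = Pz
            K[:dim, dim:] = A_act.T
            K[dim:, :dim] = A_act
            rhs = np.concatenate([-qz, hz[idx]])
            y_lam, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            y = y_lam[:dim]
            if not np.all(np.isfinite(y)):
                continue
            # stationarity must actually hold (lstsq may return a
            # least-squares "solution" of an inconsistent system)
            if np.max(np.abs(K @ y_lam - rhs), initial=0.0) > 1e-6 * (1 + np.max(np.abs(rhs), initial=0.0)):
                continue
            if m and np.max((Gz @ y - hz) / scale) > feas_tol:
                continue
            obj = float(0.5 * y @ Pz @ y + qz @ y + cz)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_x = x_part + Z @ y
    return best_x, best_obj


def grid_oracle(fun, lo, hi, rounds=40, points=41):
    """1-D dense grid refinement for a convex scalar function."""
    for _ in range(rounds):
        xs = np.linspace(lo, hi, points)
        vals = [fun(x) for x in xs]
        k = int(np.argmin(vals))
        lo = xs[max(k - 1, 0)]
        hi = xs[min(k + 1, points - 1)]
    x = 0.5 * (lo + hi)
    return x, fun(x)


def lp_oracle(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, lb=None, ub=None,
              maximize=False, feas_tol=1e-8):
    """Vertex-enumeration LP oracle (bounded instances only)."""
    c = np.asarray(c, float)
    n = c.shape[0]
    from .qp import _as_arrays, _stacked_inequalities

    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    G, h = _stacked_inequalities(A_ub, b_ub, lb, ub)
    if A_eq.size:
        x_part, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
        Z = _nullspace(A_eq)
    else:
        x_part = np.zeros(n)
        Z = np.eye(n)
    dim = Z.shape[1]
    Gz = G @ Z
    hz = h - G @ x_part
    scale = 1.0 + np.abs(hz)
    sign = -1.0 if maximize else 1.0
    best_x, best_obj = None, np.inf
    for subset in itertools.combinations(range(Gz.shape[0]), dim):
        A_act = Gz[list(subset)]
        if np.linalg.matrix_rank(A_act) < dim:
            continue
        y = np.linalg.lstsq(A_act, hz[list(subset)], rcond=None)[0]
        if np.max((Gz @ y - hz) / scale) > feas_tol:
            continue
        x = x_part + Z @ y
        obj = sign * float(c @ x)
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x
    return best_x, (best_obj if maximize is False else -best_obj) if best_x is not None else np.inf


def room_oracle(model: MetabolicModel, w: dict[str, float], delta: float,
                epsilon: float) -> int:
    """Exhaustive minimum count of significant flux changes.

    Enumerates every on/off pattern over the reactions and checks
    feasibility of the induced interval constraints under steady state via
    a phase-1 LP — an independent check of the MILP route.
    """
    from .qp import find_feasible_point

    n = model.n_reactions
    wv = np.asarray([w[r] for r in model.reaction_ids])
    w_hi = np.minimum(wv + delta * np.abs(wv) + epsilon, model.upper_bounds)
    w_lo = np.maximum(wv - delta * np.abs(wv) - epsilon, model.lower_bounds)
    best = n + 1
    for pattern in itertools.product([0, 1], repeat=n):
        count = sum(pattern)
        if count >= best:
            continue
        lb = np.where(np.array(pattern) == 0, w_lo, model.lower_bounds)
        ub = np.where(np.array(pattern) == 0, w_hi, model.upper_bounds)
        if np.any(lb > ub):
            continue
        if find_feasible_point(n, model.S, np.zeros(model.S.shape[0]),
                               lb=lb, ub=ub) is not None:
            best = count
    return best


# ---------------------------------------------------------------------
# randomized small instances for solver-vs-oracle agreement
# ---------------------------------------------------------------------

def random_scenario(seed: int):
    """A randomized small network with consistent synthetic data.

    Topology: uptake U -> A, two parallel routes A -> B (one with a
    two-isozyme GPR), export B -> ; random planted split, random positive
    expression, mildly noisy MFA.  Small enough for the exhaustive oracle.
    Returns (model, mfa, expression, physiology, rng).
    """
    rng = np.random.default_rng(seed)
    uptake = float(np.round(rng.uniform(4.0, 10.0), 3))
    rows = [
        ("U", "-> A", 0.0, uptake, ""),
        ("P1", "A -> B", 0.0, 50.0, "ga or gb"),
        ("P2", "A -> B", 0.0, 50.0, "gc"),
        ("X", "B ->", 0.0, 50.0, ""),
    ]
    df = pd.DataFrame(rows, columns=["id", "equation", "lower_bound",
                                     "upper_bound", "gpr"])
    model = model_from_table(df, biomass_id="X", name=f"random-{seed}")

    frac = rng.uniform(0.2, 0.8)
    w1 = uptake * frac
    w2 = uptake - w1
    noise = rng.normal(0.0, 0.05, size=3)
    mfa = mfa_from_records(
        [
            ("p1", "P1", w1 + noise[0], 0.1),
            ("p2", "P2", w2 + noise[1], 0.1),
            ("x", "X", uptake + noise[2], 0.1),
        ],
        model,
    )
    expression = make_expression_profile(
        {g: float(np.round(rng.uniform(0.5, 10.0), 3)) for g in ("ga", "gb", "gc")}
    )
    physiology = Physiology(exchanges={"U": (uptake, 0.0)})
    return model, mfa, expression, physiology, rng
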