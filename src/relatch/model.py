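"""Metabolic model container, loaders, and perturbation editing.

The in-memory model is a light stoichiometric container: metabolite and
reaction ids, a dense stoichiometric matrix (toy and central-metabolism
scale; genome-scale SBML inputs are loaded through COBRApy and converted),
per-reaction flux bounds in mmol/gDW/h, and the GPR association of each
reaction already enumerated into isozymes.

Two input dialects are supported:

* SBML Level 2 / Level 3 with the FBC package, read via COBRApy;
* a tabular TSV dialect (columns ``id``, ``equation``, ``lower_bound``,
  ``upper_bound``, optional ``gpr`` and ``objective``) so small fixtures
  avoid XML authoring; a nonzero ``objective`` flags the biomass reaction.

Exchange reactions are identified structurally as reactions touching a
single metabolite (one nonzero stoichiometric entry).  The sign convention
for exchanges follows SBML/FBC practice: uptake is a negative flux,
secretion positive, unless a model author writes the boundary reaction in
the producing orientation (fixtures do, for readability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import re

import numpy as np
import pandas as pd

from .gpr import GPRAssociation, parse_gpr


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationSpec:
    """A genetic and/or environmental perturbation.

    ``knockouts`` lists gene ids to delete; ``medium`` maps exchange
    reaction ids to new (lower, upper) bounds in mmol/gDW/h; a non-None
    ``fixed_growth`` (h^-1) pins the biomass reaction to that rate, the
    chemostat case where the dilution rate is known a priori.
    """

    knockouts: frozenset[str] = frozenset()
    medium: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_growth: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        if self.fixed_growth is not None and self.fixed_growth < 0:
            raise ValueError("fixed growth rate must be nonnegative")

    @property
    def is_empty(self) -> bool:
        return not self.knockouts and not self.medium and self.fixed_growth is None


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric model with enumerated GPR associations."""

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray  # metabolite x reaction
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr_strings: tuple[str, ...]
    associations: dict[str, GPRAssociation]
    biomass_id: str | None = None
    name: str = "model"

    def __post_init__(self):
        n_met, n_rxn = self.S.shape
        if n_met != len(self.metabolite_ids) or n_rxn != len(self.reaction_ids):
            raise ModelValidationError("stoichiometric matrix shape mismatch")
        if len(set(self.reaction_ids)) != n_rxn:
            dupes = sorted(
                {r for r in self.reaction_ids if self.reaction_ids.count(r) > 1}
            )
            raise ModelValidationError(f"duplicate reaction id(s): {', '.join(dupes)}")
        if len(set(self.metabolite_ids)) != n_met:
            raise ModelValidationError("duplicate metabolite ids")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = [
                self.reaction_ids[j]
                for j in np.nonzero(self.lower_bounds > self.upper_bounds)[0]
            ]
            raise ModelValidationError(f"lower bound above upper bound: {', '.join(bad)}")
        if self.biomass_id is not None and self.biomass_id not in self.reaction_index:
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} not in model")

    # -- indexing helpers -------------------------------------------------
    @property
    def reaction_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for assoc in self.associations.values():
            out |= assoc.genes
        return frozenset(out)

    @property
    def gpr_reactions(self) -> tuple[str, ...]:
        """J_GPR: reactions whose GPR enumerates to at least one enzyme."""
        return tuple(
            r for r in self.reaction_ids if self.associations[r].n_enzymes > 0
        )

    @property
    def exchange_ids(self) -> frozenset[str]:
        """Reactions with exactly one nonzero stoichiometric entry."""
        nnz = np.count_nonzero(self.S, axis=0)
        return frozenset(
            r for j, r in enumerate(self.reaction_ids) if nnz[j] == 1
        )

    @property
    def enzyme_pairs(self) -> tuple[tuple[str, int], ...]:
        """All (reaction id, enzyme index) pairs over J_GPR, in model order."""
        return tuple(
            (r, n)
            for r in self.gpr_reactions
            for n in range(self.associations[r].n_enzymes)
        )

    def with_bounds(self, rid: str, lb: float, ub: float) -> "MetabolicModel":
        j = self.reaction_index[rid]
        lower = self.lower_bounds.copy()
        upper = self.upper_bounds.copy()
        lower[j], upper[j] = lb, ub
        return replace(self, lower_bounds=lower, upper_bounds=upper)


# -- tabular dialect -----------------------------------------------------

_ARROW_RE = re.compile(r"<->|<=>|->|=>|<-")


def _parse_side(side: str, coefs: dict[str, float], sign: float) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelValidationError(f"empty species term in {side!r}")
        m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
        if m is None:
            raise ModelValidationError(f"cannot parse species term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        coefs[met] = coefs.get(met, 0.0) + sign * coef


def parse_reaction_equation(eq: str) -> dict[str, float]:
    """Parse ``'A + 2 B -> C'`` into {'A': -1, 'B': -2, 'C': 1}.

    ``<->`` (or ``<=>``) marks reversibility in the written direction but
    stoichiometry is stored the same way; ``-> A`` / ``A ->`` describe
    boundary reactions.  ``<-`` flips the written direction.
    """
    m = _ARROW_RE.search(eq)
    if m is None:
        raise ModelValidationError(f"no reaction arrow in equation {eq!r}")
    left, right = eq[: m.start()], eq[m.end():]
    flip = m.group(0) == "<-"
    coefs: dict[str, float] = {}
    _parse_side(left, coefs, 1.0 if flip else -1.0)
    _parse_side(right, coefs, -1.0 if flip else 1.0)
    coefs = {k: v for k, v in coefs.items() if v != 0.0}
    if not coefs:
        raise ModelValidationError(f"equation {eq!r} has no net stoichiometry")
    return coefs


def model_from_table(df: pd.DataFrame, biomass_id: str | None = None,
                     name: str = "model") -> MetabolicModel:
    """Build a model from a reactions table (tabular dialect)."""
    required = {"id", "equation", "lower_bound", "upper_bound"}
    missing = required - set(df.columns)
    if missing:
        raise ModelValidationError(f"missing column(s): {', '.join(sorted(missing))}")
    rids = [str(r) for r in df["id"]]
    if len(set(rids)) != len(rids):
        dupes = sorted({r for r in rids if rids.count(r) > 1})
        raise ModelValidationError(f"duplicate reaction id(s): {', '.join(dupes)}")

    stoich: list[dict[str, float]] = []
    mets: list[str] = []
    seen: set[str] = set()
    for rid, eq in zip(rids, df["equation"]):
        try:
            coefs = parse_reaction_equation(str(eq))
        except ModelValidationError as exc:
            raise ModelValidationError(f"reaction {rid!r}: {exc}") from exc
        stoich.append(coefs)
        for met in coefs:
            if met not in seen:
                seen.add(met)
                mets.append(met)

    S = np.zeros((len(mets), len(rids)))
    met_idx = {m: i for i, m in enumerate(mets)}
    for j, coefs in enumerate(stoich):
        for met, c in coefs.items():
            S[met_idx[met], j] = c

    gprs = [str(g) if not pd.isna(g) else "" for g in df.get("gpr", [""] * len(rids))]
    associations = {rid: parse_gpr(g, reaction_id=rid) for rid, g in zip(rids, gprs)}

    if biomass_id is None and "objective" in df.columns:
        flagged = [rid for rid, obj in zip(rids, df["objective"])
                   if not pd.isna(obj) and float(obj) != 0.0]
        if len(flagged) > 1:
            raise ModelValidationError("multiple reactions flagged as objective")
        if flagged:
            biomass_id = flagged[0]

    return MetabolicModel(
        metabolite_ids=tuple(mets),
        reaction_ids=tuple(rids),
        S=S,
        lower_bounds=df["lower_bound"].to_numpy(dtype=float),
        upper_bounds=df["upper_bound"].to_numpy(dtype=float),
        gpr_strings=tuple(gprs),
        associations=associations,
        biomass_id=biomass_id,
        name=name,
    )


def _from_cobra(cmodel, biomass_id: str | None) -> MetabolicModel:
    mets = tuple(m.id for m in cmodel.metabolites)
    rxns = tuple(r.id for r in cmodel.reactions)
    met_idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    lbs = np.empty(len(rxns))
    ubs = np.empty(len(rxns))
    gprs = []
    for j, rxn in enumerate(cmodel.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_idx[met.id], j] = coef
        lbs[j], ubs[j] = rxn.lower_bound, rxn.upper_bound
        gprs.append(rxn.gene_reaction_rule or "")
    if biomass_id is None:
        objective = [r.id for r in cmodel.reactions if r.objective_coefficient]
        biomass_id = objective[0] if len(objective) == 1 else None
    associations = {rid: parse_gpr(g, reaction_id=rid) for rid, g in zip(rxns, gprs)}
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        gpr_strings=tuple(gprs),
        associations=associations,
        biomass_id=biomass_id,
        name=cmodel.id or "model",
    )


def load_model(path, dialect: str = "sbml", biomass_id: str | None = None) -> MetabolicModel:
    """Load a metabolic model from SBML or the tabular TSV dialect.

    Parameters
    ----------
    path:
        File path.  SBML Level 2 (GPRs in notes fields) and Level 3 + FBC
        are both accepted via COBRApy; the tabular dialect is a TSV with
        columns ``id``, ``equation``, ``lower_bound``, ``upper_bound`` and
        optional ``gpr``.
    dialect:
        ``"sbml"`` or ``"tabular"``.
    biomass_id:
        Reaction id to treat as biomass.  For SBML, defaults to the model
        objective when it is a single reaction.
    """
    if dialect == "sbml":
        import cobra.io

        cmodel = cobra.io.read_sbml_model(str(path))
        return _from_cobra(cmodel, biomass_id)
    if dialect == "tabular":
        df = pd.read_csv(path, sep="\t", comment="#")
        return model_from_table(df, biomass_id=biomass_id)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'sbml' or 'tabular')")


def apply_environment(model: MetabolicModel, spec: PerturbationSpec) -> MetabolicModel:
    """Apply the environmental part of a perturbation as bound edits.

    Medium edits touch exchange reactions only (an edit on an internal
    reaction is an error: environmental perturbations change what the cell
    may take up or secrete, not its internal capacities).  A fixed growth
    rate clamps both biomass bounds.
    """
    exchanges = model.exchange_ids
    idx = model.reaction_index
    lower = model.lower_bounds.copy()
    upper = model.upper_bounds.copy()
    for rid, (lb, ub) in spec.medium.items():
        if rid not in idx:
            raise KeyError(f"medium edit on unknown reaction {rid!r}")
        if rid not in exchanges:
            raise ValueError(
                f"medium edit on non-exchange reaction {rid!r}; "
                "environmental perturbations act only on uptake/secretion"
            )
        if lb > ub:
            raise ValueError(f"medium edit on {rid!r} has lower bound above upper")
        lower[idx[rid]], upper[idx[rid]] = lb, ub
    if spec.fixed_growth is not None:
        if model.biomass_id is None:
            raise ValueError("fixed growth rate given but model has no biomass reaction")
        j = idx[model.biomass_id]
        lower[j] = upper[j] = spec.fixed_growth
    return replace(model, lower_bounds=lower, upper_bounds=upper)
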