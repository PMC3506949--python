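"""Readers for MFA, expression and physiology tables; enzyme expression.

MFA measurements may be lumped: one measured value can map onto a signed
linear combination of model reactions (e.g. the sum of two parallel
acetate-producing pathways, or a net flux through a reversible pair).  The
mapping mini-language accepts ``PGI``, ``PDH+PFL``, ``ACKr-ACS`` and
rational coefficients such as ``0.5*R1+R2``.

Enzyme expression values E_n weight the reference-state regularizer: an
enzyme complex is assigned the minimum expression over its subunits (the
limiting subunit sets the achievable amount of complex), and missing or
near-zero values are floored so reciprocal weights stay finite.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import GPRAssociation
from .model import MetabolicModel

logger = logging.getLogger(__name__)

#: below this fraction of the profile median, expression is floored
EXPRESSION_FLOOR_FRACTION = 0.01
#: minimum confidence half-width, mmol/gDW/h
CONFIDENCE_FLOOR = 0.01


@dataclass(frozen=True)
class MFAMeasurement:
    """One measured flux, mapped onto model reactions.

    ``mapping`` is reaction id -> coefficient; the measurement compares
    ``sum_j c_j v_j`` against ``value`` with confidence half-width ``ci``.
    """

    measurement_id: str
    mapping: dict[str, float]
    value: float
    ci: float

    def evaluate(self, flux: dict[str, float] | "pd.Series") -> float:
        return float(sum(c * flux[rid] for rid, c in self.mapping.items()))


@dataclass(frozen=True)
class MFADataset:
    measurements: tuple[MFAMeasurement, ...]

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.measurement_id for m in self.measurements)


@dataclass(frozen=True)
class ExpressionProfile:
    """Gene -> expression value, floored at construction.

    ``floor`` is the substitution value used for missing genes and for
    values below ``EXPRESSION_FLOOR_FRACTION`` of the profile median.
    """

    values: dict[str, float]
    floor: float

    def __post_init__(self):
        if self.floor <= 0:
            raise ValueError("expression floor must be positive")
        bad = [g for g, v in self.values.items() if v < self.floor]
        if bad:
            raise ValueError("profile contains values below the floor; "
                             "construct via make_expression_profile")

    def __getitem__(self, gene: str) -> float:
        val = self.values.get(gene)
        if val is None:
            logger.warning("gene %s missing from expression profile; using floor %g",
                           gene, self.floor)
            return self.floor
        return val

    def __contains__(self, gene: str) -> bool:
        return gene in self.values


def make_expression_profile(values: dict[str, float]) -> ExpressionProfile:
    """Validate and floor a raw gene-expression mapping."""
    for g, v in values.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"negative or non-finite expression for gene {g!r}: {v}")
    if values:
        median = float(np.median(list(values.values())))
        floor = max(EXPRESSION_FLOOR_FRACTION * median, 1e-12)
    else:
        floor = 1e-12
    floored = {g: max(v, floor) for g, v in values.items()}
    n_floored = sum(1 for g in values if values[g] < floor)
    if n_floored:
        logger.info("floored %d expression value(s) at %g", n_floored, floor)
    return ExpressionProfile(values=floored, floor=floor)


@dataclass(frozen=True)
class Physiology:
    """Measured external rates and growth for the reference state.

    ``exchanges`` maps exchange reaction ids to (value, half-width) in
    mmol/gDW/h; ``growth`` is (value, half-width) in h^-1; a non-None
    ``dilution_rate`` (h^-1) marks a chemostat, imposed as an equality on
    the biomass flux (at most one of growth/dilution may be an equality).
    """

    exchanges: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth: tuple[float, float] | None = None
    dilution_rate: float | None = None

    def __post_init__(self):
        for rid, (_, ci) in self.exchanges.items():
            if ci < 0:
                raise ValueError(f"negative half-width for exchange {rid!r}")
        if self.growth is not None and self.growth[1] < 0:
            raise ValueError("negative half-width for growth")
        if self.dilution_rate is not None:
            if self.dilution_rate < 0:
                raise ValueError("dilution rate must be nonnegative")
            if self.growth is not None and self.growth[1] == 0:
                raise ValueError("growth equality and dilution rate both set")


# -- mapping mini-language ----------------------------------------------

_TERM_RE = re.compile(
    r"^\s*(?P<sign>[+-]?)\s*(?:(?P<coef>\d+(?:\.\d+)?|\d+/\d+)\s*\*\s*)?(?P<rid>[^\s+*-][^\s+]*?)\s*$"
)


def parse_mapping(text: str) -> dict[str, float]:
    """Parse ``'0.5*R1+R2-R3'`` into {'R1': 0.5, 'R2': 1.0, 'R3': -1.0}."""
    terms = re.findall(r"[+-]?[^+-]+(?:/\d+)?", text.strip())
    mapping: dict[str, float] = {}
    if not terms:
        raise ValueError(f"empty measurement mapping {text!r}")
    for term in terms:
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"cannot parse mapping term {term!r} in {text!r}")
        coef_txt = m.group("coef")
        if coef_txt is None:
            coef = 1.0
        elif "/" in coef_txt:
            num, den = coef_txt.split("/")
            coef = float(num) / float(den)
        else:
            coef = float(coef_txt)
        if m.group("sign") == "-":
            coef = -coef
        rid = m.group("rid")
        mapping[rid] = mapping.get(rid, 0.0) + coef
    return mapping


def read_mfa_table(path, model: MetabolicModel) -> MFADataset:
    """Read a TSV of measurements (measurement_id, mapping, flux, ci).

    Mappings are validated against the model: any reaction id absent from
    the model is a hard error naming the measurement and the reaction.
    Confidence half-widths below ``CONFIDENCE_FLOOR`` are raised to it so
    reciprocal weights stay bounded.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"measurement_id": str})
    required = {"measurement_id", "mapping", "flux", "ci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MFA table missing column(s): {', '.join(sorted(missing))}")
    return mfa_from_records(
        [
            (str(r.measurement_id), str(r.mapping), float(r.flux), float(r.ci))
            for r in df.itertuples()
        ],
        model,
    )


def mfa_from_records(records, model: MetabolicModel) -> MFADataset:
    """Build an MFADataset from (id, mapping text, flux, ci) tuples."""
    idx = model.reaction_index
    out = []
    for mid, mapping_text, flux, ci in records:
        mapping = parse_mapping(mapping_text)
        unknown = sorted(set(mapping) - set(idx))
        if unknown:
            raise KeyError(
                f"measurement {mid!r} maps to unknown reaction(s): {', '.join(unknown)}"
            )
        if not np.isfinite(flux) or not np.isfinite(ci):
            raise ValueError(f"non-numeric flux/ci for measurement {mid!r}")
        ci = max(float(ci), CONFIDENCE_FLOOR)
        out.append(MFAMeasurement(mid, mapping, float(flux), ci))
    return MFADataset(tuple(out))


def read_expression_table(path) -> ExpressionProfile:
    """Read a TSV of (gene_id, value) rows into a floored profile."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError("expression table needs columns gene_id, value")
    return make_expression_profile(
        {str(r.gene_id): float(r.value) for r in df.itertuples()}
    )


def read_physiology(path) -> Physiology:
    """Read a TSV of (quantity, value, ci) rows.

    ``quantity`` is either ``growth``, ``dilution_rate``, or an exchange
    reaction id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"quantity": str})
    if not {"quantity", "value"} <= set(df.columns):
        raise ValueError("physiology table needs columns quantity, value[, ci]")
    exchanges: dict[str, tuple[float, float]] = {}
    growth = None
    dilution = None
    for r in df.itertuples():
        value = float(r.value)
        ci = float(getattr(r, "ci", 0.0)) if not pd.isna(getattr(r, "ci", 0.0)) else 0.0
        if r.quantity == "growth":
            growth = (value, ci)
        elif r.quantity == "dilution_rate":
            dilution = value
        else:
            exchanges[str(r.quantity)] = (value, ci)
    return Physiology(exchanges=exchanges, growth=growth, dilution_rate=dilution)


def enzyme_expression(profile: ExpressionProfile, assoc: GPRAssociation) -> tuple[float, ...]:
    """Per-enzyme expression E_n: minimum over the enzyme's subunit genes.

    Genes absent from the profile take the profile floor (logged by the
    profile itself), so E_n > 0 always and reciprocal weights are finite.
    """
    return tuple(min(profile[g] for g in enz) for enz in assoc.enzymes)
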