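"""Scoring predictions against measured fluxes and growth phenotypes.

Flux accuracy is the sum of squared errors per flux (SSE): the mean, over
MFA measurements, of the squared deviation between the measured value and
the mapped prediction (lumped measurements evaluate a signed linear
combination of predicted fluxes).  Pearson's r between measured and mapped
predicted values summarizes pattern agreement.  Growth phenotype calls
(growth / no growth) against experimental gene-essentiality data are
tabulated in a 2x2 confusion matrix whose accuracy is the percentage of
concordant calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import MFADataset

GROWTH_CUTOFF_FRACTION = 0.05  # fraction of wild-type growth calling "no growth"


@dataclass(frozen=True)
class EvaluationReport:
    sse: float
    pearson_r: float | None  # None when undefined (zero variance)
    per_measurement: dict[str, float]  # squared error per measurement
    n_measurements: int

    def __str__(self):
        r = "undefined" if self.pearson_r is None else f"{self.pearson_r:.4f}"
        return f"SSE per flux = {self.sse:.4g} over {self.n_measurements} measurements, r = {r}"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Growth phenotype confusion counts.

    First sign is the experimental phenotype, second the model prediction:
    ``pp`` = +/+, ``pn`` = +/-, ``np_`` = -/+, ``nn`` = -/-.
    """

    pp: int
    pn: int
    np_: int
    nn: int

    def __post_init__(self):
        if min(self.pp, self.pn, self.np_, self.nn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.pp + self.pn + self.np_ + self.nn

    @property
    def accuracy(self) -> float:
        """Percent of concordant calls, 100 * (pp + nn) / total."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * (self.pp + self.nn) / self.total


def _mapped(pred_flux: dict[str, float], mfa: MFADataset):
    measured = np.array([m.value for m in mfa])
    predicted = np.array([m.evaluate(pred_flux) for m in mfa])
    return measured, predicted


def compute_sse(pred_flux: dict[str, float], mfa: MFADataset) -> EvaluationReport:
    """Sum of squared errors per flux between predictions and MFA data."""
    if len(mfa) == 0:
        raise ValueError("cannot evaluate against an empty MFA dataset")
    measured, predicted = _mapped(pred_flux, mfa)
    sq = (measured - predicted) ** 2
    return EvaluationReport(
        sse=float(np.mean(sq)),
        pearson_r=pearson(pred_flux, mfa) if len(mfa) >= 2 else None,
        per_measurement=dict(zip(mfa.ids, sq.tolist())),
        n_measurements=len(mfa),
    )


def pearson(pred_flux: dict[str, float], mfa: MFADataset) -> float | None:
    """Pearson correlation between measured and mapped predicted fluxes.

    Returns None when either vector has zero variance (undefined).
    """
    if len(mfa) < 2:
        raise ValueError("Pearson correlation needs at least two measurements")
    measured, predicted = _mapped(pred_flux, mfa)
    if np.ptp(measured) == 0 or np.ptp(predicted) == 0:
        return None
    return float(stats.pearsonr(measured, predicted).statistic)


def classify_growth(pred_growth: float, wt_growth: float,
                    cutoff_frac: float = GROWTH_CUTOFF_FRACTION) -> str:
    """Call 'no_growth' when predicted growth is below cutoff_frac * wild type.

    Ties go to 'growth' (strict inequality).  Small negative predictions
    within numerical noise are treated as zero; genuinely negative growth
    is an input error.
    """
    if wt_growth <= 0:
        raise ValueError("wild-type growth must be positive")
    if pred_growth < -1e-9:
        raise ValueError(f"negative predicted growth: {pred_growth}")
    pred_growth = max(pred_growth, 0.0)
    return "no_growth" if pred_growth < cutoff_frac * wt_growth else "growth"


def confusion_accuracy(calls: list[tuple[str, str]]) -> ConfusionMatrix:
    """Tabulate (experimental, predicted) phenotype pairs.

    Each element is a pair of ``"growth"``/``"no_growth"`` labels (or
    ``"+"``/``"-"``), experimental first.
    """
    if not calls:
        raise ValueError("no phenotype calls to tabulate")
    norm = {"growth": "+", "+": "+", "no_growth": "-", "-": "-"}
    counts = Counter()
    for exp, pred in calls:
        try:
            counts[(norm[exp], norm[pred])] += 1
        except KeyError as exc:
            raise ValueError(f"unknown phenotype label {exc}") from exc
    return ConfusionMatrix(
        pp=counts[("+", "+")], pn=counts[("+", "-")],
        np_=counts[("-", "+")], nn=counts[("-", "-")],
    )
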