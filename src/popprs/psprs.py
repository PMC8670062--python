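"""Population-specific polygenic risk scores and prevalence regression.

A population-specific PRS (psPRS) summarises the genetic load of a
population for a trait as the unweighted sum of risk-allele frequencies
over a SNP set:

    psPRS(pop) = sum_k p_k(pop)

where ``p_k(pop)`` is the frequency of the k-th risk allele in that
population. The score is deliberately unweighted: GWAS effect sizes are
estimated in particular discovery cohorts and transfer poorly across
ancestries, whereas — as long as the direction of effect is shared — the
contribution of a variant to population prevalence should scale with its
risk-allele frequency.

Trait prevalence (or a population mean, e.g. height) is then regressed
on the psPRS across populations under three link models:

* linear        — y ~ a + b * s
* poly2         — y ~ a + b * s + c * s**2
* exponential   — log(y) ~ a + b * s, i.e. y = exp(a) * exp(b * s)

The exponential model is fit by ordinary least squares on the
log-transformed phenotype (closed-form and deterministic); its r2 is on
the log scale. All fits report the coefficient of determination, the
overall F-test p-value, and the first-order slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ValidationError
from .io_formats import FrequencyMatrix, PopulationPanel

logger = logging.getLogger(__name__)

ModelKind = Literal["linear", "poly2", "exponential"]

_MIN_N = {"linear": 3, "poly2": 4, "exponential": 3}


@dataclass(frozen=True)
class PsprsVector:
    """Per-population psPRS values with the SNP set that was summed."""

    scores: pd.Series  # index: population code
    snp_set: frozenset[str]

    def __post_init__(self) -> None:
        if (self.scores < -1e-12).any() or (self.scores > len(self.snp_set) + 1e-12).any():
            raise ValidationError(
                f"psPRS scores must lie in [0, {len(self.snp_set)}]"
            )


@dataclass(frozen=True)
class RegressionFit:
    """One prevalence-vs-psPRS regression.

    For the exponential model coefficients are on the log-prevalence
    scale; ``growth_factor`` is the back-transformed per-unit-score
    multiplicative change exp(slope).
    """

    model: ModelKind
    coefficients: pd.Series  # const, score [, score2]
    r2: float
    p_value: float
    n: int

    @property
    def slope(self) -> float:
        """First-order coefficient of the score."""
        return float(self.coefficients["score"])

    @property
    def intercept(self) -> float:
        return float(self.coefficients["const"])

    @property
    def growth_factor(self) -> float:
        if self.model != "exponential":
            raise ValueError("growth_factor is defined for the exponential model only")
        return math.exp(self.slope)


def compute_psprs(freqs: FrequencyMatrix, snp_set: Iterable[str]) -> PsprsVector:
    """Sum risk-allele frequencies per population over ``snp_set``.

    Every rsid must be present and complete (no missing population
    entry) in ``freqs``; the result is independent of rsid order.
    """
    rsids = list(dict.fromkeys(snp_set))
    present = set(freqs.values.index)
    missing = sorted(r for r in rsids if r not in present)
    if missing:
        raise ValidationError(f"rsids absent from frequency matrix: {missing}")
    sub = freqs.values.loc[rsids]
    incomplete = sorted(sub.index[sub.isna().any(axis=1)])
    if incomplete:
        raise ValidationError(
            f"rsids with missing population frequencies: {incomplete}"
        )
    scores = sub.sum(axis=0) if rsids else pd.Series(
        0.0, index=freqs.values.columns, dtype=float
    )
    scores.name = "psprs"
    return PsprsVector(scores=scores, snp_set=frozenset(rsids))


def _shared_xy(scores: PsprsVector, panel: PopulationPanel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    codes = [c for c in scores.scores.index if c in panel.table.index]
    dropped = [c for c in panel.table.index if c not in scores.scores.index]
    if dropped:
        logger.debug("populations without scores excluded from fit: %s", dropped)
    x = scores.scores.loc[codes].to_numpy(dtype=float)
    y = panel.table.loc[codes, "phenotype_value"].to_numpy(dtype=float)
    return x, y, codes


def _ols_fit(X: np.ndarray, y: np.ndarray, model: ModelKind, names: list[str]) -> RegressionFit:
    res = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = pd.Series(res.params, index=["const"] + names)
    return RegressionFit(
        model=model,
        coefficients=coefs,
        r2=float(res.rsquared),
        p_value=float(res.f_pvalue),
        n=int(res.nobs),
    )


def _check_fit_inputs(x: np.ndarray, model: ModelKind) -> None:
    if len(x) < _MIN_N[model]:
        raise ValidationError(
            f"{model} fit needs >= {_MIN_N[model]} shared populations, got {len(x)}"
        )
    if np.ptp(x) == 0.0:
        raise ValidationError("psPRS has zero variance across populations; slope undefined")


def fit_linear(scores: PsprsVector, panel: PopulationPanel) -> RegressionFit:
    """OLS of phenotype on psPRS; r2 and slope F-test p-value."""
    x, y, _ = _shared_xy(scores, panel)
    _check_fit_inputs(x, "linear")
    return _ols_fit(x[:, None], y, "linear", ["score"])


def fit_poly2(scores: PsprsVector, panel: PopulationPanel) -> RegressionFit:
    """OLS of phenotype on (psPRS, psPRS^2); overall F-test p-value."""
    x, y, _ = _shared_xy(scores, panel)
    _check_fit_inputs(x, "poly2")
    return _ols_fit(np.column_stack([x, x**2]), y, "poly2", ["score", "score2"])


def fit_exponential(scores: PsprsVector, panel: PopulationPanel) -> RegressionFit:
    """OLS of log(phenotype) on psPRS; r2 reported on the log scale."""
    x, y, codes = _shared_xy(scores, panel)
    _check_fit_inputs(x, "exponential")
    nonpos = [c for c, v in zip(codes, y) if v <= 0]
    if nonpos:
        raise ValidationError(
            f"exponential fit requires positive phenotype values; offending populations: {nonpos}"
        )
    return _ols_fit(x[:, None], np.log(y), "exponential", ["score"])


_FITTERS = {"linear": fit_linear, "poly2": fit_poly2, "exponential": fit_exponential}


def fit_model(scores: PsprsVector, panel: PopulationPanel, model: ModelKind) -> RegressionFit:
    """Dispatch to the requested link model."""
    try:
        fitter = _FITTERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return fitter(scores, panel)


def fit_by_super_population(
    scores: PsprsVector, panel: PopulationPanel, model: ModelKind = "linear"
) -> dict[str, RegressionFit]:
    """Fit the chosen model independently within each super-population.

    Groups with fewer shared populations than the model needs are
    skipped with a logged note, as are groups where the fit is
    degenerate (e.g. constant scores).
    """
    fits: dict[str, RegressionFit] = {}
    for super_pop, group in panel.table.groupby("super_population", sort=True):
        sub_panel = PopulationPanel(group.copy())
        try:
            fits[str(super_pop)] = fit_model(scores, sub_panel, model)
        except ValidationError as exc:
            logger.info("super-population %s skipped: %s", super_pop, exc)
    return fits
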