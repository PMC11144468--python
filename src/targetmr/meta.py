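"""Summary-statistic operators for drug-target Mendelian randomization.

This module is the layer that works purely on published (or internally
pooled) effect estimates: back-calculation of standard errors from printed
confidence intervals, Wald p-values, rescaling of per-allele estimates to a
per-SD-of-LDL-C scale, inverse-variance-weighted fixed-effect (IVW-FE)
pooling, Cochran's Q heterogeneity between instruments or between cohorts,
and multiple-testing control (Benjamini-Hochberg FDR and Bonferroni).

Conventions
-----------
* Binary-outcome effects are carried as log odds ratios (``beta``) with
  standard error ``se``; continuous effects are in SD units.
* Orientation (risk per 1-SD *lower* LDL-C vs per 1-SD higher) is explicit
  metadata on estimates, never inferred from the sign of ``beta``.
* Confidence-interval arithmetic uses the exact normal quantile
  (Phi^-1(0.975) = 1.959964...), not 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryEstimate",
    "MetaResult",
    "ScalingConstants",
    "se_from_ci",
    "wald_p",
    "rescale_per_allele",
    "ivw_meta",
    "cochran_q",
    "bh_fdr",
    "bonferroni_threshold",
    "round_sig",
]


@dataclass(frozen=True)
class SummaryEstimate:
    """A single effect estimate on the log-odds (or SD) scale.

    Parameters
    ----------
    label : endpoint or trait name.
    beta : log odds ratio (binary outcomes) or effect in SD units.
    se : standard error of ``beta``; must be positive.
    source : cohort or study the estimate came from (e.g. ``"CKB"``).
    scale : ``"per-allele"`` or ``"per-SD-ldl"``.
    """

    label: str
    beta: float
    se: float
    source: str = ""
    scale: str = "per-SD-ldl"

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"se must be positive and finite, got {self.se!r}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-theory confidence interval on the beta scale."""
        z = float(special.ndtri(0.5 + level / 2.0))
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect pooled estimate with heterogeneity diagnostics.

    ``q`` is Cochran's Q, chi-square with ``df = k - 1`` under homogeneity;
    ``p_het`` is its upper-tail p-value (NaN when ``df == 0``).
    """

    beta: float
    se: float
    p: float
    q: float
    df: int
    p_het: float

    def __post_init__(self) -> None:
        if self.q < 0 or self.df < 0:
            raise ValueError("q and df must be non-negative")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = float(special.ndtri(0.5 + level / 2.0))
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass(frozen=True)
class ScalingConstants:
    """Constants used to put external estimates on the per-SD-LDL-C scale.

    ``ukb_per_allele_sd`` is the per-allele effect of the external functional
    variant on standardized LDL-C (default 0.497 SD, the GLGC estimate for
    rs11591147-T) used to rescale UK Biobank per-allele disease estimates.
    ``sd_ldl_mgdl`` records what 1 SD of LDL-C corresponds to in mg/dL.
    """

    ukb_per_allele_sd: float = 0.497
    sd_ldl_mgdl: float = 27.41
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.ukb_per_allele_sd == 0:
            raise ValueError("ukb_per_allele_sd must be non-zero")


def se_from_ci(
    point: float,
    lo: float,
    hi: float,
    level: float = 0.95,
    label: str = "",
    source: str = "",
    scale: str = "per-SD-ldl",
) -> SummaryEstimate:
    """Back-calculate a log-scale SummaryEstimate from a printed OR and CI.

    ``beta = ln(point)``, ``se = (ln hi - ln lo) / (2 z)`` with z the exact
    normal quantile for ``level``. The point estimate may sit slightly
    outside the printed interval because all three numbers are rounded; a
    2% relative tolerance is allowed before erroring.
    """
    if not (lo > 0 and hi > 0 and point > 0):
        raise ValueError("odds ratio and CI bounds must be positive")
    if hi < lo:
        raise ValueError(f"upper bound {hi} below lower bound {lo}")
    if point < lo * 0.98 or point > hi * 1.02:
        raise ValueError(
            f"point estimate {point} outside [{lo}, {hi}] beyond rounding tolerance"
        )
    z = float(special.ndtri(0.5 + level / 2.0))
    se = (math.log(hi) - math.log(lo)) / (2.0 * z)
    if se <= 0:
        raise ValueError("degenerate confidence interval: se must be positive")
    return SummaryEstimate(
        label=label, beta=math.log(point), se=se, source=source, scale=scale
    )


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p-value, ``2 Phi(-|beta|/se)``."""
    if not se > 0:
        raise ValueError("se must be positive")
    # clamp at the smallest positive float so a perfect fit stays in (0, 1]
    return float(max(2.0 * special.ndtr(-abs(beta) / se), np.finfo(float).tiny))


def rescale_per_allele(
    est: SummaryEstimate,
    constants: ScalingConstants = ScalingConstants(),
    inverse: bool = False,
) -> SummaryEstimate:
    """Convert a per-allele estimate to the per-1-SD-of-LDL-C scale.

    Divides beta and se by the per-allele effect of the variant on
    standardized LDL-C (0.497 SD for rs11591147-T). ``inverse=True`` undoes
    the rescaling. The orientation convention of the input is preserved:
    this is a pure change of units, sign bookkeeping lives on the estimate.
    """
    c = constants.ukb_per_allele_sd
    if c == 0:
        raise ValueError("scaling constant must be non-zero")
    if inverse:
        if est.scale != "per-SD-ldl":
            raise ValueError(f"expected scale 'per-SD-ldl', got {est.scale!r}")
        return replace(est, beta=est.beta * c, se=est.se * abs(c), scale="per-allele")
    if est.scale != "per-allele":
        raise ValueError(f"expected scale 'per-allele', got {est.scale!r}")
    return replace(est, beta=est.beta / c, se=est.se / abs(c), scale="per-SD-ldl")


def _check_common_scale(estimates: Sequence[SummaryEstimate]) -> None:
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"estimates on mixed scales cannot be pooled: {sorted(scales)}")


def ivw_meta(estimates: Iterable[SummaryEstimate]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    Weights ``w_i = se_i^-2``; pooled beta is the weighted mean, pooled
    se is ``(sum w_i)^-1/2``. Heterogeneity (Q, df, p_het) is filled via
    :func:`cochran_q`; for a single input Q=0, df=0 and p_het is NaN.
    """
    ests = list(estimates)
    if len(ests) == 0:
        raise ValueError("ivw_meta requires at least one estimate")
    _check_common_scale(ests)
    betas = np.array([e.beta for e in ests], dtype=float)
    w = np.array([e.se for e in ests], dtype=float) ** -2.0
    beta_pooled = float(np.sum(w * betas) / np.sum(w))
    se_pooled = float(np.sum(w) ** -0.5)
    p = wald_p(beta_pooled, se_pooled)
    if len(ests) >= 2:
        q, df, p_het = cochran_q(ests)
    else:
        q, df, p_het = 0.0, 0, float("nan")
    return MetaResult(beta=beta_pooled, se=se_pooled, p=p, q=q, df=df, p_het=p_het)


def cochran_q(estimates: Iterable[SummaryEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic.

    ``Q = sum w_i (beta_i - beta_pooled)^2`` with IVW-FE weights and pooled
    mean; under homogeneity Q ~ chi-square with df = k-1. Returns
    ``(q, df, p_het)``. Requires at least two estimates.
    """
    ests = list(estimates)
    if len(ests) < 2:
        raise ValueError("cochran_q requires at least two estimates")
    _check_common_scale(ests)
    betas = np.array([e.beta for e in ests], dtype=float)
    w = np.array([e.se for e in ests], dtype=float) ** -2.0
    beta_pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta_pooled) ** 2))
    df = len(ests) - 1
    p_het = float(stats.chi2.sf(q, df))
    return q, df, p_het


def bh_fdr(pvalues: Sequence[float], q_level: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``q_level``.

    Returns a boolean array aligned with the input: True where the
    hypothesis is rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return np.asarray(reject, dtype=bool)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def bonferroni_threshold(alpha: float, m: int, sig: int | None = 2) -> float:
    """Bonferroni-adjusted significance threshold ``alpha / m``.

    ``sig`` rounds to the given number of significant figures, matching how
    such thresholds are conventionally reported (0.05/7 -> 0.0071,
    0.05/48 -> 0.0010); pass ``sig=None`` for the exact value.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    t = alpha / m
    return t if sig is None else round_sig(t, sig)
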