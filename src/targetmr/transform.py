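"""Phenotype preparation: residualization and rank inverse-normal transform.

Continuous biomarkers (LDL-C, apolipoproteins, NMR measures) enter the
association pipeline after being regressed on baseline covariates within
each recruitment-region stratum, with the residuals mapped to standard
normal quantiles (RINT). The transformed variable has mean ~0 and SD ~1
inside every stratum, so downstream effect sizes are in SD units and
region-level location/scale differences cannot leak into genetic estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "TransformSpec",
    "CollinearityError",
    "residualize",
    "rint",
    "stratified_transform",
    "StratifiedRINT",
]

BLOM_OFFSET = 3.0 / 8.0


class CollinearityError(ValueError):
    """Raised when the covariate design matrix is rank deficient."""


@dataclass
class TransformSpec:
    """Configuration for a stratified residualize-then-RINT transform.

    ``covariates`` are column names of the design (an intercept is always
    added); ``strata`` names the stratifying column or is ``"none"``;
    ``rint_offset`` is the rank offset c in Phi^-1((r - c) / (n - 2c + 1)),
    default Blom's 3/8.
    """

    covariates: list[str] = field(default_factory=list)
    strata: str = "none"
    rint_offset: float = BLOM_OFFSET
    min_stratum_size: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.rint_offset <= 0.5:
            raise ValueError("rint_offset must lie in [0, 0.5]")


def _as_design(covariates) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, names


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    culprits = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            culprits.append(names[j])
    return culprits


def residualize(values, covariates) -> np.ndarray:
    """Ordinary least-squares residuals of ``values`` on ``covariates``.

    An intercept column is added automatically. Residuals are orthogonal to
    every covariate column. Rows must be complete (no NaN); a rank-deficient
    design raises :class:`CollinearityError` naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    X, names = _as_design(covariates)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {y.shape[0]} values vs {X.shape[0]} rows")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
        raise ValueError("residualize requires complete, finite rows")
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        culprits = _find_collinear(design, ["intercept"] + names)
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {culprits}"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def rint(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank inverse-normal transform.

    The value with (average, tie-aware) rank r maps to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``. Rank-preserving; output
    is approximately standard normal for continuous input.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("rint requires a 1-d vector of length >= 2")
    if np.any(~np.isfinite(y)):
        raise ValueError("rint requires finite values")
    if np.all(y == y[0]):
        raise ValueError("rint undefined: all values identical")
    ranks = stats.rankdata(y, method="average")
    n = y.size
    return ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))


def stratified_transform(
    values,
    covariates: pd.DataFrame,
    spec: TransformSpec,
) -> pd.Series:
    """Residualize then RINT, independently within each stratum.

    ``values`` is a Series (or array aligned with ``covariates``); rows with
    missing values or covariates are dropped listwise, and strata smaller
    than ``spec.min_stratum_size`` are dropped entirely (counts logged).
    Returns a Series aligned to the input index with NaN for dropped rows.
    """
    if not isinstance(covariates, pd.DataFrame):
        raise TypeError("covariates must be a DataFrame with named columns")
    if len(covariates) == 0:
        raise ValueError("empty input")
    y = pd.Series(np.asarray(values, dtype=float), index=covariates.index)
    cov_cols = list(spec.covariates)
    missing = [c for c in cov_cols if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns not found: {missing}")
    out = pd.Series(np.nan, index=covariates.index, dtype=float)

    usable = np.isfinite(y.to_numpy())
    if cov_cols:
        usable &= np.isfinite(covariates[cov_cols].to_numpy(dtype=float)).all(axis=1)
    n_dropped_missing = int((~usable).sum())
    if n_dropped_missing:
        logger.info("stratified_transform: %d rows dropped for missingness", n_dropped_missing)

    if spec.strata == "none" or spec.strata is None:
        groups = [(None, covariates.index[usable])]
    else:
        if spec.strata not in covariates.columns:
            raise KeyError(f"stratum column {spec.strata!r} not found")
        strat = covariates.loc[usable, spec.strata]
        groups = [(k, idx) for k, idx in strat.groupby(strat).groups.items()]

    n_small = 0
    for key, idx in groups:
        if len(idx) < spec.min_stratum_size:
            n_small += len(idx)
            logger.warning(
                "stratified_transform: stratum %r dropped (%d rows < minimum %d)",
                key, len(idx), spec.min_stratum_size,
            )
            continue
        sub_y = y.loc[idx].to_numpy()
        if cov_cols:
            resid = residualize(sub_y, covariates.loc[idx, cov_cols])
        else:
            resid = sub_y - sub_y.mean()
        out.loc[idx] = rint(resid, offset=spec.rint_offset)
    if n_small:
        logger.info("stratified_transform: %d rows in undersized strata excluded", n_small)
    return out


class StratifiedRINT(TransformerMixin, BaseEstimator):
    """Stratum-wise residualize-and-RINT as a scikit-learn transformer.

    Operates on a DataFrame ``X``; ``value_col`` names the phenotype column
    to transform, ``covariate_cols`` the adjustment design, ``stratum_col``
    the stratifying column (or None for a single stratum). ``transform``
    returns a single-column DataFrame aligned with the input (NaN for rows
    dropped by missingness or undersized strata).

    The transform is stateless across calls (ranks are recomputed per
    dataset, as in the analysis pipeline it mirrors); ``fit`` only validates
    columns and records bookkeeping attributes.
    """

    def __init__(
        self,
        value_col: str = "ldl_mmol",
        covariate_cols: Sequence[str] = (),
        stratum_col: str | None = None,
        offset: float = BLOM_OFFSET,
        min_stratum_size: int = 30,
    ) -> None:
        self.value_col = value_col
        self.covariate_cols = covariate_cols
        self.stratum_col = stratum_col
        self.offset = offset
        self.min_stratum_size = min_stratum_size

    def _spec(self) -> TransformSpec:
        return TransformSpec(
            covariates=list(self.covariate_cols),
            strata=self.stratum_col if self.stratum_col is not None else "none",
            rint_offset=self.offset,
            min_stratum_size=self.min_stratum_size,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "StratifiedRINT":
        if self.value_col not in X.columns:
            raise KeyError(f"value column {self.value_col!r} not found")
        self._spec()  # validates offset
        self.n_input_ = len(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_input_"):
            self.fit(X)
        aux_cols = list(self.covariate_cols)
        if self.stratum_col is not None:
            aux_cols.append(self.stratum_col)
        aux = X[aux_cols] if aux_cols else pd.DataFrame(index=X.index)
        transformed = stratified_transform(X[self.value_col], aux, self._spec())
        self.n_used_ = int(np.isfinite(transformed.to_numpy()).sum())
        return transformed.to_frame(name=f"rint_{self.value_col}")
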