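"""Locus and polygenic genetic scores calibrated to SD units of LDL-C.

The locus score is a weighted sum of dosages for a small set of
mutually-adjusted SNPs at a drug-target gene, with weights equal to their
joint per-allele effects on rank-inverse-normal-transformed LDL-C. Because
the weights are estimated in the same cohort in which the score is used,
participants contributing LDL-C data receive *jackknifed* weights: the
sample is partitioned into B random blocks (default 100) and each
participant's weights come from a refit that excluded their own block.
This removes the correlation between weight-estimation error and the
participant's own phenotype that otherwise inflates instrument-strength
statistics under weak or null effects. Participants outside the
weight-estimation sample receive the full-sample weights.

All weight fits are region-stratified ordinary least squares with
inverse-variance-weighted fixed-effect pooling of the per-region
coefficients. Fits are computed from per-stratum/per-block cross-products,
so the B leave-one-block-out refits cost B small linear solves rather than
B passes over the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator, TransformerMixin

from .meta import SummaryEstimate, ivw_meta

__all__ = [
    "ScoreWeights",
    "InstrumentDiagnostics",
    "fit_locus_weights",
    "assign_jackknife_blocks",
    "jackknife_weights",
    "build_score",
    "instrument_strength",
    "f_stat_from_r2",
    "build_polygenic_score",
    "LocusScoreModel",
]


@dataclass
class ScoreWeights:
    """Per-allele score weights, optionally with jackknife blocks.

    ``betas``/``ses`` are the full-sample mutually-adjusted per-allele
    effects on RINT LDL-C (SD units). When jackknifed, ``per_block_betas``
    row b holds the weights estimated *without* block b, and ``block_map``
    maps participant ids (of the estimation sample) to their block; everyone
    else implicitly uses the full-sample row.
    """

    snp_ids: list[str]
    betas: np.ndarray
    ses: np.ndarray
    n_blocks: int = 0
    per_block_betas: np.ndarray | None = None
    block_map: pd.Series | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if len(self.snp_ids) != self.betas.size or self.betas.size != self.ses.size:
            raise ValueError("snp_ids, betas and ses must have equal length")
        if self.per_block_betas is not None:
            self.per_block_betas = np.asarray(self.per_block_betas, dtype=float)
            if self.per_block_betas.shape != (self.n_blocks, self.betas.size):
                raise ValueError("per_block_betas must be (n_blocks, n_snps)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "beta": self.betas, "se": self.ses}
        )


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Strength of a genetic instrument for its exposure."""

    r_squared: float
    f_statistic: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.f_statistic < 0:
            raise ValueError("f_statistic must be non-negative")


def _validate_dosages(dosages: pd.DataFrame) -> None:
    arr = dosages.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("dosages contain missing values")
    counts = arr.sum(axis=0)
    n2 = 2 * arr.shape[0]
    for j, snp in enumerate(dosages.columns):
        mac = min(counts[j], n2 - counts[j])
        if arr[:, j].std() == 0 or mac < 2:
            raise ValueError(f"SNP {snp!r} is monomorphic (or <2 minor alleles) in the estimation sample")
    if arr.shape[1] > 1:
        corr = np.corrcoef(arr, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        bad = np.abs(corr[iu]) > 0.999
        if np.any(bad):
            pairs = [
                (dosages.columns[iu[0][k]], dosages.columns[iu[1][k]])
                for k in np.flatnonzero(bad)
            ]
            raise ValueError(f"collinear dosage columns (|r|>0.999): {pairs}")


def _xprod(X: np.ndarray, y: np.ndarray):
    return X.T @ X, X.T @ y, float(y @ y), len(y)


def _ols_from_xprod(A: np.ndarray, c: np.ndarray, yty: float, n: int):
    """Solve OLS from cross-products; returns (beta, se) or None if degenerate."""
    p = A.shape[0]
    if n < p:
        return None
    try:
        beta = np.linalg.solve(A, c)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    if n == p:  # saturated: beta defined, no residual dof for an SE
        return beta, np.full(p, np.inf)
    rss = max(yty - float(beta @ c), 0.0)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.clip(np.diag(Ainv) * sigma2, 0.0, None))
    return beta, se


def _design_blocks(dosages, covariates):
    G = dosages.to_numpy(dtype=float)
    parts = [G]
    if covariates is not None and np.size(covariates) > 0:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
    parts.append(np.ones((G.shape[0], 1)))
    return np.column_stack(parts)


def _pool_snp_estimates(per_stratum: list[tuple[np.ndarray, np.ndarray]], n_snps: int):
    """IVW-FE pool each SNP coefficient across strata."""
    if len(per_stratum) == 0:
        raise ValueError("no usable stratum for weight estimation")
    if len(per_stratum) == 1:
        beta, se = per_stratum[0]
        return beta[:n_snps].copy(), se[:n_snps].copy()
    betas = np.empty(n_snps)
    ses = np.empty(n_snps)
    for j in range(n_snps):
        pooled = ivw_meta(
            [
                SummaryEstimate(label=f"snp{j}", beta=float(b[j]), se=float(s[j]))
                for b, s in per_stratum
                if s[j] > 0 and np.isfinite(s[j])
            ]
        )
        betas[j], ses[j] = pooled.beta, pooled.se
    return betas, ses


def fit_locus_weights(
    dosages: pd.DataFrame,
    rint_ldl,
    covariates: pd.DataFrame | None = None,
    strata=None,
) -> ScoreWeights:
    """Mutually-adjusted per-allele weights from a joint stratified OLS fit.

    Regresses RINT LDL-C on all SNP dosage columns plus covariates (and an
    intercept) within each stratum, then pools each SNP's coefficient across
    strata by IVW-FE. Returns full-sample :class:`ScoreWeights`.
    """
    y = np.asarray(rint_ldl, dtype=float)
    if len(y) != len(dosages):
        raise ValueError("dosages and phenotype lengths differ")
    if np.any(~np.isfinite(y)):
        raise ValueError("phenotype must be complete in the estimation sample")
    _validate_dosages(dosages)
    X = _design_blocks(dosages, covariates)
    n_snps = dosages.shape[1]

    if strata is None:
        groups = [np.arange(len(y))]
    else:
        strat = np.asarray(strata)
        groups = [np.flatnonzero(strat == s) for s in pd.unique(strat)]

    per_stratum = []
    for idx in groups:
        res = _ols_from_xprod(*_xprod(X[idx], y[idx]))
        if res is not None:
            per_stratum.append(res)
    betas, ses = _pool_snp_estimates(per_stratum, n_snps)
    return ScoreWeights(snp_ids=[str(c) for c in dosages.columns], betas=betas, ses=ses)


def assign_jackknife_blocks(ids: Sequence, B: int = 100, seed: int = 0) -> pd.Series:
    """Random partition of participant ids into B near-equal blocks.

    Block sizes differ by at most one; the partition is a deterministic
    function of the seed. Returns a Series (index = ids, values = block
    index in 0..B-1).
    """
    ids = pd.Index(ids)
    n = len(ids)
    if B > n:
        raise ValueError(f"cannot form {B} blocks from {n} participants")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    blocks = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(perm, B)):
        blocks[chunk] = b
    return pd.Series(blocks, index=ids, name="block")


def jackknife_weights(
    dosages: pd.DataFrame,
    rint_ldl,
    covariates: pd.DataFrame | None = None,
    strata=None,
    jackknife_map: pd.Series | None = None,
) -> ScoreWeights:
    """Leave-one-block-out weight estimation.

    Row b of ``per_block_betas`` equals :func:`fit_locus_weights` on the
    sample excluding block b. Implemented by accumulating per-(stratum,
    block) cross-products and subtracting, so each refit is a small linear
    solve. Raises identifying the block if any leave-out fit is degenerate
    in every stratum.
    """
    if jackknife_map is None:
        raise ValueError("jackknife_map is required")
    y = np.asarray(rint_ldl, dtype=float)
    if not (len(y) == len(dosages) == len(jackknife_map)):
        raise ValueError("dosages, phenotype and jackknife_map lengths differ")
    full = fit_locus_weights(dosages, y, covariates, strata)
    X = _design_blocks(dosages, covariates)
    n_snps = dosages.shape[1]
    blocks = np.asarray(jackknife_map.to_numpy(), dtype=int)
    B = int(blocks.max()) + 1

    if strata is None:
        strat = np.zeros(len(y), dtype=int)
    else:
        strat = np.asarray(pd.factorize(np.asarray(strata))[0])
    n_strata = int(strat.max()) + 1

    p = X.shape[1]
    A_sb = np.zeros((n_strata, B, p, p))
    c_sb = np.zeros((n_strata, B, p))
    yty_sb = np.zeros((n_strata, B))
    n_sb = np.zeros((n_strata, B), dtype=int)
    for s in range(n_strata):
        for b in range(B):
            idx = np.flatnonzero((strat == s) & (blocks == b))
            if idx.size:
                Xi, yi = X[idx], y[idx]
                A_sb[s, b] = Xi.T @ Xi
                c_sb[s, b] = Xi.T @ yi
                yty_sb[s, b] = yi @ yi
                n_sb[s, b] = idx.size
    A_s = A_sb.sum(axis=1)
    c_s = c_sb.sum(axis=1)
    yty_s = yty_sb.sum(axis=1)
    n_s = n_sb.sum(axis=1)

    per_block = np.empty((B, n_snps))
    for b in range(B):
        per_stratum = []
        for s in range(n_strata):
            n_rem = int(n_s[s] - n_sb[s, b])
            if n_rem < p:
                continue
            res = _ols_from_xprod(
                A_s[s] - A_sb[s, b], c_s[s] - c_sb[s, b], float(yty_s[s] - yty_sb[s, b]), n_rem
            )
            if res is not None:
                per_stratum.append(res)
        if not per_stratum:
            raise ValueError(f"leave-one-out fit failed for jackknife block {b}")
        per_block[b], _ = _pool_snp_estimates(per_stratum, n_snps)

    return ScoreWeights(
        snp_ids=full.snp_ids,
        betas=full.betas,
        ses=full.ses,
        n_blocks=B,
        per_block_betas=per_block,
        block_map=jackknife_map,
    )


def build_score(dosages: pd.DataFrame, weights: ScoreWeights) -> pd.Series:
    """Weighted dosage sum, in predicted SDs of RINT LDL-C.

    Participants present in ``weights.block_map`` are scored with their
    block's leave-out weights; everyone else with the full-sample weights.
    Missing dosages are an error (no imputation).
    """
    missing = [s for s in weights.snp_ids if s not in dosages.columns]
    if missing:
        raise KeyError(f"dosage columns missing for SNPs: {missing}")
    G = dosages[weights.snp_ids].to_numpy(dtype=float)
    if np.any(~np.isfinite(G)):
        raise ValueError("missing dosage values; no imputation is performed")
    W = np.tile(weights.betas, (len(dosages), 1))
    if weights.per_block_betas is not None and weights.block_map is not None:
        in_map = dosages.index.isin(weights.block_map.index)
        if in_map.any():
            blocks = weights.block_map.reindex(dosages.index[in_map]).to_numpy(dtype=int)
            W[np.flatnonzero(in_map)] = weights.per_block_betas[blocks]
    return pd.Series((G * W).sum(axis=1), index=dosages.index, name="score")


def f_stat_from_r2(r_squared: float, n: int) -> float:
    """1-df instrument F from a partial R-squared: ``r2/(1-r2) * (n-2)``."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("r_squared must lie in [0, 1]")
    if r_squared == 1.0:
        return float("inf")
    return r_squared / (1.0 - r_squared) * (n - 2)


def instrument_strength(score, rint_ldl, covariates=None) -> InstrumentDiagnostics:
    """Partial R-squared and 1-df F of the score for the exposure.

    ``r_squared`` is the fraction of covariate-adjusted RINT LDL-C variance
    explained by the score; F uses the closed form
    ``r2/(1-r2)*(n-2)`` (infinite when the fit is exact).
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(rint_ldl, dtype=float)
    if len(s) != len(y):
        raise ValueError("score and phenotype lengths differ")
    if len(y) < 10:
        raise ValueError("need at least 10 complete rows")
    if np.any(~np.isfinite(s)) or np.any(~np.isfinite(y)):
        raise ValueError("instrument_strength requires complete rows")
    if covariates is not None and np.size(covariates) > 0:
        from .transform import residualize

        y = residualize(y, covariates)
        s = residualize(s, covariates)
    ys = y - y.mean()
    ss = s - s.mean()
    denom = math.sqrt(float(ys @ ys) * float(ss @ ss))
    if denom == 0:
        raise ValueError("score or phenotype has zero variance")
    r2 = min(float(ss @ ys) ** 2 / denom**2, 1.0)
    return InstrumentDiagnostics(
        r_squared=r2, f_statistic=f_stat_from_r2(r2, len(y)), n=len(y)
    )


def build_polygenic_score(
    dosages: pd.DataFrame,
    external_betas,
    external_ses,
    internal_betas,
    internal_ses,
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[list[str], pd.Series]:
    """Externally-weighted polygenic score with a consistency filter.

    Monomorphic SNPs are dropped first. A remaining SNP is kept when its
    internal effect estimate is directionally consistent with the external
    one, or when a two-sample heterogeneity z-test between the two is not
    significant at the Bonferroni level ``alpha / m`` (m defaults to the
    number of non-monomorphic candidates). The score is the dosage sum
    weighted by the *external* betas of the kept SNPs. Effect alleles must
    already be aligned between the two sources.
    """
    be = np.asarray(external_betas, dtype=float)
    se_e = np.asarray(external_ses, dtype=float)
    bi = np.asarray(internal_betas, dtype=float)
    se_i = np.asarray(internal_ses, dtype=float)
    snps = [str(c) for c in dosages.columns]
    if not (len(snps) == be.size == se_e.size == bi.size == se_i.size):
        raise ValueError("per-SNP vectors must align with dosage columns")

    arr = dosages.to_numpy(dtype=float)
    poly = arr.std(axis=0) > 0
    if m is None:
        m = int(poly.sum())
    if m < 1:
        raise ValueError("no polymorphic candidate SNPs")
    z_het = (bi - be) / np.sqrt(se_i**2 + se_e**2)
    p_het = 2.0 * special.ndtr(-np.abs(z_het))
    consistent = np.sign(bi) == np.sign(be)
    keep = poly & (consistent | (p_het >= alpha / m))
    kept = [s for s, k in zip(snps, keep) if k]
    score = pd.Series(
        arr[:, keep] @ be[keep], index=dosages.index, name="polygenic_score"
    )
    return kept, score


class LocusScoreModel(BaseEstimator, TransformerMixin):
    """Jackknife-weighted locus score as a scikit-learn estimator.

    ``fit(X, y)`` takes a DataFrame containing SNP dosage columns and
    covariate columns, and the RINT-transformed exposure ``y`` (NaN where
    unmeasured; those rows are excluded from weight estimation and later
    scored with full-sample weights). ``transform(X)`` returns the score.

    Parameters mirror the pipeline: ``snp_cols`` the locus SNPs,
    ``covariate_cols`` the adjustment design, ``stratum_col`` the region
    column (or None), ``n_blocks`` jackknife folds (``jackknife=False``
    gives naive full-sample internal weights, useful only to demonstrate
    the bias the jackknife removes).

    Attributes (after fit): ``weights_`` (:class:`ScoreWeights`),
    ``betas_``, ``ses_``, ``n_estimation_``.
    """

    def __init__(
        self,
        snp_cols: Sequence[str] = (),
        covariate_cols: Sequence[str] = (),
        stratum_col: str | None = None,
        n_blocks: int = 100,
        jackknife: bool = True,
        random_state: int = 0,
    ) -> None:
        self.snp_cols = snp_cols
        self.covariate_cols = covariate_cols
        self.stratum_col = stratum_col
        self.n_blocks = n_blocks
        self.jackknife = jackknife
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "LocusScoreModel":
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        est = X.index[np.isfinite(y.to_numpy())]
        dosages = X.loc[est, list(self.snp_cols)]
        cov = X.loc[est, list(self.covariate_cols)] if self.covariate_cols else None
        strata = X.loc[est, self.stratum_col] if self.stratum_col else None
        if self.jackknife:
            block_map = assign_jackknife_blocks(est, B=self.n_blocks, seed=self.random_state)
            self.weights_ = jackknife_weights(dosages, y.loc[est], cov, strata, block_map)
        else:
            self.weights_ = fit_locus_weights(dosages, y.loc[est], cov, strata)
        self.betas_ = self.weights_.betas
        self.ses_ = self.weights_.ses
        self.n_estimation_ = len(est)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "weights_"):
            raise ValueError("LocusScoreModel is not fitted")
        return build_score(X[list(self.snp_cols)], self.weights_)
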