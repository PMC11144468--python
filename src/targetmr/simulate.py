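"""Synthetic biobank cohort generator.

Emulates the statistical structure the downstream analysis assumes: ~10
recruitment regions; three locus SNPs (one rare loss-of-function variant)
with configurable haplotype-level LD and per-allele effects on standardized
LDL-C; an independent panel of polygenic LDL-C SNPs; baseline covariates
(age, sex, fasting time, height, genetic PCs); LDL-C measured in a random
subset; spirometry (FEV1/FVC) with a COPD liability and regions with
unusable spirometry; and multi-year event histories with ICD-10-style
codes, calendar years and fatal flags, generated from logistic outcome
models with either an LDL-C-mediated or a score-direct (pleiotropic) path.

Defaults are chosen to mirror a population-representative East Asian
biobank: LDL-C 2.36 (SD 0.69) mmol/L, locus per-allele effects
(0.65, 0.10, 0.16) SD with the loss-of-function variant at MAF 0.013, and
the locus explaining ~1.2% of LDL-C variance.

All randomness flows from a single config seed through named substreams,
so cohorts are bit-reproducible and any one component (genotypes, LDL,
outcomes, ...) is insensitive to whether the others were generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "OutcomeModel",
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_ldl",
    "simulate_outcomes",
    "simulate_spirometry",
    "simulate_covariates",
    "simulate_cohort",
    "LOCUS_SNPS",
]

LOCUS_SNPS = ["rs151193009", "rs2495477", "rs11206517"]

# Named substream indices under the config seed.
_STREAMS = {
    "covariates": 0,
    "genotypes": 1,
    "ldl": 2,
    "outcomes": 3,
    "spirometry": 4,
    "regions": 5,
    "grs_panel": 6,
    "missing": 7,
    "liability": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic generating model for one binary endpoint.

    Both log-odds coefficients are on the per-1-SD-**lower**-LDL-C
    (equivalent) scale, the orientation in which drug-target effects are
    reported: ``log_or_per_sd_ldl`` acts through measured LDL-C (the
    mediated path) and ``log_or_per_sd_score_direct`` acts through the
    locus score while bypassing LDL-C (a pleiotropic path, which is what
    gives instrument-heterogeneity tests something to detect). Cases get a
    uniform event year within follow-up and are fatal with probability
    ``fatal_fraction``.
    """

    outcome_id: str
    baseline_risk: float
    log_or_per_sd_ldl: float = 0.0
    log_or_per_sd_score_direct: float = 0.0
    fatal_fraction: float = 0.0
    code: str = ""

    def __post_init__(self) -> None:
        for name in ("baseline_risk", "fatal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")


def _default_covariate_effects() -> dict[str, float]:
    # Effects on LDL-C in mmol/L per unit of the centred covariate.
    return {"age": 0.006, "sex": 0.05, "fasting_time": -0.008}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; see module docstring for defaults.

    ``locus_ld`` is either ``"independent"`` or a vector of 8 haplotype
    frequencies over the 3 locus SNPs (index = 4*a1 + 2*a2 + a3, where a_j
    is the effect-allele indicator of SNP j); sampling two haplotypes per
    individual gives Hardy-Weinberg at the haplotype level.
    """

    n_participants: int = 100_000
    n_regions: int = 10
    locus_maf: tuple[float, float, float] = (0.013, 0.025, 0.013)
    locus_ld: object = "independent"
    locus_betas: tuple[float, float, float] = (0.65, 0.10, 0.16)
    grs_n_snps: int = 64
    grs_betas: np.ndarray | None = None
    grs_mafs: np.ndarray | None = None
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    ldl_mean_mmol: float = 2.36
    ldl_sd_mmol: float = 0.69
    ldl_measured_fraction: float = 0.25
    outcome_models: tuple[OutcomeModel, ...] = ()
    followup_years: float = 10.0
    baseline_year_range: tuple[int, int] = (2004, 2008)
    n_pcs: int = 2
    spirometry_bad_region_fraction: float = 0.2
    copd_liability_fraction: float = 0.10
    copd_liability_shift: float = -1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_regions < 1:
            raise ConfigurationError("n_participants and n_regions must be positive")
        if self.ldl_sd_mmol <= 0:
            raise ConfigurationError("ldl_sd_mmol must be positive")
        if len(self.locus_maf) != 3 or len(self.locus_betas) != 3:
            raise ConfigurationError("locus_maf and locus_betas must have length 3")
        for p in self.locus_maf:
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"MAF {p} outside [0, 1)")
        if not isinstance(self.locus_ld, str):
            h = np.asarray(self.locus_ld, dtype=float)
            if h.shape != (8,):
                raise ConfigurationError("haplotype table must have 8 frequencies")
            if np.any(h < 0):
                raise ConfigurationError("haplotype frequencies must be non-negative")
            if abs(h.sum() - 1.0) > 1e-12:
                raise ConfigurationError("haplotype frequencies must sum to 1 within 1e-12")
        elif self.locus_ld != "independent":
            raise ConfigurationError("locus_ld must be 'independent' or 8 haplotype frequencies")
        if self.followup_years <= 0:
            raise ConfigurationError("followup_years must be positive")
        if not 0.0 <= self.ldl_measured_fraction <= 1.0:
            raise ConfigurationError("ldl_measured_fraction must lie in [0, 1]")

    def grs_panel(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic (mafs, betas) for the polygenic SNP panel.

        Drawn once from the ``grs_panel`` substream unless supplied
        explicitly; per-allele effects are in SD-of-LDL units with random
        signs, magnitudes typical of genome-wide significant lipid loci.
        """
        if self.grs_mafs is not None and self.grs_betas is not None:
            return (
                np.asarray(self.grs_mafs, dtype=float),
                np.asarray(self.grs_betas, dtype=float),
            )
        rng = _rng(self.seed, "grs_panel")
        mafs = rng.uniform(0.05, 0.5, size=self.grs_n_snps)
        betas = rng.choice([-1.0, 1.0], size=self.grs_n_snps) * rng.uniform(
            0.02, 0.08, size=self.grs_n_snps
        )
        return mafs, betas

    def locus_variance_fraction(self) -> float:
        """Analytic fraction of LDL-C variance explained by the locus,
        ``sum_j 2 p_j (1-p_j) beta_j^2`` (betas in SD units, independent SNPs)."""
        p = np.asarray(self.locus_maf)
        b = np.asarray(self.locus_betas)
        return float(np.sum(2.0 * p * (1.0 - p) * b**2))


@dataclass
class Cohort:
    """A simulated cohort: participant table, dosage matrix, event history.

    ``participants`` is indexed by participant id and carries covariates,
    phenotypes and self-report flags; ``dosages`` is id-indexed with one
    column per SNP (values in [0, 2]); ``events`` has columns
    (id, code, year, fatal). ``latent`` holds generating quantities that a
    real cohort would not observe (complete LDL-C, true score, liabilities)
    for use in tests.
    """

    participants: pd.DataFrame
    dosages: pd.DataFrame
    events: pd.DataFrame
    config: SimulationConfig
    latent: dict = field(default_factory=dict)


def _haplotype_table(config: SimulationConfig) -> np.ndarray:
    if isinstance(config.locus_ld, str):
        p = np.asarray(config.locus_maf)
        freqs = np.empty(8)
        for h in range(8):
            bits = [(h >> (2 - j)) & 1 for j in range(3)]
            freqs[h] = np.prod([p[j] if bits[j] else 1 - p[j] for j in range(3)])
        return freqs
    return np.asarray(config.locus_ld, dtype=float)


_HAP_ALLELES = np.array([[(h >> 2) & 1, (h >> 1) & 1, h & 1] for h in range(8)])


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Dosage matrix: 3 locus SNPs from haplotype pairs, plus the GRS panel.

    Locus columns are sums of two haplotypes drawn from the haplotype
    frequency table (Hardy-Weinberg at the haplotype level); GRS columns
    are independent Binomial(2, maf).
    """
    rng = rng or _rng(config.seed, "genotypes")
    n = config.n_participants
    freqs = _haplotype_table(config)
    haps = rng.choice(8, size=(n, 2), p=freqs / freqs.sum())
    locus = _HAP_ALLELES[haps[:, 0]] + _HAP_ALLELES[haps[:, 1]]
    cols = {LOCUS_SNPS[j]: locus[:, j].astype(float) for j in range(3)}
    if config.grs_n_snps > 0:
        mafs, _ = config.grs_panel()
        grs = rng.binomial(2, mafs, size=(n, config.grs_n_snps)).astype(float)
        for k in range(config.grs_n_snps):
            cols[f"grs_{k:03d}"] = grs[:, k]
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="id"))


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Baseline covariate table: region, age, sex, fasting time, height,
    genetic PCs, baseline year, ascertainment category and self-report flags."""
    rng = rng or _rng(config.seed, "covariates")
    n = config.n_participants
    region = rng.integers(0, config.n_regions, size=n)
    age = rng.uniform(30.0, 79.0, size=n)
    sex = (rng.uniform(size=n) < 0.597).astype(int)  # 1 = female
    fasting = np.clip(rng.gamma(2.0, 2.0, size=n), 0.25, 16.0)
    height = np.where(sex == 1, rng.normal(152.0, 6.0, n), rng.normal(165.0, 6.0, n))
    baseline_year = rng.integers(
        config.baseline_year_range[0], config.baseline_year_range[1] + 1, size=n
    )
    ascertainment = rng.choice(
        ["population", "cvd_case_control", "respiratory_case_control"],
        size=n,
        p=[0.8, 0.1, 0.1],
    )
    df = pd.DataFrame(
        {
            "region": region,
            "age": age,
            "sex": sex,
            "fasting_time": fasting,
            "height": height,
            "baseline_year": baseline_year,
            "ascertainment_category": ascertainment,
            "self_report_chd": rng.uniform(size=n) < 0.036,
            "self_report_stroke_tia": rng.uniform(size=n) < 0.017,
            "self_report_diabetes": rng.uniform(size=n) < 0.061,
            "self_report_asthma": rng.uniform(size=n) < 0.010,
            "self_report_copd": rng.uniform(size=n) < 0.020,
        },
        index=pd.RangeIndex(n, name="id"),
    )
    for k in range(config.n_pcs):
        df[f"pc{k + 1}"] = rng.normal(size=n)
    return df


def simulate_ldl(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent and observed LDL-C (mmol/L).

    ``ldl = mean + region intercept + covariate effects + sd * sum_j beta_j
    (g_j - 2 p_j) + noise``, with the noise variance set so the marginal SD
    is approximately ``ldl_sd_mmol``. Returns ``(latent, observed)`` where
    ``observed`` has NaN outside the randomly measured subset (MCAR).
    """
    if len(genotypes) != len(covariates):
        raise ValueError("genotype and covariate tables must have aligned rows")
    rng = rng or _rng(config.seed, "ldl")
    region_rng = _rng(config.seed, "regions")
    n = len(covariates)
    sd = config.ldl_sd_mmol

    region_fx = region_rng.normal(0.0, 0.05, size=config.n_regions)
    region_fx -= region_fx.mean()  # sum-to-zero so the marginal mean stays configured
    systematic = region_fx[covariates["region"].to_numpy()]
    for name, eff in config.covariate_effects.items():
        x = covariates[name].to_numpy(dtype=float)
        systematic = systematic + eff * (x - x.mean())

    mafs_all = list(config.locus_maf)
    betas_all = list(config.locus_betas)
    snp_ids = list(LOCUS_SNPS)
    if config.grs_n_snps > 0:
        gm, gb = config.grs_panel()
        mafs_all += list(gm)
        betas_all += list(gb)
        snp_ids += [f"grs_{k:03d}" for k in range(config.grs_n_snps)]
    G = genotypes[snp_ids].to_numpy(dtype=float)
    p = np.asarray(mafs_all)
    b = np.asarray(betas_all)
    genetic = sd * ((G - 2.0 * p) @ b)
    var_g = float(np.sum(2.0 * p * (1.0 - p) * b**2))  # in SD^2 units

    noise_var = max(sd**2 * (1.0 - var_g) - systematic.var(), (0.25 * sd) ** 2)
    latent = config.ldl_mean_mmol + systematic + genetic + rng.normal(0.0, np.sqrt(noise_var), n)

    miss_rng = _rng(config.seed, "missing")
    measured = miss_rng.uniform(size=n) < config.ldl_measured_fraction
    observed = np.where(measured, latent, np.nan)
    return latent, observed


def simulate_outcomes(
    config: SimulationConfig,
    ldl_std,
    score,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event histories from the configured logistic outcome models.

    ``ldl_std`` is latent LDL-C in SD units; ``score`` is the (true) locus
    score in SD-of-LDL units. Coefficients are per 1-SD-*lower* exposure,
    so the linear predictor uses the negated centred values. Returns
    ``(events, case_table)``: a long (id, code, year, fatal) table and an
    id-indexed boolean table with one column per outcome_id.
    """
    rng = rng or _rng(config.seed, "outcomes")
    n = len(covariates)
    ldl_c = np.asarray(ldl_std, dtype=float)
    ldl_c = ldl_c - ldl_c.mean()
    sc = np.asarray(score, dtype=float)
    sc = sc - sc.mean()
    rows = []
    cases = {}
    baseline = covariates["baseline_year"].to_numpy()
    for om in config.outcome_models:
        eta = (
            logit(om.baseline_risk)
            + om.log_or_per_sd_ldl * (-ldl_c)
            + om.log_or_per_sd_score_direct * (-sc)
        )
        case = rng.uniform(size=n) < expit(eta)
        cases[om.outcome_id] = case
        idx = np.flatnonzero(case)
        years = baseline[idx] + rng.uniform(0.0, config.followup_years, size=idx.size)
        fatal = rng.uniform(size=idx.size) < om.fatal_fraction
        for i, yr, f in zip(idx, years, fatal):
            rows.append((i, om.code or om.outcome_id, float(yr), bool(f)))
    events = pd.DataFrame(rows, columns=["id", "code", "year", "fatal"])
    case_table = pd.DataFrame(cases, index=covariates.index)
    return events, case_table


def simulate_spirometry(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    copd_liability=None,
    lms_ref=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FEV1 and FVC (litres) plus a per-row spirometry-usable flag.

    FVC follows a log-scale height/age/sex mean model with lognormal noise;
    FEV1 = FVC * ratio, with the ratio drawn from the LMS reference
    distribution at z ~ N(0, 1) + liability (negative liability shifts the
    ratio down, creating airflow obstruction). A fixed set of regions
    (``spirometry_bad_region_fraction`` of them) is flagged unusable,
    mimicking systematic collection errors.
    """
    from .respiratory import default_lms_reference, ratio_from_z

    rng = rng or _rng(config.seed, "spirometry")
    ref = lms_ref if lms_ref is not None else default_lms_reference()
    n = len(covariates)
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=int)
    height = covariates["height"].to_numpy(dtype=float)
    if copd_liability is None:
        copd_liability = np.zeros(n)
    liab = np.asarray(copd_liability, dtype=float)

    log_fvc = (
        np.log(2.9)
        + 2.0 * np.log(height / 160.0)
        - 0.006 * (age - 50.0)
        + 0.25 * (sex == 0)
        + rng.normal(0.0, 0.12, n)
    )
    fvc = np.exp(log_fvc)
    z = rng.normal(size=n) + liab
    ratio = ratio_from_z(z, age, sex, height, ref)
    fev1 = fvc * np.clip(ratio, 0.05, 1.0)

    n_bad = int(round(config.spirometry_bad_region_fraction * config.n_regions))
    bad_regions = set(range(config.n_regions - n_bad, config.n_regions))
    usable = ~covariates["region"].isin(bad_regions).to_numpy()
    return fev1, fvc, usable


def default_outcome_models() -> tuple[OutcomeModel, ...]:
    """A small endpoint panel with realistic effect magnitudes: a protective
    LDL-mediated vascular outcome, a harmful score-direct respiratory
    outcome, and null endpoints."""
    return (
        OutcomeModel("move", 0.10, log_or_per_sd_ldl=np.log(0.80), code="I21", fatal_fraction=0.2),
        OutcomeModel("urti", 0.02, log_or_per_sd_score_direct=np.log(2.18), code="J06"),
        OutcomeModel("copd_hosp", 0.05, log_or_per_sd_score_direct=np.log(1.38), code="J44", fatal_fraction=0.2),
        OutcomeModel("null_a", 0.05, code="K29"),
        OutcomeModel("null_b", 0.02, code="N20"),
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort assembly: covariates, genotypes, LDL-C, spirometry and
    event histories, wired together exactly as the analysis assumes."""
    covariates = simulate_covariates(config)
    dosages = simulate_genotypes(config)
    ldl_latent, ldl_obs = simulate_ldl(config, dosages, covariates)

    true_score = dosages[LOCUS_SNPS].to_numpy() @ np.asarray(config.locus_betas)
    ldl_std = (ldl_latent - config.ldl_mean_mmol) / config.ldl_sd_mmol
    events, case_table = simulate_outcomes(config, ldl_std, true_score, covariates)

    liab_rng = _rng(config.seed, "liability")
    liab = np.where(
        liab_rng.uniform(size=len(covariates)) < config.copd_liability_fraction,
        config.copd_liability_shift,
        0.0,
    )
    fev1, fvc, usable = simulate_spirometry(config, covariates, copd_liability=liab)

    participants = covariates.copy()
    participants["ldl_mmol"] = ldl_obs
    participants["fev1"] = fev1
    participants["fvc"] = np.maximum(fvc, fev1)
    participants["spirometry_usable"] = usable

    return Cohort(
        participants=participants,
        dosages=dosages,
        events=events,
        config=config,
        latent={
            "ldl_latent": ldl_latent,
            "true_score": true_score,
            "copd_liability": liab,
            "case_table": case_table,
        },
    )
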