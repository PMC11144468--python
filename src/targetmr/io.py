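"""File readers/writers and pipeline configuration.

TSV is the canonical interchange format: a phenotype/covariate table, a
dosage matrix (header = SNP ids, index = participant id), a long event
table (id, code, year, fatal), a weights manifest and result tables. VCF
dosage input (per-sample ``DS`` FORMAT field) is supported read-only via
cyvcf2 when installed. Configuration is YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .score import ScoreWeights
from .simulate import Cohort, SimulationConfig, OutcomeModel

__all__ = [
    "PipelineConfig",
    "read_dosages",
    "write_dosages_tsv",
    "read_phenotypes",
    "read_events",
    "write_cohort",
    "read_cohort",
    "write_weights",
    "read_weights",
    "write_results",
    "read_summary_estimates",
    "published_estimates",
]

_DATA_DIR = Path(__file__).parent / "data"


def _to_native(obj):
    """Recursively convert numpy scalars/arrays so YAML can represent them."""
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_native(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineConfig:
    """Paths, transform settings and seeds for a full pipeline run."""

    output_dir: str = "results"
    phenotype_path: str | None = None
    dosage_path: str | None = None
    event_path: str | None = None
    seed: int = 0
    n_blocks: int = 100
    min_stratum_cases: int = 5
    min_stratum_size: int = 30
    rint_offset: float = 0.375
    covariates: list[str] = field(default_factory=lambda: ["age", "age2", "sex", "fasting_time"])
    assoc_covariates: list[str] = field(default_factory=lambda: ["age", "age2", "sex"])
    stratum_col: str = "region"
    simulation: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation or {})
        outcome_models = tuple(
            OutcomeModel(**om) for om in sim.pop("outcome_models", [])
        )
        sim.setdefault("seed", self.seed)
        cfg = SimulationConfig(**sim)
        if outcome_models:
            cfg.outcome_models = outcome_models
        return cfg


def _validate_dosage_frame(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~((arr >= 0) & (arr <= 2)) & np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"dosage out of [0, 2] at participant {df.index[r]!r}, SNP {df.columns[c]!r}: {arr[r, c]}"
        )
    nan = np.argwhere(~np.isfinite(arr))
    if nan.size:
        r, c = nan[0]
        raise ValueError(f"missing dosage at participant {df.index[r]!r}, SNP {df.columns[c]!r}")
    return df.astype(float)


def read_dosages(path, fmt: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dosage matrix from TSV or VCF.

    Returns ``(dosages, manifest)``: an id-indexed matrix with one column
    per SNP (validated in [0, 2]) and a manifest recording SNP id, ref/alt
    (effect) alleles where known. Format is inferred from the extension
    unless ``fmt`` is given. VCF requires a per-sample ``DS`` FORMAT field.
    """
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = _validate_dosage_frame(df)
        manifest = pd.DataFrame(
            {"snp_id": df.columns, "ref": "", "effect_allele": "", "source": str(path)}
        )
        return df, manifest
    if fmt == "vcf":
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover
            raise ImportError("VCF input requires cyvcf2") from exc
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        cols, rows = [], []
        for variant in vcf:
            ds = variant.format("DS")
            if ds is None:
                raise ValueError(f"variant {variant.ID or variant.POS} lacks a DS FORMAT field")
            cols.append(
                {
                    "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                    "ref": variant.REF,
                    "effect_allele": variant.ALT[0] if variant.ALT else "",
                    "source": str(path),
                }
            )
            rows.append(np.asarray(ds, dtype=float).reshape(-1))
        manifest = pd.DataFrame(cols)
        df = pd.DataFrame(
            np.column_stack(rows) if rows else np.empty((len(samples), 0)),
            index=pd.Index(samples, name="id"),
            columns=manifest["snp_id"].tolist(),
        )
        return _validate_dosage_frame(df), manifest
    raise ValueError(f"unknown dosage format {fmt!r}")


def write_dosages_tsv(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index_label="id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "code", "year", "fatal"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    df["fatal"] = df["fatal"].astype(bool)
    return df


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write a cohort as phenotypes.tsv, dosages.tsv, events.tsv, config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": str(outdir / "phenotypes.tsv"),
        "dosages": str(outdir / "dosages.tsv"),
        "events": str(outdir / "events.tsv"),
        "config": str(outdir / "config.yaml"),
    }
    cohort.participants.to_csv(paths["phenotypes"], sep="\t", index_label="id")
    write_dosages_tsv(cohort.dosages, paths["dosages"])
    cohort.events.to_csv(paths["events"], sep="\t", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["outcome_models"] = [dataclasses.asdict(om) for om in cohort.config.outcome_models]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_to_native(cfg), fh)
    return paths


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    outcome_models = tuple(OutcomeModel(**om) for om in cfg.pop("outcome_models", []))
    for key in ("locus_maf", "locus_betas", "baseline_year_range"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    config = SimulationConfig(**cfg)
    config.outcome_models = outcome_models
    dosages, _ = read_dosages(indir / "dosages.tsv", fmt="tsv")
    return Cohort(
        participants=read_phenotypes(indir / "phenotypes.tsv"),
        dosages=dosages,
        events=read_events(indir / "events.tsv"),
        config=config,
    )


def write_weights(weights: ScoreWeights, path, per_block_path=None) -> None:
    """Weights manifest TSV (snp_id, beta, se) and optional per-block TSV."""
    weights.to_frame().to_csv(path, sep="\t", index=False)
    if per_block_path is not None and weights.per_block_betas is not None:
        pb = pd.DataFrame(weights.per_block_betas, columns=weights.snp_ids)
        pb.insert(0, "block", np.arange(weights.n_blocks))
        pb.to_csv(per_block_path, sep="\t", index=False)


def read_weights(path, per_block_path=None, block_map=None) -> ScoreWeights:
    df = pd.read_csv(path, sep="\t")
    per_block = None
    n_blocks = 0
    if per_block_path is not None:
        pb = pd.read_csv(per_block_path, sep="\t").drop(columns="block")
        per_block = pb.to_numpy(dtype=float)
        n_blocks = per_block.shape[0]
    return ScoreWeights(
        snp_ids=[str(s) for s in df["snp_id"]],
        betas=df["beta"].to_numpy(dtype=float),
        ses=df["se"].to_numpy(dtype=float),
        n_blocks=n_blocks,
        per_block_betas=per_block,
        block_map=block_map,
    )


def write_results(estimates, path) -> None:
    """Write a list of EffectEstimate (or a DataFrame) as a results TSV."""
    if isinstance(estimates, pd.DataFrame):
        estimates.to_csv(path, sep="\t")
        return
    rows = []
    for e in estimates:
        lo, hi = e.beta - 1.959963984540054 * e.se, e.beta + 1.959963984540054 * e.se
        rows.append(
            {
                "outcome_id": e.outcome_id,
                "n_cases": e.n_cases,
                "n_controls": e.n_controls,
                "n": e.n,
                "beta": e.beta,
                "se": e.se,
                "or": float(np.exp(e.beta)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "p": e.p,
                "unit": e.unit,
                "orientation": e.orientation,
                "strata_pooled": e.n_strata,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_summary_estimates(path) -> pd.DataFrame:
    """Read a summary-estimate TSV: label, source, or, ci_low, ci_high, scale."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "source", "or", "ci_low", "ci_high"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary table must have columns {sorted(required)}")
    if "scale" not in df.columns:
        df["scale"] = "per-SD-ldl"
    return df


def published_estimates() -> pd.DataFrame:
    """The bundled table of published per-1-SD-lower-LDL-C effect estimates
    (odds ratios with 95% CIs) used by the worked examples."""
    return read_summary_estimates(_DATA_DIR / "published_estimates.tsv")
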