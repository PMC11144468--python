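"""Spirometry-based COPD classification and respiratory event typing.

Prevalent COPD at baseline is defined as FEV1/FVC below the lower limit of
normal (LLN), the 5th centile of the reference distribution from an LMS
(lambda-mu-sigma) spirometry reference framework: for covariates x,

    z = ((ratio / M(x))^L(x) - 1) / (L(x) * S(x)),   L -> 0: ln(ratio/M)/S

and the LLN is z < Phi^-1(centile). Reference coefficient tables (L, M, S
as functions of age, sex and height) are pluggable via YAML; the package
ships a self-consistent synthetic default so nothing external is needed.

Follow-up COPD events are then typed relative to baseline status:
an event in a participant with spirometry-defined prevalent COPD is an
*exacerbation* (fatal if any such event is fatal, i.e. COPD recorded as
cause of death); an event in a non-prevalent participant is *incident*;
prevalent COPD with no event is *prevalent-only*. Regions with unusable
spirometry are excluded up front. Upper-respiratory-tract-infection (URTI)
cases can be filtered by calendar year to avoid reporting-spike artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

__all__ = [
    "LmsReference",
    "CopdEventClassification",
    "default_lms_reference",
    "lms_zscore",
    "ratio_from_z",
    "prevalent_copd",
    "classify_copd_events",
    "urti_filter",
    "spike_report",
]

COPD_CATEGORIES = (
    "none",
    "prevalent-only",
    "incident-fatal",
    "incident-nonfatal",
    "exacerbation-fatal",
    "exacerbation-nonfatal",
)


@dataclass
class LmsReference:
    """Polynomial L/M/S coefficient tables for the FEV1/FVC ratio.

    For each sex key (``"male"``/``"female"``): ``L`` and ``S`` are
    polynomial coefficients in age (ascending order, evaluated at
    ``(age - 50)/10``); ``M`` is ``exp(poly_age((age-50)/10) +
    log_height_coef * ln(height/160))``, which keeps M positive over the
    supported age range. ``centile`` defines the lower limit of normal.
    """

    sexes: Mapping[str, Mapping[str, object]]
    centile: float = 0.05
    age_range: tuple[float, float] = (30.0, 79.0)
    ancestry: str = "synthetic-default"

    def _sex_key(self, sex) -> str:
        if isinstance(sex, str):
            return sex
        return "female" if int(sex) == 1 else "male"

    def coefficients(self, age, sex, height):
        """Vectorized (L, M, S) at the given covariates."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        height = np.atleast_1d(np.asarray(height, dtype=float))
        sex_arr = np.atleast_1d(np.asarray(sex))
        t = (age - 50.0) / 10.0
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for key in ("male", "female"):
            tab = self.sexes[key]
            mask = np.array([self._sex_key(s) == key for s in sex_arr])
            if not mask.any():
                continue
            L[mask] = np.polyval(list(reversed(tab["L"])), t[mask])
            m_log = np.polyval(list(reversed(tab["M"]["poly_age"])), t[mask])
            m_log = m_log + tab["M"].get("log_height_coef", 0.0) * np.log(
                height[mask] / 160.0
            )
            M[mask] = np.exp(m_log)
            S[mask] = np.polyval(list(reversed(tab["S"])), t[mask])
        if np.any(M <= 0) or np.any(S <= 0):
            raise ValueError("LMS reference must have M > 0 and S > 0")
        return L, M, S

    def to_yaml(self, path) -> None:
        payload = {
            "centile": float(self.centile),
            "age_range": [float(a) for a in self.age_range],
            "ancestry": self.ancestry,
            "sexes": {
                k: {
                    "L": [float(x) for x in v["L"]],
                    "M": {
                        "poly_age": [float(x) for x in v["M"]["poly_age"]],
                        "log_height_coef": float(v["M"].get("log_height_coef", 0.0)),
                    },
                    "S": [float(x) for x in v["S"]],
                }
                for k, v in self.sexes.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "LmsReference":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            sexes=d["sexes"],
            centile=float(d.get("centile", 0.05)),
            age_range=tuple(d.get("age_range", (30.0, 79.0))),
            ancestry=d.get("ancestry", "unspecified"),
        )


def default_lms_reference() -> LmsReference:
    """Self-consistent synthetic LMS reference for FEV1/FVC.

    Synthetic stand-in for a published reference-equation table: a mild
    age decline in the median ratio, near-constant coefficient of
    variation, and a Box-Cox lambda of 1. Suitable for exercising the
    framework and the simulator; not for clinical interpretation.
    """
    return LmsReference(
        sexes={
            "male": {
                "L": [1.0],
                "M": {"poly_age": [np.log(0.79), -0.025], "log_height_coef": 0.0},
                "S": [0.075],
            },
            "female": {
                "L": [1.0],
                "M": {"poly_age": [np.log(0.81), -0.022], "log_height_coef": 0.0},
                "S": [0.070],
            },
        }
    )


def lms_zscore(ratio, age, sex, height, ref: LmsReference, extrapolate: bool = False):
    """LMS z-score for an observed FEV1/FVC ratio.

    ``z = ((ratio/M)^L - 1) / (L S)`` with the L->0 limit ``ln(ratio/M)/S``.
    Ages outside the reference range raise unless ``extrapolate=True``.
    Strictly increasing in the ratio for fixed covariates.
    """
    ratio_arr = np.atleast_1d(np.asarray(ratio, dtype=float))
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(ratio_arr <= 0) or np.any(ratio_arr > 1.5):
        raise ValueError("FEV1/FVC ratio must lie in (0, 1.5]")
    lo, hi = ref.age_range
    if not extrapolate and (np.any(age_arr < lo) or np.any(age_arr > hi)):
        raise ValueError(
            f"age outside reference range [{lo}, {hi}]; pass extrapolate=True to override"
        )
    L, M, S = ref.coefficients(age_arr, sex, np.atleast_1d(np.asarray(height, dtype=float)))
    z = np.where(
        np.abs(L) < 1e-7,
        np.log(ratio_arr / M) / S,
        ((ratio_arr / M) ** np.where(np.abs(L) < 1e-7, 1.0, L) - 1.0)
        / (np.where(np.abs(L) < 1e-7, 1.0, L) * S),
    )
    return z if np.ndim(ratio) else float(z[0])


def ratio_from_z(z, age, sex, height, ref: LmsReference):
    """Inverse of :func:`lms_zscore`: the ratio at a given reference z."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    L, M, S = ref.coefficients(
        np.atleast_1d(np.asarray(age, dtype=float)),
        sex,
        np.atleast_1d(np.asarray(height, dtype=float)),
    )
    small = np.abs(L) < 1e-7
    Lsafe = np.where(small, 1.0, L)
    ratio = np.where(
        small,
        M * np.exp(S * z),
        M * np.clip(1.0 + Lsafe * S * z, 1e-6, None) ** (1.0 / Lsafe),
    )
    return ratio


def prevalent_copd(z, centile: float = 0.05) -> np.ndarray:
    """Below-LLN flag: ``z < Phi^-1(centile)`` (strict inequality)."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return z < ndtri(centile)


@dataclass(frozen=True)
class CopdEventClassification:
    participant_id: object
    category: str
    first_event_year: float | None = None

    def __post_init__(self) -> None:
        if self.category not in COPD_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _match_codes(codes: pd.Series, patterns: Sequence[str]) -> np.ndarray:
    pats = tuple(patterns)
    return codes.astype(str).str.startswith(pats).to_numpy()


def classify_copd_events(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    prevalent: pd.Series,
    copd_codes: Sequence[str] = ("J41", "J42", "J43", "J44"),
    usable: pd.Series | None = None,
) -> pd.DataFrame:
    """Type each spirometry-usable participant's COPD history.

    ``prevalent`` is a boolean Series (id-indexed) of spirometry-defined
    baseline COPD; ``usable`` optionally marks rows with usable spirometry
    (others are excluded from the output entirely). Events must occur during
    follow-up (``year >= baseline_year``); earlier events are an error.
    Returns a DataFrame (id, category, first_event_year) whose categories
    partition the usable cohort.
    """
    if usable is not None:
        keep = participants.index[usable.reindex(participants.index).fillna(False)]
    else:
        keep = participants.index
    prev = prevalent.reindex(keep).fillna(False)

    ev = events[events["id"].isin(keep)]
    ev = ev[_match_codes(ev["code"], copd_codes)]
    if len(ev):
        base = participants.loc[ev["id"], "baseline_year"].to_numpy()
        if np.any(ev["year"].to_numpy() < base):
            raise ValueError("COPD events before baseline: event history must be follow-up only")

    grouped = ev.groupby("id").agg(
        first_event_year=("year", "min"), any_fatal=("fatal", "any")
    )
    rows = []
    for pid in keep:
        has_event = pid in grouped.index
        is_prev = bool(prev.loc[pid])
        if has_event:
            fatal = bool(grouped.loc[pid, "any_fatal"])
            year = float(grouped.loc[pid, "first_event_year"])
            kind = "exacerbation" if is_prev else "incident"
            cat = f"{kind}-{'fatal' if fatal else 'nonfatal'}"
        else:
            year = np.nan
            cat = "prevalent-only" if is_prev else "none"
        rows.append((pid, cat, year))
    return pd.DataFrame(rows, columns=["id", "category", "first_event_year"]).set_index("id")


def urti_filter(
    events: pd.DataFrame,
    min_year: float = 2009,
    region_exclusions: Iterable[tuple[int, tuple[float, float]]] = (),
    regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep URTI case events from ``min_year`` onwards.

    ``region_exclusions`` is an iterable of ``(region, (year_lo, year_hi))``
    windows to drop (requires ``regions``, an id-indexed Series mapping
    participants to regions). Use ``min_year=-inf`` for the identity.
    """
    out = events[events["year"] >= min_year]
    for region, (lo, hi) in region_exclusions:
        if regions is None:
            raise ValueError("region_exclusions requires an id->region mapping")
        ev_region = regions.reindex(out["id"]).to_numpy()
        drop = (ev_region == region) & (out["year"].to_numpy() >= lo) & (
            out["year"].to_numpy() <= hi
        )
        out = out[~drop]
    return out


def spike_report(
    events: pd.DataFrame,
    regions: pd.Series,
    window: tuple[float, float],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Flag regions holding more than ``threshold`` of all cases in a window.

    Returns a per-region table with the fraction of *all* events (across all
    years and regions) that fall in that region within the window, and a
    ``flagged`` column — the diagnostic that motivates calendar-year
    exclusions of reporting spikes.
    """
    total = len(events)
    if total == 0:
        return pd.DataFrame(columns=["n_in_window", "fraction_of_all", "flagged"])
    ev_region = regions.reindex(events["id"]).to_numpy()
    in_window = (events["year"].to_numpy() >= window[0]) & (
        events["year"].to_numpy() <= window[1]
    )
    out = []
    for region in pd.unique(regions):
        n = int(np.sum(in_window & (ev_region == region)))
        frac = n / total
        out.append((region, n, frac, frac > threshold))
    return pd.DataFrame(
        out, columns=["region", "n_in_window", "fraction_of_all", "flagged"]
    ).set_index("region")
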