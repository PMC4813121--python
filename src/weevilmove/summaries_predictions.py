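"""Descriptive summaries and model-based prediction surfaces.

Covers the study's descriptive outputs: the night-activity profile (share of
individuals moving per time bin), per-sex crossing statistics, predicted
movement-probability surfaces over pairs of covariates (population-typical:
random effects at 0), and the density-response switch point — the
neighboring density at which the marginal effect of local density on the
movement log-odds changes sign.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .experiment_sim import ModelCoefficients, movement_probability

logger = logging.getLogger(__name__)

#: covariate context of the published density surface: 120 min into the
#: night, both sex ratios at the 1:1 release value
DENSITY_SURFACE_CONTEXT = {
    "time": 120.0, "local_sex_ratio": 0.5, "neighboring_sex_ratio": 0.5,
    "sex": 0.0, "bulb_age": 0.0,
}
#: context of the sex-ratio surface: both densities at 20 individuals
SEX_RATIO_SURFACE_CONTEXT = {
    "time": 120.0, "local_density": 20.0, "neighboring_density": 20.0,
    "bulb_age": 0.0,
}


# ---------------------------------------------------------------------------
# activity profile
# ---------------------------------------------------------------------------

@dataclass
class ActivityProfile:
    bin_start_min: np.ndarray
    bin_end_min: np.ndarray
    pct_moving: np.ndarray       # mean across replicates, in percent
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_min": self.bin_start_min,
            "bin_end_min": self.bin_end_min,
            "pct_moving": self.pct_moving,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def activity_profile(
    crossings: pd.DataFrame,
    roster: pd.DataFrame,
    bin_min: float = 30.0,
    night_length_min: int = 720,
) -> ActivityProfile:
    """Percentage of individuals completing >= 1 crossing per time bin.

    Computed per replicate, then averaged; 95% CIs use the across-replicate
    normal approximation.  Percentages are clipped to [0, 100].
    """
    if bin_min <= 0:
        raise ValueError("bin_min must be positive")
    n_bins = int(math.ceil(night_length_min / bin_min))
    edges = np.arange(n_bins + 1) * bin_min * 60.0
    rep_ids = roster["replicate_id"].unique()
    per_rep = np.zeros((len(rep_ids), n_bins))
    for k, rep in enumerate(rep_ids):
        ros = roster[roster["replicate_id"] == rep]
        cross = crossings[crossings["replicate_id"] == rep]
        n_ind = len(ros)
        for b in range(n_bins):
            sel = cross[(cross["end_s"] >= edges[b]) &
                        (cross["end_s"] < edges[b + 1])]
            per_rep[k, b] = 100.0 * sel["tag_id"].nunique() / n_ind
    mean = per_rep.mean(axis=0)
    if len(rep_ids) > 1:
        sem = per_rep.std(axis=0, ddof=1) / math.sqrt(len(rep_ids))
    else:
        sem = np.zeros(n_bins)
    return ActivityProfile(
        bin_start_min=edges[:-1] / 60.0,
        bin_end_min=edges[1:] / 60.0,
        pct_moving=mean,
        ci_low=np.clip(mean - 1.959964 * sem, 0.0, 100.0),
        ci_high=np.clip(mean + 1.959964 * sem, 0.0, 100.0),
        n_replicates=len(rep_ids),
    )


# ---------------------------------------------------------------------------
# prediction surfaces
# ---------------------------------------------------------------------------

def predict_surface(
    coefficients: ModelCoefficients,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    context: Mapping[str, float],
) -> pd.DataFrame:
    """Movement probability on a 2-D covariate grid (random effects at 0).

    ``axis1``/``axis2`` are ``(covariate_name, values)``; the remaining
    covariates come from ``context``.  Returns a long-format frame with one
    row per grid point.  A warning is issued for densities beyond the
    experimental support (> 50 individuals).
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    for nm, vals in ((name1, vals1), (name2, vals2)):
        if "density" in nm and np.any(vals > 50):
            warnings.warn(
                f"{nm} grid exceeds the experimental support (max 50)")
    g1, g2 = np.meshgrid(vals1, vals2, indexing="ij")
    cov = {
        "time": context.get("time", 120.0),
        "local_density": context.get("local_density", 0.0),
        "neighboring_density": context.get("neighboring_density", 0.0),
        "local_sex_ratio": context.get("local_sex_ratio", 0.5),
        "neighboring_sex_ratio": context.get("neighboring_sex_ratio", 0.5),
        "sex": context.get("sex", 0.0),
        "bulb_age": context.get("bulb_age", 0.0),
    }
    cov[name1] = g1.ravel()
    cov[name2] = g2.ravel()
    p = movement_probability(cov, coefficients)
    return pd.DataFrame({
        name1: g1.ravel(),
        name2: g2.ravel(),
        "p_move": np.asarray(p, dtype=float).ravel(),
    })


def sex_ratio_slopes(
    coefficients: ModelCoefficients,
    context: Mapping[str, float] = SEX_RATIO_SURFACE_CONTEXT,
) -> dict[str, float]:
    """d(eta)/d(local sex ratio) for each sex at a covariate context."""
    c = coefficients
    ld = float(context.get("local_density", 20.0))
    nd = float(context.get("neighboring_density", 20.0))
    base = c.local_sex_ratio + c.ld_x_lsr * ld + c.nd_x_lsr * nd
    return {"F": base, "M": base + c.sex_x_lsr}


def density_switch_point(
    coefficients: ModelCoefficients,
    context: Mapping[str, float] | None = None,
) -> float | None:
    """Neighboring density at which d(eta)/d(local density) changes sign.

    Solves ``beta_LD + beta_LDxND * ND + beta_LDxLSR * LSR
    + beta_LDxNSR * NSR = 0`` for ND in the given sex-ratio context.
    Returns ``None`` (with a log record) when the density-density
    interaction is zero, i.e. no switch exists.
    """
    c = coefficients
    ctx = dict(context or {})
    lsr = float(ctx.get("local_sex_ratio", 0.5))
    nsr = float(ctx.get("neighboring_sex_ratio", 0.5))
    if c.ld_x_nd == 0.0:
        logger.info("no density-density interaction: no switch point")
        return None
    return -(c.local_density + c.ld_x_lsr * lsr + c.ld_x_nsr * nsr) / c.ld_x_nd


# ---------------------------------------------------------------------------
# crossing statistics
# ---------------------------------------------------------------------------

def crossing_stats(
    crossings: pd.DataFrame,
    roster: pd.DataFrame,
    n_nights: int = 1,
) -> dict:
    """Per-sex mean crossings per individual per night, and durations.

    The denominator counts *all* released individuals of that sex
    (individuals that never moved contribute zeros).  With no crossings the
    duration statistics are flagged undefined (NaN).
    """
    out: dict = {"n_crossings": int(len(crossings))}
    counts = crossings.groupby("tag_id").size() if len(crossings) else pd.Series(dtype=int)
    for sex, label in (("F", "female"), ("M", "male")):
        tags = roster.loc[roster["sex"] == sex, "tag_id"]
        total = counts.reindex(tags).fillna(0).sum() if len(tags) else 0.0
        denom = len(tags) * n_nights
        out[f"mean_crossings_{label}"] = float(total / denom) if denom else float("nan")
    denom = len(roster) * n_nights
    out["mean_crossings_overall"] = float(len(crossings) / denom) if denom else float("nan")
    if len(crossings):
        dur_min = crossings["duration_s"].to_numpy(dtype=float) / 60.0
        out["duration_mean_min"] = float(dur_min.mean())
        out["duration_sd_min"] = float(dur_min.std(ddof=1)) if len(dur_min) > 1 else float("nan")
    else:
        out["duration_mean_min"] = float("nan")
        out["duration_sd_min"] = float("nan")
        out["duration_undefined"] = True
    return out
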