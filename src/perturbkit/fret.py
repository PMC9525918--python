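"""FRET ratio extraction and dose-response EC50 estimation.

Pixelwise FRET/CFP ratios are computed from background- and flat-field-
corrected two-channel images over an above-background cell mask.  Per
sensor and time point, replicate measurements are scaled to the unit
interval and fit with the logistic y = 1/(1 + exp(-k*(x - m))) on the
(log10 by default) dose axis; goodness of fit is R^2 between the sigmoid
and the per-dose replicate medians.  Fits with EC50 outside the dose range
or R^2 at or below the threshold (default 0.75) are discarded, and the kept
EC50 values are summarised by their median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datamodel import ImageFrame


# ---------------------------------------------------------------------------
# Image-level ratio
# ---------------------------------------------------------------------------

def fret_ratio_from_images(fret: ImageFrame, cfp: ImageFrame,
                           flatfield_fret: ImageFrame | None = None,
                           flatfield_cfp: ImageFrame | None = None,
                           background: str | float = "percentile",
                           k_sigma: float = 3.0) -> float:
    """Mean pixelwise FRET/CFP ratio over the above-background cell mask.

    Each channel is corrected as (pixels - background) / normalised
    flat-field; the mask is CFP-corrected pixels above the background mean
    plus ``k_sigma`` background standard deviations.
    """
    from .imaging import correct_image, mask_above_background

    if fret.pixels.shape != cfp.pixels.shape:
        raise ValueError("FRET and CFP frames must share a shape")
    corr_f = correct_image(fret, flatfield_fret, background)
    corr_c = correct_image(cfp, flatfield_cfp, background)
    mask = mask_above_background(corr_c, k_sigma=k_sigma)
    if not mask.any():
        raise ValueError("no cell pixels above background")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = corr_f.pixels[mask] / corr_c.pixels[mask]
    ratio = ratio[np.isfinite(ratio)]
    if ratio.size == 0:
        raise ValueError("no finite pixel ratios")
    return float(ratio.mean())


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scale_unit_interval(values: np.ndarray, doses: np.ndarray | None = None
                        ) -> tuple[np.ndarray, dict]:
    """(v - min)/(max - min) over one sensor/time's replicate measurements.

    When ``doses`` is given, the scale is taken from the extremes of the
    per-dose replicate medians rather than the raw points; with a fixed-
    asymptote logistic fit this keeps a single noisy excursion at the top
    or bottom plateau from stretching the whole curve.  A degenerate
    constant vector maps to all 0.5 with ``degenerate=True``.
    """
    values = np.asarray(values, dtype=float)
    if doses is None:
        lo, hi = float(np.min(values)), float(np.max(values))
    else:
        med = pd.Series(values).groupby(np.asarray(doses, dtype=float)).median()
        lo, hi = float(med.min()), float(med.max())
    if hi == lo:
        return np.full_like(values, 0.5), {"min": lo, "max": hi, "degenerate": True}
    return (values - lo) / (hi - lo), {"min": lo, "max": hi, "degenerate": False}


# ---------------------------------------------------------------------------
# Logistic fit
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Per sensor x time logistic dose-response fit."""

    sensor: str
    time_s: float
    ec50: float
    k: float
    r2: float
    kept: bool = False
    reason: str = ""
    scale: dict | None = None


def _logistic(x, k, m):
    return 1.0 / (1.0 + np.exp(-k * (x - m)))


class LogisticEC50(BaseEstimator):
    """Least-squares logistic dose-response fit y = 1/(1+exp(-k(x-m))).

    Parameters
    ----------
    x_transform : 'log10' (default; zero doses excluded from the fit) or
        'linear'.
    max_restarts : jittered re-initialisations before declaring
        non-convergence.

    Attributes: ``ec50_`` (dose units), ``k_``, ``r2_`` (vs per-dose
    replicate medians), ``converged_``.
    """

    def __init__(self, x_transform="log10", max_restarts=3, random_state=0):
        self.x_transform = x_transform
        self.max_restarts = max_restarts
        self.random_state = random_state

    def _x(self, dose):
        return np.log10(dose) if self.x_transform == "log10" else np.asarray(dose, float)

    def fit(self, dose, value):
        dose = np.asarray(dose, dtype=float)
        value = np.asarray(value, dtype=float)
        if self.x_transform == "log10":
            keep = dose > 0
            dose, value = dose[keep], value[keep]
        if len(np.unique(dose)) < 4:
            raise ValueError("need >= 4 distinct doses")
        x = self._x(dose)
        rho = stats.spearmanr(dose, value).statistic
        k0 = 1.0 if not np.isfinite(rho) or rho >= 0 else -1.0
        m0 = float(np.median(x))
        rng = np.random.default_rng(self.random_state)
        self.converged_ = False
        best = None
        for attempt in range(self.max_restarts + 1):
            if attempt == 0:
                p0 = (k0, m0)
            else:
                p0 = (k0 * np.exp(rng.normal(0, 0.5)),
                      m0 + rng.normal(0, 0.5) * (x.max() - x.min() + 1e-12))
            try:
                popt, _ = optimize.curve_fit(_logistic, x, value, p0=p0, maxfev=5000)
            except RuntimeError:
                continue
            rss = float(np.sum((value - _logistic(x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
            self.converged_ = True
        if not self.converged_:
            self.k_ = np.nan
            self.ec50_ = np.nan
            self.r2_ = -np.inf
            return self
        (self.k_, m) = (float(best[0][0]), float(best[0][1]))
        if self.x_transform == "log10":
            # a diverged midpoint maps to inf/0 and is discarded by the
            # dose-range filter
            self.ec50_ = float(10.0 ** np.clip(m, -300.0, 300.0))
        else:
            self.ec50_ = m
        self.midpoint_ = m
        # R^2 against the per-dose replicate medians
        med = pd.DataFrame({"x": x, "y": value}).groupby("x")["y"].median()
        fit_at = _logistic(med.index.to_numpy(), self.k_, m)
        ss_res = float(np.sum((med.to_numpy() - fit_at) ** 2))
        ss_tot = float(np.sum((med.to_numpy() - med.to_numpy().mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
        return self


def fit_logistic_ec50(scaled: pd.DataFrame, x_transform: str = "log10",
                      sensor: str = "", time_s: float = 0.0,
                      scale: dict | None = None) -> DoseResponseFit:
    """Fit one sensor/time dose-response table with columns (dose, value)."""
    est = LogisticEC50(x_transform=x_transform)
    est.fit(scaled["dose"].to_numpy(), scaled["value"].to_numpy())
    if not est.converged_:
        return DoseResponseFit(sensor=sensor, time_s=time_s, ec50=np.nan, k=np.nan,
                               r2=-np.inf, kept=False, reason="non-convergence",
                               scale=scale)
    return DoseResponseFit(sensor=sensor, time_s=time_s, ec50=est.ec50_, k=est.k_,
                           r2=est.r2_, scale=scale)


def filter_fits(fits: list[DoseResponseFit], dose_range: tuple[float, float],
                r2_threshold: float = 0.75) -> list[DoseResponseFit]:
    """Keep fits with EC50 inside the (closed) dose range and R^2 above the
    threshold; others are marked discarded with a reason."""
    lo, hi = dose_range
    kept = []
    for f in fits:
        in_range = np.isfinite(f.ec50) and lo <= f.ec50 <= hi
        good = f.r2 > r2_threshold
        f.kept = bool(in_range and good)
        if not in_range:
            f.reason = f.reason or "ec50 outside dose range"
        elif not good:
            f.reason = "r2 below threshold"
        if f.kept:
            kept.append(f)
    return kept


def summarize_ec50(kept: list[DoseResponseFit], n_bins: int = 20) -> dict:
    """Median EC50 across kept fits (all sensors and times) plus histogram
    bins for plotting; an even count takes the mean of the central pair."""
    values = np.array([f.ec50 for f in kept], dtype=float)
    if values.size == 0:
        return {"median_ec50": np.nan, "n": 0, "hist_counts": [], "hist_edges": []}
    counts, edges = np.histogram(np.log10(values), bins=n_bins)
    return {"median_ec50": float(np.median(values)), "n": int(values.size),
            "hist_counts": counts.tolist(), "hist_edges": edges.tolist()}


def ec50_screen(measurements: pd.DataFrame, x_transform: str = "log10",
                r2_threshold: float = 0.75) -> tuple[list[DoseResponseFit], dict]:
    """Full screen: scale, fit and filter every sensor x time, then summarise.

    ``measurements`` columns: sensor, dose_um, time_s, replicate, ratio.
    Zero-dose wells participate in scaling but are excluded from log fits.
    """
    fits = []
    doses = measurements.loc[measurements["dose_um"] > 0, "dose_um"]
    dose_range = (float(doses.min()), float(doses.max()))
    for (sensor, t), group in measurements.groupby(["sensor", "time_s"], sort=True):
        scaled, scale = scale_unit_interval(group["ratio"].to_numpy(),
                                            doses=group["dose_um"].to_numpy())
        table = pd.DataFrame({"dose": group["dose_um"].to_numpy(), "value": scaled})
        try:
            fit = fit_logistic_ec50(table, x_transform=x_transform, sensor=str(sensor),
                                    time_s=float(t), scale=scale)
        except ValueError:
            continue
        fits.append(fit)
    kept = filter_fits(fits, dose_range, r2_threshold)
    return fits, summarize_ec50(kept)


def fits_frame(fits: list[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame([{ "sensor": f.sensor, "time_s": f.time_s, "ec50": f.ec50,
                           "k": f.k, "r2": f.r2, "kept": f.kept, "reason": f.reason}
                         for f in fits])
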