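"""Forecast-skill metrics, per-horizon evaluation tables and spectral lag selection.

Metrics
-------
nRMSE   root-mean-square error normalized by the observed mean.
mNSE    modified Nash-Sutcliffe efficiency ``1 - SAE/SAD`` built on absolute
        errors instead of squares, reducing sensitivity to extreme values.
mIA     modified index of agreement with the 2*SAD balancing term:
        ``1 - SAE/(2 SAD)`` while SAE <= 2 SAD, else ``2 SAD / SAE - 1``
        (the two branches meet continuously at 0).

All metrics are kept on their natural scale internally; the table formatter
multiplies by 100 where percentages are wanted.

Lag selection
-------------
The autoregressive order P is taken from the periodogram of the
mean-removed series: the period (in sampling units) of the highest spectral
peak.  Peak significance is judged against a theoretical AR(1) ("red
noise") background spectrum with the lag-1 autocorrelation estimated from
the data, using the chi-square criterion (2 degrees of freedom, 1 at the
Nyquist bin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "nrmse",
    "sae_sad",
    "mnse",
    "mia",
    "HorizonMetricsTable",
    "evaluate_per_horizon",
    "SpectrumResult",
    "fourier_power_spectrum",
    "select_lag_order",
    "relative_gain",
]

logger = logging.getLogger(__name__)


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d with equal length")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    return o, p


def nrmse(observed, predicted) -> float:
    """Root-mean-square error divided by the mean of the observations."""
    o, p = _check_pair(observed, predicted)
    xbar = o.mean()
    if xbar == 0.0:
        raise ValueError("nRMSE undefined: observed mean is zero")
    return float(np.sqrt(np.mean((o - p) ** 2)) / xbar)


def sae_sad(observed, predicted) -> tuple[float, float]:
    """Sum of absolute errors and sum of absolute deviations from the mean."""
    o, p = _check_pair(observed, predicted)
    sae = float(np.sum(np.abs(p - o)))
    sad = float(np.sum(np.abs(o - o.mean())))
    return sae, sad


def mnse(observed, predicted) -> float:
    """Modified Nash-Sutcliffe efficiency 1 - SAE/SAD (1 = perfect)."""
    sae, sad = sae_sad(observed, predicted)
    if sad == 0.0:
        raise ValueError("mNSE undefined: observations are constant (SAD = 0)")
    return 1.0 - sae / sad


def mia(observed, predicted) -> float:
    """Modified index of agreement with the 2*SAD balancing term."""
    sae, sad = sae_sad(observed, predicted)
    if sad == 0.0:
        raise ValueError("mIA undefined: observations are constant (SAD = 0)")
    if sae <= 2.0 * sad:
        return 1.0 - sae / (2.0 * sad)
    return 2.0 * sad / sae - 1.0


@dataclass(frozen=True)
class HorizonMetricsTable:
    """Per-horizon nRMSE/mNSE/mIA plus the standard summary rows.

    Summary rows: Min, Max over all horizons; means over horizons 1-8 and
    1-13 where the horizon range allows; and the mean over the full range.
    """

    per_horizon: pd.DataFrame  # index h = 1..tau, columns nRMSE/mNSE/mIA
    summary: pd.DataFrame

    @property
    def tau(self) -> int:
        return len(self.per_horizon)

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """Stacked table (horizon rows then summary rows); percent scales by 100."""
        full = pd.concat([self.per_horizon, self.summary])
        return full * 100.0 if percent else full

    def to_csv(self, path, percent: bool = False) -> None:
        self.to_frame(percent=percent).to_csv(path, index_label="h", float_format="%.6g")


def evaluate_per_horizon(observed_targets, predicted_targets) -> HorizonMetricsTable:
    """Score each forecast horizon column and assemble the summary rows."""
    obs = np.asarray(observed_targets, dtype=float)
    pred = np.asarray(predicted_targets, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 2:
        raise ValueError("observed and predicted target matrices must share a 2-d shape")
    tau = obs.shape[1]
    rows = []
    for h in range(tau):
        rows.append(
            {
                "nRMSE": nrmse(obs[:, h], pred[:, h]),
                "mNSE": mnse(obs[:, h], pred[:, h]),
                "mIA": mia(obs[:, h], pred[:, h]),
            }
        )
    per = pd.DataFrame(rows, index=pd.RangeIndex(1, tau + 1, name="h"))
    summary_rows = {"Min": per.min(), "Max": per.max()}
    for upper in (8, 13):
        if tau >= upper:
            summary_rows[f"Mean 1–{upper}"] = per.iloc[:upper].mean()
    summary_rows[f"Mean 1–{tau}"] = per.mean()
    summary = pd.DataFrame(summary_rows).T
    return HorizonMetricsTable(per_horizon=per, summary=summary)


@dataclass(frozen=True)
class SpectrumResult:
    """Periodogram with an AR(1) red-noise significance background."""

    frequencies: np.ndarray   # cycles per sample, k/N for k = 1..N//2
    periods: np.ndarray       # N/k, in sampling units (weeks)
    power: np.ndarray
    background: np.ndarray    # scaled AR(1) spectrum
    confidence: float
    dominant_period: int
    significant: np.ndarray   # bool per frequency bin
    ar1_coefficient: float


def fourier_power_spectrum(x, confidence: float = 0.95, detrend: str = "linear") -> SpectrumResult:
    """Periodogram with an AR(1) red-noise significance background.

    The series is detrended first — linearly by default, so that a slowly
    drifting level does not bury the seasonal peak in the lowest frequency
    bins (``detrend="mean"`` removes only the mean).  The background is the
    theoretical AR(1) spectrum with the lag-1 autocorrelation estimated from
    the detrended series, normalized to carry the same mean power as the
    periodogram; a bin is flagged significant when its power exceeds the
    background scaled by the chi-square quantile at the requested confidence
    (2 dof, 1 dof at the Nyquist bin for even N).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    N = arr.size
    if N < 32:
        raise ValueError(f"series too short for spectral analysis: {N} < 32")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")

    if detrend == "linear":
        t = np.arange(N, dtype=float)
        y = arr - np.polyval(np.polyfit(t, arr, 1), t)
    elif detrend == "mean":
        y = arr - arr.mean()
    else:
        raise ValueError("detrend must be 'linear' or 'mean'")
    X = np.fft.rfft(y)
    k = np.arange(1, N // 2 + 1)
    power = (np.abs(X[1 : N // 2 + 1]) ** 2) / N

    denom = float(y @ y)
    if denom > 0.0:
        alpha = float(y[:-1] @ y[1:]) / denom
    else:
        alpha = 0.0
    alpha = min(max(alpha, 0.0), 0.999)  # red-noise model assumes alpha in [0, 1)

    raw_bg = (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos(2.0 * np.pi * k / N))
    mean_power = power.mean()
    bg = raw_bg * (mean_power / raw_bg.mean()) if mean_power > 0.0 else np.zeros_like(raw_bg)

    dof = np.full(k.size, 2.0)
    if N % 2 == 0:
        dof[-1] = 1.0  # Nyquist ordinate is a single squared Gaussian
    factor = stats.chi2.ppf(confidence, dof) / dof
    significant = power > bg * factor if mean_power > 0.0 else np.zeros(k.size, dtype=bool)

    # argmax breaks ties toward the lower frequency bin (longer period)
    k_star = int(k[np.argmax(power)])
    dominant_period = int(round(N / k_star))
    logger.debug(
        "spectrum: dominant period %d (bin k=%d), significant=%s at %.0f%%",
        dominant_period, k_star, bool(significant[k_star - 1]), 100 * confidence,
    )
    return SpectrumResult(
        frequencies=k / N,
        periods=N / k,
        power=power,
        background=bg,
        confidence=confidence,
        dominant_period=dominant_period,
        significant=significant,
        ar1_coefficient=alpha,
    )


def select_lag_order(spec: SpectrumResult) -> int:
    """AR order P = rounded period of the highest periodogram peak."""
    if spec.power.size == 0 or not np.any(spec.power > 0.0):
        raise ValueError("spectrum has no finite peak; cannot select a lag order")
    P = int(spec.dominant_period)
    logger.info(
        "selected lag order P = %d (dominant spectral peak, significant=%s "
        "at %.0f%% confidence)",
        P,
        bool(spec.significant[int(np.argmax(spec.power))]),
        100 * spec.confidence,
    )
    return max(P, 1)


def relative_gain(metric_a, metric_b, per_horizon: bool = False) -> float | np.ndarray:
    """Percent improvement of method a over method b.

    Default: ``100 * (mean(a) - mean(b)) / mean(b)``.  With
    ``per_horizon=True`` the ratio is formed horizon by horizon before
    averaging (``100 * mean((a - b) / b)``); the two conventions differ for
    heterogeneous horizons, so both are reported by the comparison layer.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric sequences must share a shape")
    if per_horizon:
        if np.any(b == 0.0):
            raise ValueError("per-horizon gain undefined: zero entry in baseline")
        return float(100.0 * np.mean((a - b) / b))
    mb = b.mean()
    if mb == 0.0:
        raise ValueError("gain undefined: baseline mean is zero")
    return float(100.0 * (a.mean() - mb) / mb)
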