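"""Seeded generators of weekly injury-count-like series and test fixtures.

The main generator emulates the statistical character of weekly counts of
persons injured in traffic accidents (the setting the pipeline targets):
roughly fifteen years of weekly sampling (~780 points), a piecewise-linear
trend with a few regime changes, a dominant seasonal cycle near half a year
(26 weeks; 17 for the minor-cause analogue), and autocorrelated AR(1)
("red") noise.  Magnitudes are chosen so the series stays strictly positive
at the default noise level.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forecasting import RegressorSet

__all__ = [
    "SyntheticSeriesConfig",
    "generate_injury_series",
    "generate_component_pair",
    "generate_linear_mimo_fixture",
]


@dataclass(frozen=True)
class SyntheticSeriesConfig:
    """Weekly count series: base + piecewise trend + seasonality + AR(1) noise.

    ``trend_segments`` is a list of (start_week, slope per week) pairs with
    strictly increasing 1-based start weeks; each slope applies from its
    start week until the next segment begins.  ``noise_sd`` is the marginal
    (stationary) standard deviation of the AR(1) noise; the innovation
    variance is derived from it.  The defaults sketch a major-cause weekly
    injury series: fifteen years of data, a rise over the first ~280 weeks,
    a decline to week ~348, then a mild recovery, with a 26-week cycle.
    """

    n_weeks: int = 780
    base_level: float = 600.0
    trend_segments: tuple[tuple[int, float], ...] = ((1, 0.8), (281, -1.5), (349, 0.3))
    seasonal_period: int = 26
    seasonal_amplitude: float = 60.0
    secondary_period: int | None = None
    secondary_amplitude: float = 0.0
    ar1_coefficient: float = 0.6
    noise_sd: float = 25.0
    integer_counts: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_weeks < 3:
            raise ValueError("n_weeks must be >= 3")
        starts = [s for s, _ in self.trend_segments]
        if starts and (starts[0] < 1 or any(b <= a for a, b in zip(starts, starts[1:]))):
            raise ValueError(
                "trend_segments must have strictly increasing start weeks >= 1"
            )
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0 or self.secondary_amplitude < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")


def _deterministic_part(cfg: SyntheticSeriesConfig) -> np.ndarray:
    n = cfg.n_weeks
    t = np.arange(1, n + 1, dtype=float)

    slope = np.zeros(n)
    for i, (start, s) in enumerate(cfg.trend_segments):
        end = cfg.trend_segments[i + 1][0] if i + 1 < len(cfg.trend_segments) else n + 1
        slope[start - 1 : min(end - 1, n)] = s
    trend = np.concatenate(([0.0], np.cumsum(slope[:-1])))

    seasonal = cfg.seasonal_amplitude * np.sin(2.0 * np.pi * t / cfg.seasonal_period)
    if cfg.secondary_period is not None and cfg.secondary_amplitude > 0.0:
        seasonal = seasonal + cfg.secondary_amplitude * np.sin(
            2.0 * np.pi * t / cfg.secondary_period
        )
    return cfg.base_level + trend + seasonal


def _ar1_noise(cfg: SyntheticSeriesConfig) -> np.ndarray:
    if cfg.noise_sd == 0.0:
        return np.zeros(cfg.n_weeks)
    rng = np.random.default_rng(cfg.seed)
    alpha = cfg.ar1_coefficient
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - alpha**2)
    e = rng.normal(0.0, innov_sd, size=cfg.n_weeks)
    v = np.empty(cfg.n_weeks)
    v[0] = rng.normal(0.0, cfg.noise_sd)  # stationary start
    for i in range(1, cfg.n_weeks):
        v[i] = alpha * v[i - 1] + e[i]
    return v


def generate_component_pair(cfg: SyntheticSeriesConfig) -> tuple[np.ndarray, np.ndarray]:
    """The generator's own low/high-frequency split, before clamping/rounding.

    ``c_L`` is the noiseless base + trend + seasonality; ``c_H`` is the
    zero-mean AR(1) noise.  Their sum is the raw series underlying
    :func:`generate_injury_series` for the same config and seed, useful for
    forecasting tests that bypass the decomposition stage.
    """
    return _deterministic_part(cfg), _ar1_noise(cfg)


def generate_injury_series(cfg: SyntheticSeriesConfig) -> np.ndarray:
    """Generate one weekly count series (clamped at zero, optionally integer)."""
    c_L, c_H = generate_component_pair(cfg)
    x = np.maximum(c_L + c_H, 0.0)
    if cfg.integer_counts:
        x = np.round(x)
    return x


def generate_linear_mimo_fixture(
    rows: int, P: int, tau: int, noise_sd: float, seed: int
) -> tuple[RegressorSet, np.ndarray]:
    """Random full-rank design with known linear coefficients.

    ``targets = z @ beta_true.T + noise``; returns the regressor set and
    ``beta_true`` (tau x 2P) so recovery can be checked exactly in the
    noiseless case and statistically otherwise.
    """
    if rows <= 2 * P:
        raise ValueError("need rows > 2P for a full-column-rank design")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((rows, 2 * P))
    beta_true = rng.uniform(-1.0, 1.0, size=(tau, 2 * P))
    targets = z @ beta_true.T
    if noise_sd > 0.0:
        targets = targets + rng.normal(0.0, noise_sd, size=targets.shape)
    reg = RegressorSet(
        z=z,
        targets=targets,
        row_index_map=np.arange(P, P + rows),
        P=P,
        tau=tau,
    )
    return reg, beta_true
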