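"""Cross-correlation lag analysis between surface water input and soil moisture.

Water applied at the surface (rain + irrigation) takes time to percolate to a
buried sensor, so the moisture series at depth *d* responds to the input
series with a depth-dependent delay.  For each candidate lag *m* ≥ 0 the
Pearson correlation between input ``x[t]`` and moisture ``y[t+m]`` is computed
over the ``n − m`` overlapping pairs (no padding, no circular wrap), with a
two-tailed t-test p-value per lag.  The modelling lag for each depth is the
significant lag with the largest |r|; depths with no significant lag get a
configurable fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationEntry",
    "CrossCorrelogram",
    "LagSpec",
    "water_input",
    "cross_correlation",
    "correlation_p_value",
    "select_lags",
    "correlogram_frame",
]

DEFAULT_MAX_LAG = 5
DEFAULT_ALPHA = 0.05
#: reporting threshold for "highly significant" correlations
HIGHLY_SIGNIFICANT = 0.001


def water_input(daily: pd.DataFrame) -> pd.Series:
    """Surface water input, mm/day: rainfall plus irrigation.

    Days where either component is missing yield a missing value.
    """
    for col in ("rain_mm", "irrigation_mm"):
        if col not in daily.columns:
            raise ValueError(f"daily series lacks {col!r}")
    return daily["rain_mm"] + daily["irrigation_mm"]


def correlation_p_value(r: float, n_overlap: int) -> float:
    """Two-tailed p-value for a Pearson correlation.

    Uses the exact small-sample t statistic ``t = r·sqrt((n−2)/(1−r²))`` with
    ``n_overlap − 2`` degrees of freedom; |r| = 1 returns the limit p = 0.
    """
    if n_overlap < 4:
        raise ValueError(f"need n_overlap >= 4, got {n_overlap}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n_overlap - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass(frozen=True)
class CorrelationEntry:
    lag: int
    r: float
    p: float
    n_overlap: int


@dataclass(frozen=True)
class CrossCorrelogram:
    """Per-depth cross-correlation evidence across candidate lags."""

    depth_cm: int
    entries: tuple[CorrelationEntry, ...]

    def best_significant(self, alpha: float) -> CorrelationEntry | None:
        """Entry with max |r| among lags ≥ 1 with p < alpha; ties → smaller lag."""
        candidates = [e for e in self.entries if e.lag >= 1 and e.p < alpha]
        if not candidates:
            return None
        return max(candidates, key=lambda e: (abs(e.r), -e.lag))


def cross_correlation(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    depth_cm: int = 0,
) -> CrossCorrelogram:
    """Lagged Pearson correlations of ``x[t]`` against ``y[t+m]``, m = 0..max_lag.

    The overlap shrinks with lag (n − m pairs); each lag carries its own
    two-tailed p-value.  Both series must be aligned, equal length and
    non-constant over every evaluated overlap.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be aligned 1-d series of equal length")
    n = xv.size
    if n <= max_lag + 3:
        raise ValueError(f"series length {n} too short for max_lag {max_lag}")
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("series contain missing values; drop or fill them first")
    entries = []
    for m in range(max_lag + 1):
        xs = xv[: n - m] if m else xv
        ys = yv[m:]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise ValueError(f"zero variance at lag {m}")
        r = float(np.corrcoef(xs, ys)[0, 1])
        entries.append(CorrelationEntry(m, r, correlation_p_value(r, n - m), n - m))
    return CrossCorrelogram(depth_cm, tuple(entries))


@dataclass(frozen=True)
class LagSpec:
    """Chosen modelling lag per depth (days), plus the water-input definition."""

    lags: dict[int, int]
    water_input_def: str = "rain + irrigation"

    def __post_init__(self) -> None:
        for depth, lag in self.lags.items():
            if lag < 1:
                raise ValueError(
                    f"soil-moisture lag must be >= 1 day (depth {depth}: {lag}); "
                    "training predictors must be strictly past values"
                )

    def max_lag(self) -> int:
        return max(self.lags.values())


def select_lags(
    correlograms: dict[int, CrossCorrelogram] | list[CrossCorrelogram],
    alpha: float = DEFAULT_ALPHA,
    fallback: int = 2,
) -> LagSpec:
    """Pick one modelling lag per depth from its correlogram.

    Per depth: the lag ≥ 1 with the largest |r| among entries significant at
    ``alpha`` (ties broken toward the smaller lag); a depth with no
    significant lag is assigned ``fallback`` — deep layers may show no
    coherent response yet still enter the model at a nominal delay.
    """
    if isinstance(correlograms, dict):
        items = list(correlograms.values())
    else:
        items = list(correlograms)
    if not items:
        raise ValueError("no correlograms supplied")
    lags: dict[int, int] = {}
    for cg in items:
        if not cg.entries:
            raise ValueError(f"empty correlogram for depth {cg.depth_cm}")
        best = cg.best_significant(alpha)
        lags[cg.depth_cm] = best.lag if best is not None else fallback
    return LagSpec(lags)


def correlogram_frame(correlograms: dict[int, CrossCorrelogram]) -> pd.DataFrame:
    """Flatten correlograms into a tidy table: depth_cm, lag, r, p, n."""
    rows = [
        {"depth_cm": cg.depth_cm, "lag": e.lag, "r": e.r, "p": e.p, "n": e.n_overlap}
        for cg in correlograms.values()
        for e in cg.entries
    ]
    return pd.DataFrame(rows)


def analyze_daily(
    daily: pd.DataFrame,
    depths: tuple[int, ...] = (30, 60, 90),
    max_lag: int = DEFAULT_MAX_LAG,
) -> dict[int, CrossCorrelogram]:
    """Correlate water input against each depth's moisture series.

    Rows with a missing value in any involved column are dropped pairwise-
    complete before lagging.
    """
    w = water_input(daily)
    out: dict[int, CrossCorrelogram] = {}
    for depth in depths:
        col = f"sm{depth}"
        if col not in daily.columns:
            raise ValueError(f"daily series lacks {col!r}")
        mask = w.notna() & daily[col].notna()
        out[depth] = cross_correlation(
            w[mask].to_numpy(), daily.loc[mask, col].to_numpy(),
            max_lag=max_lag, depth_cm=depth,
        )
    return out
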