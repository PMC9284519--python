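"""Scaling relationships between coverage, time and available area.

Two headline fits:

* at a fixed incubation time, areal coverage across surfaces is a
  straight line through the origin in the available-area fraction
  S_A/100 — patterns reduce coverage in proportion to the area they
  leave available;
* per surface, coverage is piecewise linear in time,
  ``coverage = max(0, r·(t − lag))`` — biaxial (tortuous) patterns show
  a nonzero onset lag during which proliferation is frustrated.

Deviation flags mark (pattern, time) cells whose coverage falls well
below the through-origin line relative to the residual spread of the
flat/uniaxial references — the signature of onset suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScalingFit",
    "TimeFit",
    "fit_linear_SA",
    "fit_time_linear",
    "reduction_summary",
    "plot_coverage_vs_sa",
]

REQUIRED_COLS = ("pattern", "SA_pct", "time_h", "coverage_pct")


def _check_frame(df: pd.DataFrame, cols=REQUIRED_COLS) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns {missing}")


@dataclass
class ScalingFit:
    """Through-origin fit of coverage vs available-area fraction."""

    time_h: float
    slope: float  # coverage-% per unit SA fraction
    residuals: pd.Series  # per point, coverage-%
    deviation_flags: dict[str, bool]
    baseline_sd: float


@dataclass
class TimeFit:
    """Piecewise-linear-in-time fit for one pattern."""

    pattern: str
    rate: float  # coverage-% per hour (post-lag)
    lag: float  # hours
    rate_ci: tuple[float, float] | None = None
    lag_ci: tuple[float, float] | None = None
    degenerate: bool = False
    sse: float = 0.0


def fit_linear_SA(
    points: pd.DataFrame,
    flag_threshold: float = 2.0,
    baseline_patterns: tuple[str, ...] = ("F", "1D"),
) -> ScalingFit:
    """Least-squares line through the origin at one fixed time.

    ``points`` must hold a single time; SA enters as a fraction
    (SA_pct/100) so the slope is coverage-% per unit available-area
    fraction. A pattern is flagged as deviating when its mean
    studentized residual is below ``-flag_threshold``, studentized by
    the residual spread of the baseline (F/1D) points at that time.
    """
    _check_frame(points)
    times = points["time_h"].unique()
    if len(times) != 1:
        raise ValueError("fit_linear_SA expects points at a single time")
    s = points["SA_pct"].to_numpy(dtype=float) / 100.0
    c = points["coverage_pct"].to_numpy(dtype=float)
    if np.allclose(s, s[0]):
        raise ValueError("need at least 2 distinct SA values")
    slope = float((s * c).sum() / (s * s).sum())
    resid = pd.Series(c - slope * s, index=points.index)
    base = points["pattern"].isin(baseline_patterns).to_numpy()
    baseline_sd = float(resid[base].std(ddof=1)) if base.sum() > 1 else float(resid.std(ddof=1))
    if not np.isfinite(baseline_sd) or baseline_sd <= 0:
        baseline_sd = max(1e-9, float(np.abs(resid).max()))
    flags: dict[str, bool] = {}
    for pat, grp in resid.groupby(points["pattern"]):
        flags[pat] = bool(grp.mean() / baseline_sd < -flag_threshold)
    return ScalingFit(float(times[0]), slope, resid, flags, baseline_sd)


def _fit_rate_lag(t: np.ndarray, c: np.ndarray, lag_grid: np.ndarray) -> tuple[float, float, float]:
    """Profile the lag on a grid; rate is closed-form per lag."""
    best = (0.0, 0.0, np.inf)
    for lag in lag_grid:
        tau = np.clip(t - lag, 0.0, None)
        denom = (tau * tau).sum()
        r = float((c * tau).sum() / denom) if denom > 0 else 0.0
        r = max(r, 0.0)
        sse = float(((c - r * tau) ** 2).sum())
        if sse < best[2] - 1e-15:
            best = (r, float(lag), sse)
    return best


def fit_time_linear(
    points: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    lag_step: float = 0.01,
) -> dict[str, TimeFit]:
    """Fit coverage = max(0, r·(t − lag)) per pattern.

    The lag is profiled on a grid of ``lag_step`` hours (the rate has a
    closed form at fixed lag). Bootstrap percentile CIs resample
    replicates when a ``replicate`` column is present. An all-zero
    series is degenerate: the lag is set to the last observed time and
    flagged.
    """
    _check_frame(points)
    out: dict[str, TimeFit] = {}
    rng = np.random.default_rng(seed)
    for pat, grp in points.groupby("pattern"):
        t = grp["time_h"].to_numpy(dtype=float)
        c = grp["coverage_pct"].to_numpy(dtype=float)
        if len(np.unique(t)) < 3:
            raise ValueError(f"pattern {pat}: need at least 3 time points")
        if np.allclose(c, 0.0):
            out[pat] = TimeFit(pat, 0.0, float(t.max()), degenerate=True)
            continue
        lag_grid = np.arange(0.0, t.max(), lag_step)
        r, lag, sse = _fit_rate_lag(t, c, lag_grid)
        rate_ci = lag_ci = None
        if n_boot > 0 and "replicate" in grp.columns and grp["replicate"].nunique() > 1:
            reps = grp["replicate"].unique()
            rs, lags = [], []
            for _ in range(n_boot):
                pick = rng.choice(reps, size=len(reps), replace=True)
                sub = pd.concat([grp[grp["replicate"] == p] for p in pick])
                tb = sub["time_h"].to_numpy(dtype=float)
                cb = sub["coverage_pct"].to_numpy(dtype=float)
                rb, lb, _ = _fit_rate_lag(tb, cb, lag_grid)
                rs.append(rb)
                lags.append(lb)
            rate_ci = tuple(np.percentile(rs, [2.5, 97.5]))
            lag_ci = tuple(np.percentile(lags, [2.5, 97.5]))
        out[pat] = TimeFit(pat, r, lag, rate_ci, lag_ci, sse=sse)
    return out


def reduction_summary(
    fits: dict[str, TimeFit],
    reference: str = "F",
    t_ref: float = 6.0,
) -> dict:
    """Pattern ranking and percent reduction vs the reference surface.

    Ranking orders patterns by fitted coverage at ``t_ref`` (onset lags
    included); reductions compare the post-lag proliferation *rates*,
    which is the lag-adjusted measure of how much a pattern slows
    spreading once colonization has started.
    """
    if reference not in fits:
        raise ValueError(f"reference pattern {reference!r} missing from fits")
    missing = [p for p in ("F", "1D", "C", "H") if p not in fits]
    if missing:
        warnings_msg = f"patterns missing from fits: {missing}"
        import warnings

        warnings.warn(warnings_msg, stacklevel=2)
    cov_at = {p: f.rate * max(0.0, t_ref - f.lag) for p, f in fits.items()}
    order = sorted(fits, key=lambda p: cov_at[p], reverse=True)
    ref_rate = fits[reference].rate
    reductions = {
        p: (100.0 * (1.0 - f.rate / ref_rate) if ref_rate > 0 else float("nan"))
        for p, f in fits.items()
    }
    return {
        "ranking": " > ".join(order),
        "order": order,
        "coverage_at_t_ref": cov_at,
        "t_ref": t_ref,
        "reduction_vs_reference_pct": reductions,
        "reference": reference,
    }


def plot_coverage_vs_sa(points: pd.DataFrame, ax=None):
    """Coverage vs S_A scatter with through-origin lines per time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _check_frame(points)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for t, grp in points.groupby("time_h"):
        sc = ax.scatter(grp["SA_pct"], grp["coverage_pct"], label=f"{t:g} h", s=18)
        try:
            fit = fit_linear_SA(grp)
            xs = np.linspace(0, 110, 50)
            ax.plot(xs, fit.slope * xs / 100.0, color=sc.get_facecolor()[0], lw=1)
        except ValueError:
            pass
    ax.set_xlabel(r"available surface area $S_A$ (%)")
    ax.set_ylabel("areal coverage (%)")
    ax.legend(title="time")
    return ax
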