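"""Reduce raw assay outputs to normalized activity curves and fit the
competing coupling models.

The pipeline mirrors how mixed wild-type/dead-protomer doping experiments are
interpreted: initial slopes of fluorescence traces give unfolding rates;
rates are normalized to the all-wild-type (r = 0) group; the resulting
activity-vs-r curve is compared against the closed-form threshold curves
(m = 1 strictly sequential, m = 2, ..., uncoupled), which have no free
parameters beyond the discrete threshold m, so model selection is by
residual sum of squares with bootstrap selection frequencies for confidence.
An optional stochastic fit estimates the escape rate of stalled complexes by
matching simulated ensemble curves to the data with common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ring_model import ActivityCurve, CouplingModel, RingSpec, activity_threshold
from .simulator import MotorParams, ensemble_activity
from .synthetic import DopingDataset, FluorescenceTrace

__all__ = [
    "FitResult",
    "EscapeFit",
    "DegradationFit",
    "initial_slope",
    "normalize_and_aggregate",
    "fit_threshold_model",
    "fit_escape_model",
    "quantify_degradation",
]


def initial_slope(trace: FluorescenceTrace, window: int | None = None) -> float:
    """Ordinary least-squares slope over the first points of a trace.

    ``window`` is the number of leading points; the default is the larger of
    5 points and the first 10% of the trace.  The slope is signed (negative
    for fluorescence loss), in fluorescence units per time unit.
    """
    n = len(trace.times)
    if window is None:
        window = max(5, math.ceil(0.1 * n))
    if window < 3:
        raise ValueError("window must contain at least 3 points")
    if n < window:
        raise ValueError(f"trace has {n} points, window needs {window}")
    t = np.asarray(trace.times[:window], dtype=float)
    f = np.asarray(trace.fluorescence[:window], dtype=float)
    slope, _ = np.polyfit(t, f, 1)
    return float(slope)


def _as_groups(raw) -> pd.DataFrame:
    if isinstance(raw, DopingDataset):
        return raw.data[["r", "activity"]]
    if isinstance(raw, pd.DataFrame):
        return raw[["r", "activity"]]
    rows = [(float(r), float(v)) for r, vals in dict(raw).items() for v in vals]
    return pd.DataFrame(rows, columns=["r", "activity"])


def normalize_and_aggregate(raw) -> ActivityCurve:
    """Normalize raw rates by the mean r = 0 rate; aggregate per r.

    Accepts a DopingDataset, a DataFrame with columns (r, activity), or a
    mapping r -> iterable of rates.  Returns per-r means with sample
    standard deviations (ddof = 1; 0 for singleton groups), so the r = 0
    group has mean exactly 1.
    """
    df = _as_groups(raw)
    if not (df["r"] == 0.0).any():
        raise ValueError("cannot normalize: no r = 0 group present")
    ref = df.loc[df["r"] == 0.0, "activity"].mean()
    if ref == 0:
        raise ValueError("r = 0 group has zero mean rate")
    norm = df.assign(activity=df["activity"] / ref)
    g = norm.groupby("r")["activity"]
    mean = g.mean()
    sd = g.std(ddof=1).fillna(0.0)
    return ActivityCurve(
        r_values=mean.index.to_numpy(),
        activity=mean.to_numpy(),
        stderr=sd.to_numpy(),
        label="data",
        metadata={"normalization": "per-dataset r=0 mean"},
    )


@dataclass
class FitResult:
    """Threshold-model comparison for one doping dataset."""

    rss_by_m: dict[int, float]
    best_m: int
    k_escape_hat: float | None = None
    bootstrap_ci_m: dict[int, float] = field(default_factory=dict)
    n_protomers: int = 6

    def __post_init__(self) -> None:
        best_rss = min(self.rss_by_m.values())
        # ties broken toward smaller m
        expect = min(m for m, v in self.rss_by_m.items() if v == best_rss)
        if self.best_m != expect:
            raise ValueError("best_m inconsistent with rss_by_m")

    def curve(self, m: int | None = None, r_values=None) -> ActivityCurve:
        from .ring_model import activity_curve

        m = self.best_m if m is None else m
        r = np.linspace(0, 1, 101) if r_values is None else np.asarray(r_values)
        return activity_curve(r, CouplingModel(m), RingSpec(self.n_protomers))


def _rss_per_m(df: pd.DataFrame, ring: RingSpec, weights=None) -> dict[int, float]:
    rss = {}
    for m in range(1, ring.n_protomers + 2):
        model = df["r"].map(
            lambda r: activity_threshold(float(r), CouplingModel(m), ring)
        )
        resid = (df["activity"] - model) ** 2
        if weights is not None:
            resid = resid * weights
        rss[m] = float(resid.sum())
    return rss


def fit_threshold_model(
    data: DopingDataset,
    ring: RingSpec = RingSpec(),
    normalize: bool = True,
    n_bootstrap: int = 0,
    seed=None,
) -> FitResult:
    """Least-squares comparison of a doping dataset against threshold curves.

    Each threshold m in {1, ..., n+1} defines a parameter-free activity
    curve; the fit reports per-m residual sums of squares over all replicate
    points and the minimizing m (ties broken toward smaller m).  Bootstrap
    resampling of replicates within each r gives per-m selection
    frequencies.
    """
    df = data.data.copy()
    if df["r"].nunique() < 3:
        raise ValueError("need at least 3 distinct r values to fit")
    if normalize:
        if not (df["r"] == 0.0).any():
            raise ValueError("normalize=True requires an r = 0 group")
        df["activity"] = df["activity"] / df.loc[df["r"] == 0.0, "activity"].mean()

    rss = _rss_per_m(df, ring)
    best = min(rss, key=lambda m: (rss[m], m))

    boot_freq: dict[int, float] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts = {m: 0 for m in rss}
        groups = [g for _, g in df.groupby("r")]
        for _ in range(n_bootstrap):
            resampled = pd.concat(
                [g.iloc[rng.integers(len(g), size=len(g))] for g in groups],
                ignore_index=True,
            )
            b_rss = _rss_per_m(resampled, ring)
            counts[min(b_rss, key=lambda m: (b_rss[m], m))] += 1
        boot_freq = {m: c / n_bootstrap for m, c in counts.items()}

    return FitResult(
        rss_by_m=rss,
        best_m=best,
        bootstrap_ci_m=boot_freq,
        n_protomers=ring.n_protomers,
    )


@dataclass
class EscapeFit:
    """Escape-rate estimate from matching simulated ensemble curves to data."""

    k_escape_hat: float
    profile: pd.DataFrame  # columns: k_escape, objective
    seed: int | None = None


def fit_escape_model(
    data: DopingDataset,
    params: MotorParams,
    k_escape_grid,
    seed=None,
    n_complexes: int = 500,
    t_end: float = 100.0,
) -> EscapeFit:
    """Grid search for the escape rate that best matches a doping dataset.

    For each candidate k_escape the ensemble activity curve is simulated at
    the dataset's r values with common random numbers across grid points
    (same seed stream), making the stochastic objective quasi-deterministic;
    the objective is the squared error against per-r mean activities.  The
    full profile is returned so flatness of the objective is visible.
    """
    grid = np.asarray(k_escape_grid, dtype=float)
    if grid.size < 2 or np.any(grid < 0):
        raise ValueError("k_escape_grid needs >= 2 non-negative values")
    curve = normalize_and_aggregate(data)
    r_values = curve.r_values
    rows = []
    for k in grid:
        p = replace(params, k_escape=float(k))
        obj = 0.0
        for i, r in enumerate(r_values):
            # common random numbers: seed depends on r only, not on k
            r_seed = (i,) if seed is None else (int(seed), i)
            pt = ensemble_activity(p, float(r), n_complexes, t_end, seed=r_seed)
            obj += (curve.activity[i] - pt.atpase_activity) ** 2
        if not np.isfinite(obj):
            raise RuntimeError(f"non-finite objective at k_escape={k}")
        rows.append((float(k), float(obj)))
    profile = pd.DataFrame(rows, columns=["k_escape", "objective"])
    best = profile.loc[profile["objective"].idxmin(), "k_escape"]
    return EscapeFit(k_escape_hat=float(best), profile=profile,
                     seed=seed if isinstance(seed, int) else None)


@dataclass
class DegradationFit:
    """First-order degradation rate from a band-intensity time course."""

    rate: float
    rate_se: float
    fraction_remaining: pd.DataFrame  # columns: time, fraction


def quantify_degradation(table) -> DegradationFit:
    """Normalize band intensities to t = 0 and fit a first-order decay.

    Accepts a DataFrame with columns (time, intensity); intensities must be
    positive.  The rate is minus the slope of a log-linear ordinary
    least-squares fit, with its regression standard error.
    """
    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 time points")
    t = df["time"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("intensities must be positive for a log-linear fit")
    frac = y / y[0]
    res = stats.linregress(t, np.log(frac))
    return DegradationFit(
        rate=-float(res.slope),
        rate_se=float(res.stderr),
        fraction_remaining=pd.DataFrame({"time": t, "fraction": frac}),
    )
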