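"""Synthetic-data generators emulating the doping, unfolding, degradation and
pore-loop-geometry inputs the analysis consumes.

Every generator is a pure function of its parameters and seed, so tests and
recovery studies are exactly reproducible.  The statistical structure mirrors
the assays:

* doping datasets: binomial incorporation of dead protomers into hexamers,
  replicate activity measurements (triplicate by default) with additive
  Gaussian noise, optionally with finite-sample assembly noise;
* fluorescence unfolding traces: first-order decay of folded substrate (the
  chaperonin trap prevents refolding, so fluorescence loss is cumulative)
  whose initial slope is proportional to the unfolding rate;
* degradation band intensities: first-order decay plus a no-degradation
  control condition;
* pore-loop coordinate sets: five gripping protomers on an ideal helix plus
  a seam protomer displaced outward and up, with optional Gaussian jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ring_model import CouplingModel, RingSpec, activity_threshold
from .simulator import MotorParams, ensemble_activity

__all__ = [
    "DopingDataset",
    "FluorescenceTrace",
    "PoreLoopSet",
    "LOOP_LABELS",
    "gen_doping_dataset",
    "gen_fluorescence_trace",
    "gen_pore_loop_helix",
    "gen_band_timecourse",
]

LOOP_LABELS = ("NBD1-PL1", "NBD1-PL2", "NBD2-PL1", "NBD2-PL2")


@dataclass
class DopingDataset:
    """Replicate activity measurements at a grid of mutant fractions."""

    assay_kind: str  # "atpase" or "unfolding"
    data: pd.DataFrame  # columns: r, replicate, activity
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay_kind not in ("atpase", "unfolding"):
            raise ValueError(f"unknown assay_kind {self.assay_kind!r}")
        r = self.data["r"].to_numpy()
        if np.any((r < 0) | (r > 1)):
            raise ValueError("mixing fractions must lie in [0, 1]")

    @property
    def r_values(self) -> np.ndarray:
        return np.sort(self.data["r"].unique())

    def replicates_at(self, r: float) -> np.ndarray:
        return self.data.loc[self.data["r"] == r, "activity"].to_numpy()


@dataclass
class FluorescenceTrace:
    """Fluorescence time series from an unfolding assay."""

    times: np.ndarray
    fluorescence: np.ndarray
    true_rate: float | None = None  # programmed unfolding rate, for harnesses

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) < 10:
            raise ValueError("trace must have at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PoreLoopSet:
    """Labeled pore-loop Calpha positions, one point per (protomer, loop)."""

    points: pd.DataFrame  # columns: protomer, loop, x, y, z
    seam_index: int | None = None  # ground-truth seam protomer, if known

    def __post_init__(self) -> None:
        required = {"protomer", "loop", "x", "y", "z"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points needs columns {sorted(required)}")
        if self.points.duplicated(["protomer", "loop"]).any():
            raise ValueError("one point per (protomer, loop) pair required")
        if not np.isfinite(self.points[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")

    def coords(self, loop: str) -> np.ndarray:
        """Points of one loop ring, ordered by protomer index."""
        sel = self.points[self.points["loop"] == loop].sort_values("protomer")
        if sel.empty:
            raise ValueError(f"no points labeled {loop!r}")
        return sel[["x", "y", "z"]].to_numpy(dtype=float)


def _truth_mean_activity(
    truth, r: float, ring: RingSpec, n_assembled, rng, sim_kwargs
) -> float:
    if isinstance(truth, CouplingModel):
        if n_assembled is None:
            return activity_threshold(r, truth, ring)
        # finite-sample assembly noise: average over n_assembled complexes
        k = rng.binomial(ring.n_protomers, r, size=n_assembled)
        act = np.where(k >= truth.threshold_m, 0.0,
                       (ring.n_protomers - k) / ring.n_protomers)
        return float(act.mean())
    if isinstance(truth, MotorParams):
        kw = dict(n_complexes=n_assembled or 500, t_end=200.0)
        kw.update(sim_kwargs)
        seed = int(rng.integers(2**31))
        return ensemble_activity(truth, r, seed=seed,
                                 n_protomers=ring.n_protomers, **kw).atpase_activity
    raise TypeError("truth must be a CouplingModel or MotorParams")


def gen_doping_dataset(
    truth,
    r_grid,
    reps: int = 3,
    noise_sd: float = 0.02,
    n_assembled: int | None = None,
    seed=None,
    assay_kind: str = "atpase",
    ring: RingSpec = RingSpec(),
    **sim_kwargs,
) -> DopingDataset:
    """Simulate a doping experiment.

    ``truth`` is either a :class:`CouplingModel` (closed-form threshold
    curve) or :class:`MotorParams` (mechanistic simulator).  Each replicate
    activity is the finite-sample mean complex activity under the truth
    model (exact curve when ``n_assembled`` is None) plus Gaussian noise of
    SD ``noise_sd``.  Triplicates by default.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ValueError("r_grid must not be empty")
    if reps < 1 or noise_sd < 0:
        raise ValueError("reps must be >= 1 and noise_sd >= 0")
    if n_assembled is not None and n_assembled < 1:
        raise ValueError("n_assembled must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in r_grid:
        for rep in range(reps):
            mean = _truth_mean_activity(truth, float(r), ring, n_assembled,
                                        rng, sim_kwargs)
            rows.append((float(r), rep, mean + rng.normal(0.0, noise_sd)))
    data = pd.DataFrame(rows, columns=["r", "replicate", "activity"])
    meta = {
        "n_protomers": ring.n_protomers,
        "reps": reps,
        "noise_sd": noise_sd,
        "n_assembled": n_assembled,
        "seed": seed,
        "truth": repr(truth),
    }
    return DopingDataset(assay_kind=assay_kind, data=data, metadata=meta)


def gen_fluorescence_trace(
    k_unf: float,
    F0: float = 1.0,
    F_bg: float = 0.0,
    noise_sd: float = 0.0,
    dt: float = 1.0,
    t_end: float = 100.0,
    seed=None,
) -> FluorescenceTrace:
    """First-order loss of folded-substrate fluorescence.

    F(t) = F_bg + F0 exp(-k_unf t) + Gaussian noise.  The expected initial
    slope is -F0 * k_unf, which is what the initial-slope reduction recovers.
    """
    if k_unf < 0 or noise_sd < 0:
        raise ValueError("k_unf and noise_sd must be >= 0")
    times = np.arange(0.0, t_end + dt / 2, dt)
    rng = np.random.default_rng(seed)
    f = F_bg + F0 * np.exp(-k_unf * times)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=len(times))
    return FluorescenceTrace(times=times, fluorescence=f, true_rate=k_unf)


def gen_pore_loop_helix(
    n: int = 6,
    rise: float = 13.0,
    twist: float = 60.0,
    radius: float = 14.0,
    seam_radial_offset: float = 8.0,
    seam_axial_offset: float = 6.5,
    jitter_sd: float = 0.0,
    seed=None,
    loop: str = "NBD1-PL1",
) -> PoreLoopSet:
    """Ideal helical pore-loop arrangement with an off-helix seam protomer.

    Gripping protomer i (i = 0..n-2) sits at angle i*twist (degrees) and
    height i*rise on a cylinder of the given radius about the z axis; the
    seam protomer continues the angular progression but is displaced outward
    by ``seam_radial_offset`` and up by ``seam_axial_offset``, reproducing
    the protomer that bridges top and bottom of the staircase without
    touching substrate.  Gaussian jitter of SD ``jitter_sd`` is added to all
    coordinates.
    """
    if n < 4:
        raise ValueError("need at least 4 protomers")
    if not 0 < twist < 360.0 / (n - 1):
        raise ValueError(f"twist must be in (0, {360.0 / (n - 1):.1f}) degrees")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n - 1):
        ang = np.deg2rad(i * twist)
        rows.append((i, loop, radius * np.cos(ang), radius * np.sin(ang), i * rise))
    ang = np.deg2rad((n - 1) * twist)
    r_seam = radius + seam_radial_offset
    rows.append((n - 1, loop, r_seam * np.cos(ang), r_seam * np.sin(ang),
                 (n - 1) * rise + seam_axial_offset))
    pts = pd.DataFrame(rows, columns=["protomer", "loop", "x", "y", "z"])
    if jitter_sd > 0:
        pts[["x", "y", "z"]] += rng.normal(0.0, jitter_sd, size=(n, 3))
    return PoreLoopSet(points=pts, seam_index=n - 1)


def gen_band_timecourse(
    k_deg: float,
    times,
    noise_sd: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Band-intensity time course of a degradation reaction.

    Returns a tidy table with a 'complete' condition, intensity
    exp(-k_deg t) + noise, and a 'control' condition with no degradation
    (emulating the -ATP / -protease controls), both normalized to 1 at the
    start in expectation.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if k_deg < 0 or noise_sd < 0:
        raise ValueError("k_deg and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, k in (("complete", k_deg), ("control", 0.0)):
        intensity = np.exp(-k * times)
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=len(times))
        for t, y in zip(times, intensity):
            rows.append((cond, t, y))
    return pd.DataFrame(rows, columns=["condition", "time", "intensity"])
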