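"""Geometric measurements on labeled pore-loop point sets.

The substrate-engaged unfoldase arranges five of its six protomers as a
helical staircase around the unfolded chain, with the sixth (seam) protomer
bridging top and bottom off the helix.  This module fits helical parameters
(axis, rise, twist, hence pitch) to labeled pore-loop positions with the seam
identified by leave-one-out residual minimization, and computes the derived
quantities discussed for such structures: central-pore aperture, the tilt of
the pore axis between the two nucleotide-binding-domain rings, the axial
extent of substrate gripped, and the first layer line expected (and measured)
in the power spectrum of a helical filament.

Coordinates are in angstrom, right-handed frame; the cyclic protomer order of
the input is trusted, not inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HelixParams",
    "fit_helix",
    "aperture",
    "pore_tilt",
    "grip_extent",
    "layer_line",
    "measure_layer_line",
]


@dataclass
class HelixParams:
    """Fitted helical parameters of a gripping-protomer staircase."""

    axis_direction: np.ndarray  # unit vector
    axis_point: np.ndarray  # a point on the axis
    rise: float  # angstrom per protomer
    twist: float  # degrees per protomer (magnitude)
    radius: float  # angstrom
    rms_residual: float  # angstrom
    seam_index: int | None = None  # protomer excluded from the fit
    handedness: int = 1  # +1 right-handed about axis_direction

    @property
    def pitch(self) -> float:
        """Angstrom per full helical turn, rise * 360 / twist."""
        return self.rise * 360.0 / self.twist

    def to_dict(self) -> dict:
        return {
            "axis_direction": list(map(float, self.axis_direction)),
            "axis_point": list(map(float, self.axis_point)),
            "rise": self.rise,
            "twist": self.twist,
            "pitch": self.pitch,
            "radius": self.radius,
            "rms_residual": self.rms_residual,
            "seam_index": self.seam_index,
            "handedness": self.handedness,
        }


def _extract_coords(points, loop: str | None) -> np.ndarray:
    from .synthetic import PoreLoopSet

    if isinstance(points, PoreLoopSet):
        if loop is None:
            labels = points.points["loop"].unique()
            if len(labels) != 1:
                raise ValueError("multiple loop labels present; specify one")
            loop = labels[0]
        return points.coords(loop)
    return np.asarray(points, dtype=float)


def _orthonormal_frame(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ w) * w
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def _init_axis(p: np.ndarray) -> np.ndarray:
    d = np.diff(p, axis=0)
    cross = np.zeros(3)
    for i in range(len(d) - 1):
        cross += np.cross(d[i], d[i + 1])
    nrm = np.linalg.norm(cross)
    if nrm < 1e-12:
        raise ValueError("degenerate (collinear) points: no helix axis")
    w = cross / nrm
    if (p[-1] - p[0]) @ w < 0:
        w = -w
    return w


def _helix_model(params: np.ndarray, n: int) -> np.ndarray:
    theta, phi, cx, cy, cz, radius, rise, tau, phi0 = params
    w = np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
         math.cos(theta)]
    )
    u, v = _orthonormal_frame(w)
    i = np.arange(n)
    ang = phi0 + i * tau
    return (
        np.array([cx, cy, cz])
        + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
        + (i * rise)[:, None] * w
    )


def _fit_ordered_helix(p: np.ndarray) -> tuple[dict, float]:
    """Least-squares helix through points assumed at consecutive ranks."""
    n = len(p)
    w0 = _init_axis(p)
    theta0 = math.acos(np.clip(w0[2], -1, 1))
    phi0_ax = math.atan2(w0[1], w0[0])
    u, v = _orthonormal_frame(w0)
    axial = p @ w0
    rise0 = float(np.mean(np.diff(axial)))
    inplane = np.column_stack([(p @ u), (p @ v)])
    center2d = inplane.mean(axis=0)
    rel = inplane - center2d
    radius0 = float(np.mean(np.linalg.norm(rel, axis=1)))
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    tau0 = float(np.mean(np.diff(ang)))
    # rank-0 height goes into the center so the model's i=0 point matches
    c0 = center2d[0] * u + center2d[1] * v + axial[0] * w0
    x0 = np.array([theta0, phi0_ax, *c0, radius0, rise0, tau0, ang[0]])

    def resid(x):
        return (_helix_model(x, n) - p).ravel()

    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000)
    theta, phi, cx, cy, cz, radius, rise, tau, _ = sol.x
    w = np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
         math.cos(theta)]
    )
    if rise < 0:  # orient axis along increasing rank
        w, rise, tau = -w, -rise, -tau
    rms = float(np.sqrt(np.sum(sol.fun**2) / n))  # per-point rms distance
    out = {
        "axis_direction": w,
        "axis_point": np.array([cx, cy, cz]),
        "rise": float(abs(rise)),
        "twist": float(abs(math.degrees(tau))),
        "radius": float(abs(radius)),
        "handedness": 1 if tau * rise >= 0 else -1,
    }
    return out, rms


def fit_helix(points, loop: str | None = None,
              exclude_seam: bool = True) -> HelixParams:
    """Fit axis, rise and twist to pore-loop points in cyclic order.

    The single protomer whose exclusion minimizes the rms residual is
    reported as the seam and left out of the fit (the seam protomer sits off
    the gripping helix).  Points may be a PoreLoopSet (one loop label) or an
    (n, 3) array in protomer order.
    """
    p = _extract_coords(points, loop)
    if len(p) < 4:
        raise ValueError("need at least 4 labeled protomers to fit a helix")
    if np.linalg.matrix_rank(p - p.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) points: no helix axis")
    if not exclude_seam:
        fit, rms = _fit_ordered_helix(p)
        return HelixParams(**fit, rms_residual=rms, seam_index=None)

    best = None
    n = len(p)
    for seam in range(n):
        # remaining protomers, consecutive ranks starting after the seam
        order = [(seam + 1 + i) % n for i in range(n - 1)]
        try:
            fit, rms = _fit_ordered_helix(p[order])
        except ValueError:
            continue
        if best is None or rms < best[1]:
            best = (fit, rms, seam)
    if best is None:
        raise ValueError("helix fit failed for every seam candidate")
    fit, rms, seam = best
    return HelixParams(**fit, rms_residual=rms, seam_index=seam)


def aperture(points, axis_point, axis_direction) -> float:
    """Diameter of the widest cylinder passing through a ring of loops.

    Defined as twice the minimum radial distance of the points from the pore
    axis — the 'across' distance of the opening they form.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 points to define an opening")
    w = np.asarray(axis_direction, dtype=float)
    w = w / np.linalg.norm(w)
    rel = p - np.asarray(axis_point, dtype=float)
    radial = rel - np.outer(rel @ w, w)
    return float(2.0 * np.min(np.linalg.norm(radial, axis=1)))


def _plane_normal(p: np.ndarray) -> np.ndarray:
    centered = p - p.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise ValueError("degenerate ring: points are collinear")
    return vt[2]


def pore_tilt(ring1_points, ring2_points) -> float:
    """Tilt of the pore axis between two stacked rings, in degrees.

    Angle between the centroid-to-centroid vector and the mean of the two
    least-squares ring-plane normals; 0 for coaxially stacked rings, and
    atan(d/h) when one ring is displaced laterally by d at axial
    separation h.
    """
    p1 = np.asarray(ring1_points, dtype=float)
    p2 = np.asarray(ring2_points, dtype=float)
    if len(p1) < 3 or len(p2) < 3:
        raise ValueError("both rings need at least 3 points")
    c1, c2 = p1.mean(axis=0), p2.mean(axis=0)
    axis = c2 - c1
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise ValueError("coincident ring centroids: tilt undefined")
    axis = axis / nrm
    n1, n2 = _plane_normal(p1), _plane_normal(p2)
    n1 = n1 if n1 @ axis >= 0 else -n1
    n2 = n2 if n2 @ axis >= 0 else -n2
    normal = n1 + n2
    normal = normal / np.linalg.norm(normal)
    cosang = np.clip(axis @ normal, -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def grip_extent(points, axis_direction=None) -> float:
    """Axial span of substrate-contact points, in angstrom.

    Projects the points onto the pore axis (the principal direction of the
    point cloud when no axis is given) and returns the max - min span.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 contact points")
    if axis_direction is None:
        centered = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        w = vt[0]
    else:
        w = np.asarray(axis_direction, dtype=float)
        w = w / np.linalg.norm(w)
    proj = p @ w
    return float(proj.max() - proj.min())


def layer_line(pitch: float) -> float:
    """Spatial frequency (1/angstrom) of the first layer line of a helix."""
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    return 1.0 / pitch


def measure_layer_line(profile, spacing: float) -> float:
    """Locate the first off-origin power-spectrum maximum of a 1-D profile.

    ``profile`` is a density profile sampled along the filament axis every
    ``spacing`` angstrom.  Returns the spatial frequency (1/angstrom) of the
    first local maximum of the power spectrum whose power reaches at least
    10% of the strongest off-origin peak (guards against noise ripples).
    """
    y = np.asarray(profile, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if len(y) < 8:
        raise ValueError("profile too short to resolve a layer line")
    y = y - y.mean()
    if np.allclose(y, 0):
        raise ValueError("profile is constant: no layer line")
    power = np.abs(np.fft.rfft(y)) ** 2
    freqs = np.fft.rfftfreq(len(y), d=spacing)
    off = power[1:]
    floor = 0.1 * off.max()
    for i in range(1, len(power) - 1):
        if power[i] >= power[i - 1] and power[i] >= power[i + 1] and power[i] >= floor:
            return float(freqs[i])
    return float(freqs[1 + int(np.argmax(off))])
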