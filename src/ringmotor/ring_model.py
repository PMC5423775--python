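"""Closed-form subunit-poisoning model for hexameric ring ATPases.

When active and catalytically dead (Walker-B mutant) protomers are mixed at
mutant fraction ``r`` and allowed to assemble randomly, the number of dead
protomers per complex is binomial.  A threshold coupling model says hydrolysis
in the remaining functional sites is unaffected until ``m`` dead protomers are
present, at which point the whole complex stops.  The fractional ensemble
activity, normalized to the all-wild-type rate, is then

    A(r) = (1/n) * sum_{j=0}^{m-1} (n - j) * C(n, j) * r^j * (1 - r)^(n - j)

with the two special cases A = (1-r)^n for m = 1 (a single dead protomer
poisons the complex, as expected for a strictly sequential hand-over-hand
cycle) and A = 1 - r for m = n + 1 (no coupling: every active protomer
hydrolyzes independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import binom

__all__ = [
    "RingSpec",
    "CouplingModel",
    "CompositionPMF",
    "ActivityCurve",
    "composition_pmf",
    "activity_threshold",
    "enumeration_oracle",
    "activity_curve",
]

_MAX_ENUM_PROTOMERS = 20


@dataclass(frozen=True)
class RingSpec:
    """Geometry of the oligomeric ring.

    Parameters
    ----------
    n_protomers
        Protomers per complex (6 for the hexameric unfoldase).
    sites_per_protomer
        Nucleotide-binding sites per protomer (2 for a double-ring AAA+
        enzyme: one per nucleotide-binding domain).
    """

    n_protomers: int = 6
    sites_per_protomer: int = 2

    def __post_init__(self) -> None:
        if self.n_protomers < 2:
            raise ValueError(f"n_protomers must be >= 2, got {self.n_protomers}")
        if self.sites_per_protomer < 1:
            raise ValueError(
                f"sites_per_protomer must be >= 1, got {self.sites_per_protomer}"
            )


@dataclass(frozen=True)
class CouplingModel:
    """Threshold coupling between dead protomers and ring activity.

    ``threshold_m`` dead protomers abolish all hydrolysis in a complex.
    ``threshold_m = n_protomers + 1`` encodes the uncoupled (independent
    sites) model, for which the activity reduces exactly to ``1 - r``.
    """

    threshold_m: int

    def validate(self, ring: RingSpec) -> None:
        if not 1 <= self.threshold_m <= ring.n_protomers + 1:
            raise ValueError(
                f"threshold_m must be in [1, {ring.n_protomers + 1}], "
                f"got {self.threshold_m}"
            )


@dataclass(frozen=True)
class CompositionPMF:
    """Distribution of the number of dead protomers per assembled complex."""

    probabilities: np.ndarray
    mixing_fraction_r: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < -1e-15):
            raise ValueError("composition probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"composition probabilities sum to {p.sum()}, not 1")

    @property
    def n_protomers(self) -> int:
        return len(self.probabilities) - 1


@dataclass
class ActivityCurve:
    """Fractional activity versus mutant doping fraction.

    ``activity`` is normalized so the all-wild-type (r = 0) value is 1 for
    closed-form curves; ``stderr`` carries replicate or Monte-Carlo standard
    errors where available.
    """

    r_values: np.ndarray
    activity: np.ndarray
    stderr: np.ndarray | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        d = {"r": self.r_values, "activity": self.activity}
        if self.stderr is not None:
            d["stderr"] = self.stderr
        return pd.DataFrame(d)


def _check_r(r: float) -> float:
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"mixing fraction r must be in [0, 1], got {r}")
    return r


def composition_pmf(r: float, ring: RingSpec = RingSpec()) -> CompositionPMF:
    """Binomial distribution of dead-protomer counts at mixing fraction ``r``.

    Assembly is assumed unbiased: each of the ``n_protomers`` slots is filled
    by a mutant with probability ``r`` independently, so the count of dead
    protomers k follows Binomial(n_protomers, r).
    """
    r = _check_r(r)
    k = np.arange(ring.n_protomers + 1)
    p = binom.pmf(k, ring.n_protomers, r)
    return CompositionPMF(probabilities=p, mixing_fraction_r=r)


def activity_threshold(
    r: float, coupling: CouplingModel, ring: RingSpec = RingSpec()
) -> float:
    """Fractional ensemble activity under the threshold coupling model.

    Complexes with fewer than ``m`` dead protomers run at the fraction of
    sites that remain functional, (n - k)/n; complexes at or past the
    threshold are fully inactive.
    """
    r = _check_r(r)
    coupling.validate(ring)
    n = ring.n_protomers
    j = np.arange(min(coupling.threshold_m, n + 1))
    terms = (n - j) / n * binom.pmf(j, n, r)
    return float(terms.sum())


def enumeration_oracle(
    r: float, coupling: CouplingModel, ring: RingSpec = RingSpec()
) -> float:
    """Brute-force check of :func:`activity_threshold`.

    Enumerates all 2**n labeled active/dead protomer configurations, weights
    each by r^k (1-r)^(n-k), and averages the per-complex activity
    (0 if k >= m, else (n - k)/n).  Exponential in n; refuses n > 20.
    """
    r = _check_r(r)
    coupling.validate(ring)
    n = ring.n_protomers
    if n > _MAX_ENUM_PROTOMERS:
        raise ValueError(
            f"enumeration over 2^{n} configurations refused (n_protomers "
            f"must be <= {_MAX_ENUM_PROTOMERS})"
        )
    m = coupling.threshold_m
    total = 0.0
    for config in product((0, 1), repeat=n):
        k = sum(config)
        weight = r**k * (1.0 - r) ** (n - k)
        act = 0.0 if k >= m else (n - k) / n
        total += weight * act
    return total


def activity_curve(
    r_values: np.ndarray,
    coupling: CouplingModel,
    ring: RingSpec = RingSpec(),
) -> ActivityCurve:
    """Evaluate the threshold model on a grid of mixing fractions."""
    r_values = np.asarray(r_values, dtype=float)
    act = np.array([activity_threshold(r, coupling, ring) for r in r_values])
    return ActivityCurve(
        r_values=r_values,
        activity=act,
        label=f"m={coupling.threshold_m}",
        metadata={"n": ring.n_protomers, "m": coupling.threshold_m},
    )
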