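"""Förster-law conversions between inter-dye distance and FRET efficiency.

The energy-transfer efficiency between a donor/acceptor pair separated by a
distance ``R`` follows ``E = 1 / (1 + (R/R0)**6)``, where the Förster radius
``R0`` is the distance of half-maximal transfer (52 Å for the Alexa488/Cy5
pair used throughout this package).  Only the distance dependence is modelled
here; ``R0`` is always supplied by the caller, typically from the literature
value for the dye pair, and no κ² orientation-factor correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceSummary",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "ensemble_efficiency",
]

#: Förster radius of the Alexa488/Cy5 pair, Å.
DEFAULT_R0 = 52.0


@dataclass
class DistanceSummary:
    """Summary of an inter-dye distance distribution.

    Parameters
    ----------
    mean : float
        Mean inter-dye distance, Å. Must be positive.
    sd : float
        Standard deviation of the distance distribution, Å.
    samples : list of float, optional
        Individual distance samples (Å); required by the ``mean_of_E``
        averaging regime.
    centroid_distance : float, optional
        Distance between the centroids of the two dye clouds, Å; reported
        alongside the pairwise mean when derived from accessible-volume
        clouds.
    """

    mean: float
    sd: float = 0.0
    samples: list[float] | None = None
    centroid_distance: float | None = None

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"mean distance must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")


def efficiency_from_distance(r: float, r0: float = DEFAULT_R0):
    """FRET efficiency at inter-dye distance ``r`` for Förster radius ``r0``.

    Strictly decreasing in ``r``; returns 1 at contact and 0.5 exactly at
    ``r == r0``.  Accepts array input.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    if not r0 > 0:
        raise ValueError("R0 must be positive")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


def distance_from_efficiency(e: float, r0: float = DEFAULT_R0):
    """Inter-dye distance at which the Förster law gives efficiency ``e``.

    Closed-form inverse of :func:`efficiency_from_distance`; valid for
    ``0 < e <= 1``.
    """
    e = np.asarray(e, dtype=float)
    if np.any((e <= 0) | (e > 1)):
        raise ValueError("efficiency must lie in (0, 1]")
    if not r0 > 0:
        raise ValueError("R0 must be positive")
    out = r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def ensemble_efficiency(
    dist: DistanceSummary,
    r0: float = DEFAULT_R0,
    regime: str = "E_of_mean_R",
) -> float:
    """Ensemble FRET efficiency from a distance distribution.

    ``E_of_mean_R`` (default) evaluates the Förster law at the mean distance —
    the single-number prediction used when a structure-derived average
    distance is quoted.  ``mean_of_E`` averages per-sample efficiencies and
    requires ``dist.samples``; the two differ for broad distributions because
    the Förster law is non-linear.
    """
    if regime == "E_of_mean_R":
        return efficiency_from_distance(dist.mean, r0)
    if regime == "mean_of_E":
        if dist.samples is None or len(dist.samples) == 0:
            raise ValueError("mean_of_E regime requires distance samples")
        return float(np.mean(efficiency_from_distance(np.asarray(dist.samples), r0)))
    raise ValueError(f"unknown regime {regime!r}")
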