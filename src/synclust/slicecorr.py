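"""Slice-truncation correction for presynaptic axon density.

Mapping synapses in an acute brain slice misses inputs whose
presynaptic axons were cut away.  Given a radial crossing-count
profile (Sholl-style) of the presynaptic population's axons, the
radial axon density is ``A(r) = crossings / (4π r² δr)``.  For a
dendritic site at depth ``D`` inside a slice of thickness ``T``, a
spherical shell of radius ``r`` around the site is truncated by the
slice faces: complete for ``r`` below the near-face distance, one cap
removed between the near- and far-face distances, two caps removed
beyond.  Weighting the shell volumes by ``A(r)`` gives the remaining
fraction ``F(D)`` of presynaptic axonal density; ``1 − F`` estimates
the inputs missed by slicing.  Presynaptic neuron density is assumed
uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RadialProfile:
    """Binned radial crossing counts around the presynaptic somata.

    ``r`` are strictly increasing shell-center radii (µm), ``crossings``
    the counts per shell, ``delta_r`` the shell thickness, and
    ``r_max`` the maximal radial extent of the axonal density (defaults
    to the outer edge of the last bin).
    """

    r: np.ndarray
    crossings: np.ndarray
    delta_r: float
    r_max: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.crossings = np.asarray(self.crossings, dtype=float)
        if self.r.size == 0:
            raise ValueError("profile must have at least one bin")
        if self.r.shape != self.crossings.shape:
            raise ValueError("r and crossings must be aligned")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")
        if np.any(self.crossings < 0):
            raise ValueError("crossings must be nonnegative")
        if self.delta_r <= 0:
            raise ValueError("delta_r must be positive")
        if self.r_max is None:
            self.r_max = float(self.r[-1] + self.delta_r / 2)
        if self.r_max < self.r[-1]:
            raise ValueError("r_max cannot be below the last bin center")


@dataclass(frozen=True)
class SliceGeometry:
    """Slice thickness ``T`` and dendritic-site depth ``D`` (µm), ``0 < D < T``."""

    T: float
    D: float

    def __post_init__(self) -> None:
        if not 0 < self.D < self.T:
            raise ValueError("geometry requires 0 < D < T")

    @property
    def d_near(self) -> float:
        """Distance to the nearer slice face."""
        return min(self.D, self.T - self.D)

    @property
    def d_far(self) -> float:
        """Distance to the farther slice face."""
        return max(self.D, self.T - self.D)


def load_radial_profile(path: str | Path, delta_r: float | None = None) -> RadialProfile:
    """Read a profile CSV with columns ``r_um`` and ``crossings``.

    When ``delta_r`` is omitted it is inferred from the bin spacing.
    """
    table = pd.read_csv(path)
    for col in ("r_um", "crossings"):
        if col not in table.columns:
            raise ValueError(f"radial profile {path} is missing column {col!r}")
    r = table["r_um"].to_numpy(dtype=float)
    if delta_r is None:
        if r.size < 2:
            raise ValueError("cannot infer delta_r from a single bin; pass it explicitly")
        delta_r = float(np.median(np.diff(r)))
    return RadialProfile(r, table["crossings"].to_numpy(dtype=float), delta_r)


def radial_density(profile: RadialProfile) -> np.ndarray:
    """Radial axon density ``A(r) = crossings / (4π r² δr)`` per bin."""
    r = profile.r
    if np.any((r <= 0) & (profile.crossings > 0)):
        raise ValueError("nonzero crossings at r <= 0 are unphysical")
    out = np.zeros_like(r)
    ok = r > 0
    out[ok] = profile.crossings[ok] / (4.0 * np.pi * r[ok] ** 2 * profile.delta_r)
    return out


def shell_volume(r, geom: SliceGeometry, delta_r: float = 1.0):
    """Volume of the spherical shell of radius ``r`` retained inside the slice.

    Piecewise in ``r`` against the near/far face distances: complete
    shell ``4πr²δr``; one cap removed ``2πr(r + d_near)δr``; two caps
    removed ``2πrTδr``.  The pieces are continuous at both boundaries.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    full = 4.0 * np.pi * r**2
    one_cap = 2.0 * np.pi * r * (r + geom.d_near)
    two_cap = 2.0 * np.pi * r * geom.T
    out = np.where(r <= geom.d_near, full, np.where(r <= geom.d_far, one_cap, two_cap))
    return out * delta_r if out.ndim else float(out * delta_r)


def remaining_fraction(profile: RadialProfile, geom: SliceGeometry) -> float:
    """Remaining fraction ``F(D)`` of presynaptic axonal density in the slice.

    Midpoint quadrature over the profile's own bins of
    ``Σ A(r)·V_slab(r) / Σ A(r)·4πr²δr``; ``F ∈ (0, 1]``, exactly 1
    when the profile lies entirely within the near-face distance.
    Returns NaN (with a warning) if the total density is zero.
    """
    A = radial_density(profile)
    full = 4.0 * np.pi * profile.r**2 * profile.delta_r
    den = float(np.sum(A * full))
    if den == 0:
        warnings.warn("radial profile carries zero total density; F undefined")
        return float("nan")
    num = float(np.sum(A * shell_volume(profile.r, geom, profile.delta_r)))
    return num / den


def missed_fraction(profile: RadialProfile, geom: SliceGeometry) -> float:
    """Estimated fraction of inputs missed by slicing, ``1 − F(D)``."""
    return 1.0 - remaining_fraction(profile, geom)
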