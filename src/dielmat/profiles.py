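"""Spatially resolved depth-profile analysis of laser-ablation IRMS data.

A depth profile is an ordered series of ~50 um ablation spots down a
microbial mat cross-section.  Because mat surfaces are textured, absolute
profile lengths differ; each profile is therefore normalized onto a 0 (upper,
illuminated surface) to 1 (bottom) axis before any comparison.  On that axis
the module converts spot delta13C values into percent-replacement profiles,
integrates them by trapezoidal quadrature, partitions the integrated tracer
across the photic boundary (the depth where scalar irradiance falls to a
threshold, default 10 umol photons PAR m-2 s-1), and accounts for diel
gain/loss between sampling timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import isotopes as iso
from .errors import (
    DegenerateProfileError,
    NoBoundaryError,
    UndefinedLossError,
    UndefinedPartitionError,
)

#: Scalar irradiance threshold defining the photic boundary
#: (umol photons PAR m-2 s-1).
PHOTIC_IRRADIANCE_THRESHOLD = 10.0


@dataclass(frozen=True)
class SpotMeasurement:
    """One laser-ablation spot: depth below the mat surface and delta13C."""

    depth_um: float
    delta_c13: float


@dataclass
class DepthProfile:
    """An ordered series of ablation spots down one mat cross-section."""

    profile_id: str
    depths_um: np.ndarray
    deltas: np.ndarray
    timepoint_h: float = 0.0
    treatment: str = ""
    normalized_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.depths_um.shape != self.deltas.shape:
            raise DegenerateProfileError("depths and deltas differ in length")
        if np.any(self.depths_um < 0):
            raise DegenerateProfileError("depths must be >= 0 um")
        if np.any(np.diff(self.depths_um) <= 0):
            raise DegenerateProfileError(
                "spots must be sorted by strictly increasing depth"
            )

    @classmethod
    def from_spots(cls, profile_id: str, spots: list[SpotMeasurement],
                   **kw) -> "DepthProfile":
        spots = sorted(spots, key=lambda s: s.depth_um)
        return cls(profile_id,
                   np.array([s.depth_um for s in spots]),
                   np.array([s.delta_c13 for s in spots]), **kw)

    @property
    def n_spots(self) -> int:
        return len(self.depths_um)


@dataclass
class ReplacementProfile:
    """Percent C replacement at each (normalized) depth of a profile."""

    profile_id: str
    depths: np.ndarray  # normalized, 0..1
    percent: np.ndarray
    flags: np.ndarray  # True where replacement is suspiciously negative
    timepoint_h: float = 0.0
    treatment: str = ""


@dataclass(frozen=True)
class PhoticPartition:
    """Split of the depth-integrated tracer across the photic boundary."""

    boundary: float
    fraction_below: float
    fraction_above: float
    total_integral: float
    flagged: bool = False


def normalize_depth(profile: DepthProfile) -> DepthProfile:
    """Map spot depths affinely onto [0, 1] (surface -> 0, bottom -> 1)."""
    if profile.n_spots < 2:
        raise DegenerateProfileError("need >= 2 spots to normalize a profile")
    d = profile.depths_um
    span = d[-1] - d[0]
    if span <= 0:
        raise DegenerateProfileError("all spot depths equal; cannot normalize")
    return replace(profile, normalized_depths=(d - d[0]) / span)


def replacement_profile(
    profile: DepthProfile,
    control,
    substrate: iso.SubstrateSpec,
    constants: iso.IsotopeConstants = iso.DEFAULT_CONSTANTS,
    negative_tolerance: float = -0.1,
) -> ReplacementProfile:
    """Per-spot percent replacement down a normalized profile.

    ``control`` is either a scalar delta13C of unlabeled mat biomass or a
    control :class:`DepthProfile`, which is normalized and linearly
    interpolated onto the sample's normalized grid (so control spots need
    not align with sample spots).  Spots more negative than
    ``negative_tolerance`` percent are flagged, never clipped.
    """
    if profile.normalized_depths is None:
        profile = normalize_depth(profile)
    f_sub = iso.effective_substrate_atom_fraction(substrate, constants)
    f_sample = iso.delta_to_atom_fraction(profile.deltas, constants)

    if isinstance(control, DepthProfile):
        if control.n_spots < 2:
            raise DegenerateProfileError(
                "control profile needs >= 2 spots for interpolation"
            )
        if control.normalized_depths is None:
            control = normalize_depth(control)
        ctrl_delta = np.interp(profile.normalized_depths,
                               control.normalized_depths, control.deltas)
        # elementwise mass balance with a depth-varying control
        f_ctrl = iso.delta_to_atom_fraction(ctrl_delta, constants)
        pct = 100.0 * (f_sample - f_ctrl) / (f_sub - f_ctrl)
    else:
        f_ctrl = iso.delta_to_atom_fraction(float(control), constants)
        pct = iso.percent_replacement(f_sample, f_ctrl, f_sub)

    pct = np.asarray(pct, dtype=float)
    return ReplacementProfile(
        profile_id=profile.profile_id,
        depths=np.asarray(profile.normalized_depths),
        percent=pct,
        flags=pct < negative_tolerance,
        timepoint_h=profile.timepoint_h,
        treatment=profile.treatment,
    )


@dataclass(frozen=True)
class MeanReplacement:
    """Depth-weighted (trapezoidal) and plain spot means of a profile."""

    integrated: float
    spot_mean: float


def mean_replacement(rp: ReplacementProfile) -> MeanReplacement:
    """Average percent replacement over a profile.

    The primary statistic is the trapezoidal integral over normalized depth
    divided by the depth span, which weights spots by the interval they
    represent; the unweighted spot mean is returned alongside for
    comparison with per-spot summaries.
    """
    if len(rp.depths) < 2:
        raise DegenerateProfileError("need >= 2 points to integrate")
    span = rp.depths[-1] - rp.depths[0]
    integrated = float(np.trapezoid(rp.percent, rp.depths) / span)
    return MeanReplacement(integrated=integrated,
                           spot_mean=float(np.mean(rp.percent)))


def partition_at_boundary(
    rp: ReplacementProfile,
    boundary: float,
    negative_total_tolerance: float = 1e-9,
) -> PhoticPartition:
    """Fraction of the depth-integrated replacement below/above a boundary.

    The profile is treated as piecewise linear; a virtual point is
    interpolated at the boundary so the two sub-integrals tile the total
    exactly.  A total integral that is non-positive but within
    ``negative_total_tolerance`` of zero (noise around an unlabeled
    profile) yields a flagged partition with NaN fractions instead of an
    exception.
    """
    if not 0 < boundary < 1:
        raise UndefinedPartitionError(
            f"boundary must lie in (0, 1), got {boundary}"
        )
    x, y = rp.depths, rp.percent
    yb = np.interp(boundary, x, y)
    above_mask = x <= boundary
    xa = np.append(x[above_mask], boundary)
    ya = np.append(y[above_mask], yb)
    xb = np.insert(x[~above_mask], 0, boundary)
    yb_arr = np.insert(y[~above_mask], 0, yb)
    above = float(np.trapezoid(ya, xa)) if len(xa) > 1 else 0.0
    below = float(np.trapezoid(yb_arr, xb)) if len(xb) > 1 else 0.0
    total = above + below
    if total <= 0:
        if total > -negative_total_tolerance:
            return PhoticPartition(boundary, float("nan"), float("nan"),
                                   total, flagged=True)
        raise UndefinedPartitionError(
            f"total profile integral is {total}; partition undefined"
        )
    return PhoticPartition(boundary, below / total, above / total, total)


def boundary_from_irradiance(
    depths,
    irradiance,
    threshold: float = PHOTIC_IRRADIANCE_THRESHOLD,
) -> float:
    """Normalized depth where scalar irradiance first falls to a threshold.

    Linear interpolation between the bracketing tabulated points; 0 when
    the surface is already at or below the threshold.  A non-monotone
    profile earns a warning and the first crossing is used.
    """
    z = np.asarray(depths, dtype=float)
    irr = np.asarray(irradiance, dtype=float)
    if z.shape != irr.shape or len(z) < 2:
        raise NoBoundaryError("need matching depth/irradiance arrays, n >= 2")
    if np.any(np.diff(irr) > 0):
        warnings.warn(
            "irradiance profile is not monotone non-increasing; "
            "using first threshold crossing",
            stacklevel=2,
        )
    if irr[0] <= threshold:
        return 0.0
    below = np.nonzero(irr <= threshold)[0]
    if len(below) == 0:
        raise NoBoundaryError(
            f"irradiance never reaches threshold {threshold}"
        )
    i = below[0]
    z1, z2, i1, i2 = z[i - 1], z[i], irr[i - 1], irr[i]
    return float(z1 + (z2 - z1) * (i1 - threshold) / (i1 - i2))


def diel_loss(uptake_earlier: float, uptake_later: float) -> float:
    """Percent of earlier-held tracer C lost by the later timepoint.

    Negative values mean net gain over the interval and are returned
    as-is so callers can distinguish nighttime loss from daytime gain.
    """
    if uptake_earlier <= 0:
        raise UndefinedLossError(
            f"uptake at the earlier timepoint must be > 0, "
            f"got {uptake_earlier}"
        )
    return 100.0 * (uptake_earlier - uptake_later) / uptake_earlier


def combine_profile_means(means: list[MeanReplacement]) -> MeanReplacement:
    """Average per-profile statistics across replicate profiles.

    Replicate profiles have unequal spot counts, so statistics are computed
    per profile first and then averaged across profiles (never by pooling
    spots).
    """
    if not means:
        raise DegenerateProfileError("no profiles to combine")
    return MeanReplacement(
        integrated=float(np.mean([m.integrated for m in means])),
        spot_mean=float(np.mean([m.spot_mean for m in means])),
    )
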