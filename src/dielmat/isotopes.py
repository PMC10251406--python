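"""Carbon isotope-ratio arithmetic and the two-pool tracer mass balance.

All measurements are expressed in standard delta notation,

    delta13C = (R_sample / R_standard - 1) * 1000   [permil vs VPDB],

with the VPDB reference ratio R_standard = 0.0112372.  At the high
enrichments produced by 13C tracer additions (tens of atom percent), delta
values are a badly non-linear coordinate, so every mixing computation in
this module is carried out in atom-fraction space,

    F = 13C / (12C + 13C) = R / (1 + R),

which is exactly conservative for a two-pool carbon mass balance.  The
percent replacement of biomass carbon by substrate-derived carbon is then
the linear un-mixing

    replacement% = 100 * (F_sample - F_control) / (F_substrate - F_control).

Functions accept scalars or numpy arrays and return the matching shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DegenerateCalibrationError,
    DegenerateEndMembersError,
    InvalidMeasurementError,
)

#: 13C/12C ratio of the Vienna Pee Dee Belemnite standard.
R_VPDB = 0.0112372

#: Representative natural 13C atom fraction used for binomial isotopomer
#: models of unlabeled material (IUPAC representative value, 1.07 atom %).
F13_NATURAL = 0.0107


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the carbon isotope system.

    Parameters
    ----------
    r_vpdb
        13C/12C ratio of the VPDB reference.
    f13_natural
        Natural 13C atom fraction assumed for unlabeled biological
        material; used by the mass-isotopomer module as the binomial
        success probability of each carbon being 13C.
    """

    r_vpdb: float = R_VPDB
    f13_natural: float = F13_NATURAL

    def __post_init__(self) -> None:
        if not self.r_vpdb > 0:
            raise ConfigError(f"r_vpdb must be positive, got {self.r_vpdb}")
        if not 0 < self.f13_natural < 0.02:
            raise ConfigError(
                f"f13_natural must lie in (0, 0.02), got {self.f13_natural}"
            )


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass
class IsotopeMeasurement:
    """One delta13C measurement with optional uncertainty.

    ``delta_c13`` is permil vs VPDB; ``sd`` is a one-sigma standard
    deviation in permil across ``n_replicates`` replicates.
    """

    delta_c13: float
    sd: float | None = None
    n_replicates: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.delta_c13 > -1000:
            raise InvalidMeasurementError(
                f"delta13C must exceed -1000 permil (got {self.delta_c13}); "
                "an atom fraction cannot be negative"
            )
        if self.sd is not None and self.sd < 0:
            raise InvalidMeasurementError(f"sd must be >= 0, got {self.sd}")


@dataclass
class SubstrateSpec:
    """A labeled substrate addition acting as a mixing end-member.

    ``label_atom_fraction`` is the 13C atom fraction of the added chemical
    species; ``background_conc``/``background_delta`` describe an ambient
    pool of the same species (e.g. lake-water DIC for bicarbonate
    additions) that dilutes the effective end-member.
    """

    name: str
    added_conc: float  # mM
    label_atom_fraction: float
    background_conc: float = 0.0  # mM
    background_delta: float | None = None  # permil vs VPDB

    def __post_init__(self) -> None:
        if not self.added_conc > 0:
            raise ConfigError(f"added_conc must be > 0, got {self.added_conc}")
        if not 0 <= self.label_atom_fraction <= 1:
            raise ConfigError(
                f"label_atom_fraction must lie in [0, 1], got "
                f"{self.label_atom_fraction}"
            )
        if self.background_conc < 0:
            raise ConfigError(
                f"background_conc must be >= 0, got {self.background_conc}"
            )


def default_substrates() -> dict[str, SubstrateSpec]:
    """The three substrate end-members of the diel labeling design.

    50 atom% bicarbonate at 2.25 mM, and uniformly labeled (99 atom%)
    acetate at 2.2 mM and glucose at 5 mM.  Background DIC dilution is off
    by default (ambient concentration unquantified); enable it per
    substrate via ``background_conc``/``background_delta``.
    """
    return {
        "bicarbonate": SubstrateSpec("bicarbonate", added_conc=2.25,
                                     label_atom_fraction=0.50),
        "acetate": SubstrateSpec("acetate", added_conc=2.2,
                                 label_atom_fraction=0.99),
        "glucose": SubstrateSpec("glucose", added_conc=5.0,
                                 label_atom_fraction=0.99),
    }


@dataclass(frozen=True)
class CalibrationPair:
    """A reference material measured against its certified delta13C."""

    standard_id: str
    certified_delta: float
    measured_delta: float


def _as_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def delta_to_ratio(delta, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert delta13C (permil vs VPDB) to the 13C/12C ratio."""
    arr, scalar = _as_array(delta)
    if np.any(arr <= -1000):
        raise InvalidMeasurementError(
            "delta13C must exceed -1000 permil; got values <= -1000"
        )
    return _ret((arr / 1000.0 + 1.0) * constants.r_vpdb, scalar)


def ratio_to_delta(ratio, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert a 13C/12C ratio to delta13C (permil vs VPDB)."""
    arr, scalar = _as_array(ratio)
    if np.any(arr <= 0):
        raise InvalidMeasurementError("isotope ratio must be positive")
    return _ret((arr / constants.r_vpdb - 1.0) * 1000.0, scalar)


def delta_to_atom_fraction(delta,
                           constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert delta13C to the 13C atom fraction F = R/(1+R)."""
    arr, scalar = _as_array(delta_to_ratio(delta, constants))
    return _ret(arr / (1.0 + arr), scalar)


def atom_fraction_to_delta(f,
                           constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert a 13C atom fraction in (0, 1) to delta13C."""
    arr, scalar = _as_array(f)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise InvalidMeasurementError(
            "atom fraction must lie strictly inside (0, 1)"
        )
    return _ret(np.asarray(ratio_to_delta(arr / (1.0 - arr), constants)),
                scalar)


def two_point_correction(pairs: Sequence[CalibrationPair], raw):
    """Apply a linear calibration fitted through reference materials.

    Fits ``certified = a * measured + b`` through the pairs (ordinary least
    squares when more than two are given) and applies it to ``raw``.  Two
    distinct certified values are required; the canonical pairing is USGS 40
    and USGS 41 glutamic acid (-26.39 and +37.63 permil).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise DegenerateCalibrationError(
            "two-point correction needs at least two calibration pairs"
        )
    certified = np.array([p.certified_delta for p in pairs], dtype=float)
    measured = np.array([p.measured_delta for p in pairs], dtype=float)
    if np.ptp(certified) == 0:
        raise DegenerateCalibrationError(
            "all certified deltas identical; calibration line undefined"
        )
    if np.ptp(measured) == 0:
        raise DegenerateCalibrationError(
            "all measured deltas identical; calibration line undefined"
        )
    a, b = np.polyfit(measured, certified, 1)
    arr, scalar = _as_array(raw)
    return _ret(a * arr + b, scalar)


def effective_substrate_atom_fraction(
    spec: SubstrateSpec,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> float:
    """Concentration-weighted 13C atom fraction of the substrate pool.

    When an ambient background pool of the same species is declared, the
    effective end-member is the mole-weighted mean of the added and
    background atom fractions; with no background it is simply the added
    substrate's enrichment.
    """
    if spec.background_conc > 0:
        if spec.background_delta is None:
            raise ConfigError(
                f"substrate {spec.name!r}: background_conc > 0 requires "
                "background_delta"
            )
        f_bg = delta_to_atom_fraction(spec.background_delta, constants)
        total = spec.added_conc + spec.background_conc
        return (spec.added_conc * spec.label_atom_fraction
                + spec.background_conc * f_bg) / total
    return spec.label_atom_fraction


def percent_replacement(f_sample, f_control, f_substrate):
    """Percent of biomass carbon derived from the labeled substrate.

    Linear two-pool un-mixing in atom-fraction space.  Values are not
    clipped: measurement noise can legitimately produce slightly negative
    replacements, which downstream code flags rather than hides.
    """
    f_control = float(f_control)
    f_substrate = float(f_substrate)
    for name, v in (("f_control", f_control), ("f_substrate", f_substrate)):
        if not 0 < v < 1:
            raise InvalidMeasurementError(
                f"{name} must lie in (0, 1), got {v}"
            )
    if f_substrate == f_control:
        raise DegenerateEndMembersError(
            "substrate and control atom fractions coincide; "
            "replacement is undefined"
        )
    arr, scalar = _as_array(f_sample)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise InvalidMeasurementError("f_sample must lie in (0, 1)")
    return _ret(100.0 * (arr - f_control) / (f_substrate - f_control), scalar)
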