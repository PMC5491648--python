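"""Physio-biochemical assay calculators.

Each function implements one published assay formula on a single reading;
replicate aggregation and group statistics live in :mod:`saltphen.stats`.
All arithmetic is kept in full precision — rounding happens only in report
writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SpectroReading",
    "ConductivityPair",
    "StandardCurve",
    "ScavengingCurve",
    "IonProfile",
    "total_chlorophyll",
    "mda_level",
    "membrane_stability_index",
    "proline_content",
    "fit_standard_curve",
    "interpolate_concentration",
    "dpph_scavenging",
    "ic50",
    "percent_change",
    "ion_ratio",
]

#: Denominator printed with the lipid-peroxidation formula.  The stated
#: extinction coefficient of 155 mM^-1 cm^-1 would imply 1.55e5; both are
#: supported via the ``coefficient`` argument, with the printed value as
#: default.  See docs/methods.md for the unit discussion.
MDA_DEFAULT_COEFFICIENT = 1.56e5

#: Proline molar mass expressed as µg/µmol, as used in the ninhydrin assay.
PROLINE_UG_PER_UMOL = 115.5


@dataclass
class SpectroReading:
    """One spectrophotometer reading set for a sample.

    ``absorbances`` maps wavelength labels (``"A645"``, ``"A663"``, ``"A532"``,
    ``"A600"``, ``"A630"``, ``"A760"``, ``"A517"``...) to unitless absorbance.
    """

    sample_id: str
    absorbances: Mapping[str, float]
    sample_mass: float = 1.0  # grams fresh or dry weight
    extract_volume: float = 1.0  # mL
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for label, a in self.absorbances.items():
            if a < 0:
                raise ValueError(f"absorbance {label} must be >= 0, got {a}")
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be > 0")
        if self.extract_volume <= 0:
            raise ValueError("extract_volume must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass
class ConductivityPair:
    """Electrolyte-leakage conductivities: EC1 unboiled, EC2 autoclaved."""

    ec1: float
    ec2: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ec1 < 0:
            raise ValueError("ec1 must be >= 0")
        if self.ec2 < 0:
            raise ValueError("ec2 must be >= 0")

    @property
    def leakage_exceeds_total(self) -> bool:
        """True when EC1 > EC2 — physically suspect, flagged not fatal."""
        return self.ec1 > self.ec2


@dataclass
class StandardCurve:
    """Least-squares calibration line: absorbance = slope * conc + intercept."""

    points: Sequence[tuple[float, float]]
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")

    @property
    def fitted(self) -> bool:
        return math.isfinite(self.slope)


@dataclass
class ScavengingCurve:
    """DPPH dose–response points (extract concentration, scavenging percent)."""

    points: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c <= 0 for c in concs):
            raise ValueError("extract concentrations must be strictly positive")
        if len(set(concs)) != len(concs):
            raise ValueError("extract concentrations must be unique")
        if any(s > 100 for _, s in self.points):
            raise ValueError("scavenging percent cannot exceed 100")


@dataclass
class IonProfile:
    """Cation concentrations (per unit dry weight) for one sample."""

    sample_id: str
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"{ion} concentration must be >= 0, got {c}")


def total_chlorophyll(a645: float, a663: float) -> float:
    """Total chlorophyll (mg/g FW) from DMSO-extract absorbances.

    Uses the two-wavelength Arnon-type relation
    ``20.2 * A645 + 8.02 * A663``.
    """
    if a645 < 0 or a663 < 0:
        raise ValueError("absorbances must be >= 0")
    return 20.2 * a645 + 8.02 * a663


def mda_level(
    a532: float, a600: float, coefficient: float = MDA_DEFAULT_COEFFICIENT
) -> float:
    """Malondialdehyde level from the TBARS assay: ``(A532 - A600) / coefficient``.

    ``coefficient`` defaults to the printed 1.56e5 denominator; pass 1.55e5 to
    use the value implied by the 155 mM^-1 cm^-1 extinction coefficient.
    """
    if a532 < 0 or a600 < 0:
        raise ValueError("absorbances must be >= 0")
    if coefficient <= 0:
        raise ValueError("extinction denominator must be > 0")
    return (a532 - a600) / coefficient


def membrane_stability_index(pair: ConductivityPair) -> float:
    """MSI (%) = 100 * (1 - EC1/EC2); 100 = no leakage, 0 = total leakage."""
    if pair.ec2 == 0:
        raise ZeroDivisionError(
            "autoclaved-set conductivity (EC2) is zero; MSI undefined"
        )
    return 100.0 * (1.0 - pair.ec1 / pair.ec2)


def proline_content(conc_ug_per_ml: float, toluene_ml: float, sample_g: float) -> float:
    """Proline (µM/g DW) from the ninhydrin–toluene assay.

    ``[(µg proline/mL × mL toluene) / 115.5 µg/µmol] / (g sample / 5)``.
    """
    if conc_ug_per_ml <= 0 or toluene_ml <= 0:
        raise ValueError("concentration and toluene volume must be > 0")
    if sample_g <= 0:
        raise ValueError("sample mass must be > 0")
    return ((conc_ug_per_ml * toluene_ml) / PROLINE_UG_PER_UMOL) / (sample_g / 5.0)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit absorbance = slope*concentration + intercept by ordinary least squares.

    Points are (concentration, absorbance) pairs; at least two distinct
    concentrations are required.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 calibration points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    absb = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("degenerate fit: all calibration concentrations identical")
    res = _sps.linregress(conc, absb)
    return StandardCurve(
        points=list(points),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def interpolate_concentration(curve: StandardCurve, absorbance: float) -> float:
    """Invert a fitted standard curve: conc = (absorbance - intercept) / slope."""
    if not curve.fitted:
        raise ValueError("standard curve has not been fitted")
    if curve.slope == 0:
        raise ZeroDivisionError("standard curve slope is zero; cannot interpolate")
    return (absorbance - curve.intercept) / curve.slope


def dpph_scavenging(a0: float, a1: float) -> float:
    """DPPH radical scavenging (%) = 100 * (A0 - A1) / A0.

    ``a0`` is the control-reaction absorbance, ``a1`` the sample absorbance.
    """
    if a0 <= 0:
        raise ZeroDivisionError("control absorbance A0 must be > 0")
    if a1 < 0:
        raise ValueError("sample absorbance must be >= 0")
    return 100.0 * (a0 - a1) / a0


def ic50(curve: ScavengingCurve) -> Optional[float]:
    """Extract concentration producing 50% DPPH scavenging.

    Linear interpolation between the two sampled points bracketing 50%; an
    exactly-sampled 50% is returned as-is.  Returns ``None`` when the curve
    never crosses 50% in the sampled range (never extrapolates).
    """
    pts = sorted(curve.points)
    if len(pts) < 2:
        raise ValueError("need >= 2 scavenging points")
    for conc, scav in pts:
        if scav == 50.0:
            return conc
    for (c_lo, s_lo), (c_hi, s_hi) in zip(pts, pts[1:]):
        if (s_lo - 50.0) * (s_hi - 50.0) < 0:
            return c_lo + (50.0 - s_lo) * (c_hi - c_lo) / (s_hi - s_lo)
    return None


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent change relative to control: 100*(control - treated)/control.

    Decreases under treatment are positive (matching how stress-induced
    reductions are tabulated); increases come out negative.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (control_mean - treated_mean) / control_mean


def ion_ratio(profile: IonProfile, numerator: str = "Na", denominator: str = "K") -> float:
    """Ratio of two cation concentrations, e.g. the Na+/K+ ratio."""
    try:
        num = profile.concentrations[numerator]
        den = profile.concentrations[denominator]
    except KeyError as exc:
        raise KeyError(f"ion {exc.args[0]!r} missing from profile") from exc
    if den == 0:
        raise ZeroDivisionError(f"{denominator} concentration is zero")
    return num / den
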