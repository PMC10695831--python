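"""Design and validation math for charge-asymmetric liposomes.

Asymmetric liposomes are made by methyl-β-cyclodextrin (MβCD)-mediated
exchange of donor lipid into the outer leaflet of acceptor vesicles.  This
module implements the exchange stoichiometry used to plan such preparations,
the readout that converts a measured total donor fraction into an
outer-leaflet fraction (valid for a single round of outside-only exchange),
the ±3% binning rule used to group preparations to the nearest 10%
asymmetry, and the theoretical ζ-potential "asymmetry line" against which a
measured ζ classifies a liposome as asymmetric or symmetric.

Units follow lab convention: lipid concentrations in mM, ζ-potentials in mV,
temperatures in °C.  The MβCD stoichiometry formula is dimensionally
irregular (K is quoted in M⁻³ yet enters linearly); it is evaluated exactly
as written in the caller's unit system and no conversion is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Union

import numpy as np

from .errors import DomainError, InconsistencyError

__all__ = [
    "LipidSpecies",
    "LeafletComposition",
    "LiposomeComposition",
    "ExchangePlan",
    "AsymmetryLine",
    "BUILTIN_SPECIES",
    "DONOR_K",
    "plan_exchange",
    "outer_leaflet_fraction",
    "bin_asymmetry",
    "classify_on_asymmetry_line",
]


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid (or sterol) with the properties the design math needs.

    headgroup_charge is the net elementary charge per headgroup at neutral
    pH (0 for PC/PE zwitterions, −1 for PG/PS).  tm_celsius is the gel–fluid
    transition temperature; cholesterol has no transition and carries NaN.
    """

    name: str
    headgroup_charge: int
    tm_celsius: float
    is_cholesterol: bool = False

    def __post_init__(self):
        if self.headgroup_charge not in (-1, 0, 1):
            raise DomainError(
                f"unsupported headgroup charge {self.headgroup_charge} for {self.name}"
            )
        if not self.is_cholesterol and not math.isfinite(self.tm_celsius):
            raise DomainError(f"non-finite Tm for non-cholesterol lipid {self.name}")


#: Species used throughout the study.  Tm values in °C.
BUILTIN_SPECIES: Dict[str, LipidSpecies] = {
    s.name: s
    for s in (
        LipidSpecies("DMPC", 0, 24.0),
        LipidSpecies("DMPG", -1, 23.0),
        LipidSpecies("DMPS", -1, 35.0),
        LipidSpecies("DMPE", 0, 50.0),
        LipidSpecies("POPC", 0, -2.0),
        LipidSpecies("POPG", -1, -2.0),
        LipidSpecies("cholesterol", 0, float("nan"), is_cholesterol=True),
    )
}

#: Donor-class constant K of the MβCD stoichiometry formula, by donor headgroup.
DONOR_K: Dict[str, float] = {"PC": 292.0, "PG": 292.0, "PS": 292.0, "PE": 150.0}


@dataclass(frozen=True)
class LeafletComposition:
    """Mole fractions of the species in one leaflet (mol/mol, summing to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        fr = dict(self.fractions)
        if any(v < 0 for v in fr.values()):
            raise DomainError("negative mole fraction")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"mole fractions sum to {total}, not 1")
        object.__setattr__(self, "fractions", fr)

    def fraction(self, species: str) -> float:
        return self.fractions.get(species, 0.0)


@dataclass(frozen=True)
class LiposomeComposition:
    """Inner/outer leaflet compositions plus the exchange-accessible fraction.

    accessible_fraction_a is the fraction of total lipid residing in the
    outer, exchange-accessible leaflet (~0.5 for large unilamellar vesicles).
    """

    inner: LeafletComposition
    outer: LeafletComposition
    accessible_fraction_a: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.accessible_fraction_a < 1.0:
            raise DomainError("accessible fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class ExchangePlan:
    """Concentrations for one MβCD-mediated exchange reaction.

    Cd = a·Ca·asym/(1−asym) gives the donor lipid needed to reach the target
    outer-leaflet asymmetry; Cm = n·Cd + (Cd·K)/n gives the MβCD
    concentration, with n the CD–lipid complex stoichiometry and K an
    empirically derived donor-class constant.  saturation records the
    intermediate CD–lipid saturation at which K was calibrated; it is
    metadata and does not enter the arithmetic.
    """

    Ca: float
    Cd: float
    Cm: float
    target_asym: float
    n_stoichiometry: int = 4
    K_value: float = 292.0
    saturation: float = 0.70


def plan_exchange(
    Ca: float,
    target_asym: float,
    a: float = 0.5,
    donor_K: Union[str, float] = 292.0,
    n: int = 4,
    saturation: float = 0.70,
) -> ExchangePlan:
    """Plan donor-lipid and MβCD concentrations for a target asymmetry.

    Parameters
    ----------
    Ca : acceptor lipid concentration (mM), > 0.
    target_asym : desired outer-leaflet donor fraction, in [0, 1).  A single
        round of outside-only exchange tops out around 0.5; values above
        0.55 trigger a warning.
    a : fraction of acceptor lipid accessible to exchange (outer leaflet).
    donor_K : the donor-class constant K, either a number or a headgroup key
        ("PC", "PG", "PS", "PE").
    n : CD–lipid complex stoichiometry.
    """
    if isinstance(donor_K, str):
        try:
            K = DONOR_K[donor_K.upper()]
        except KeyError:
            raise DomainError(f"unknown donor headgroup {donor_K!r}; known: {sorted(DONOR_K)}")
    else:
        K = float(donor_K)
    if Ca <= 0:
        raise DomainError("acceptor concentration Ca must be positive")
    if target_asym < 0 or not 0 < a < 1 or K < 0 or n < 1:
        raise DomainError("negative or out-of-range exchange parameter")
    if target_asym >= 1:
        raise DomainError("target asymmetry must be < 1")
    if target_asym > 0.55:
        warnings.warn(
            "single-round exchange rarely exceeds ~50% asymmetry; "
            f"target {target_asym} may be unreachable",
            stacklevel=2,
        )
    Cd = a * Ca * target_asym / (1.0 - target_asym)
    Cm = n * Cd + (Cd * K) / n
    return ExchangePlan(
        Ca=Ca,
        Cd=Cd,
        Cm=Cm,
        target_asym=target_asym,
        n_stoichiometry=n,
        K_value=K,
        saturation=saturation,
    )


def outer_leaflet_fraction(total_donor_fraction: float, a: float = 0.5) -> float:
    """Convert a measured total donor mole fraction to an outer-leaflet fraction.

    After a single round of outside-only exchange all donor lipid sits in the
    outer leaflet, so the outer-leaflet content is total/a.  A total fraction
    exceeding a would imply donor in the inner leaflet and is rejected.
    """
    if not 0 < a < 1:
        raise DomainError("accessible fraction must lie strictly in (0, 1)")
    if total_donor_fraction < 0:
        raise DomainError("donor fraction cannot be negative")
    if total_donor_fraction > a + 1e-12:
        raise InconsistencyError(
            f"total donor fraction {total_donor_fraction} exceeds accessible "
            f"fraction {a}: implies inner-leaflet donor"
        )
    return float(np.clip(total_donor_fraction / a, 0.0, 1.0))


def bin_asymmetry(
    measured_fraction: float, bin_width: float = 0.10, tolerance: float = 0.03
) -> Union[float, str]:
    """Group a measured asymmetry to the nearest 10% bin, within ±3%.

    Returns the bin centre (a multiple of bin_width) when the measurement
    lies within ``tolerance`` of it, else the string ``"excluded"``.
    """
    if not 0 <= measured_fraction <= 1:
        raise DomainError("measured fraction must lie in [0, 1]")
    centre = round(measured_fraction / bin_width) * bin_width
    if abs(measured_fraction - centre) <= tolerance + 1e-12:
        return round(centre, 10)
    return "excluded"


@dataclass
class AsymmetryLine:
    """Theoretical ζ line for asymmetric liposomes, from a symmetric calibration.

    sym_calibration is a table of (outer-lipid fraction, ζ mV) points for
    symmetric liposomes; it is interpolated piecewise-linearly and must be
    monotone.  For an asymmetric liposome with total donor fraction f all
    donor lipid is in the outer leaflet, so its predicted ζ is the symmetric
    calibration evaluated at f/a.  margin is the relative tolerance band on
    the predicted ζ magnitude (the figure-style 10% shading of the line).
    """

    fractions: Sequence[float]
    zeta_mv: Sequence[float]
    accessible_fraction_a: float = 0.5
    margin: float = 0.10

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        z = np.asarray(self.zeta_mv, dtype=float)
        if f.size != z.size or f.size < 2:
            raise DomainError("calibration needs >= 2 (fraction, zeta) pairs")
        order = np.argsort(f)
        f, z = f[order], z[order]
        dz = np.diff(z)
        if not (np.all(dz >= -1e-12) or np.all(dz <= 1e-12)):
            raise DomainError("calibration must be monotone in fraction")
        if self.margin < 0:
            raise DomainError("margin must be >= 0")
        self.fractions = f
        self.zeta_mv = z

    def __call__(self, fraction: float) -> float:
        f = self.fractions
        if fraction < f[0] - 1e-12 or fraction > f[-1] + 1e-12:
            raise DomainError(
                f"fraction {fraction} outside calibrated range [{f[0]}, {f[-1]}]"
            )
        return float(np.interp(fraction, f, self.zeta_mv))


def classify_on_asymmetry_line(
    line: AsymmetryLine, total_fraction: float, zeta_measured: float
) -> str:
    """Classify a liposome as "asymmetric", "symmetric" or "indeterminate".

    Both hypotheses are evaluated: a symmetric liposome of total donor
    fraction f sits at ζ_sym(f); a fully outside-exchanged one sits at
    ζ_sym(f/a).  The label whose prediction brackets the measurement within
    the relative ±margin band is returned; "indeterminate" when both or
    neither match (e.g. f = 0, where the predictions coincide).
    """
    a = line.accessible_fraction_a
    scaled = total_fraction / a
    if scaled > 1 + 1e-12:
        raise DomainError(
            f"total fraction {total_fraction} with accessible fraction {a} "
            "implies an outer-leaflet fraction > 1"
        )
    z_sym = line(total_fraction)
    z_asym = line(min(scaled, 1.0))

    def matches(pred: float) -> bool:
        return abs(zeta_measured - pred) <= line.margin * abs(pred)

    m_sym, m_asym = matches(z_sym), matches(z_asym)
    if m_sym and not m_asym:
        return "symmetric"
    if m_asym and not m_sym:
        return "asymmetric"
    return "indeterminate"
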