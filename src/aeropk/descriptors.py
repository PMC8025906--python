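"""Particle- and bulk-level powder descriptors for DPI carriers and blends.

Pure, deterministic functions: Kelvin radius from nitrogen-sorption relative
pressure, Heywood equivalent diameter and Wong-Pipel shape coefficient from
image measurements, diametral-compression tensile strength, powder-rheometer
summary statistics (mean and endpoint difference over an applied-stress
window) and laser-diffraction pressure-titration deltas.

Units are SI internally (m, kg, N, K); interfaces report the field's customary
units (um, N/mm^2, m^2/g) where noted.  The Kelvin relation is implemented in
its magnitude convention r_k = 2*sigma*V / (R*T*ln(p0/p)) so that radii are
positive for condensation (p < p0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, MissingLevelError

#: Universal gas constant, J/(mol K).
R_GAS = 8.314462618

#: Liquid-nitrogen constants at 77.35 K (surface tension N/m, molar volume m^3/mol).
N2_SURFACE_TENSION = 8.85e-3
N2_MOLAR_VOLUME = 34.7e-6
N2_BOILING_T = 77.35


@dataclass(frozen=True)
class KelvinInput:
    """Inputs of the Kelvin capillary-condensation relation."""

    p_rel: float  # relative pressure p/p0, in (0, 1)
    sigma: float = N2_SURFACE_TENSION
    Vm: float = N2_MOLAR_VOLUME
    T: float = N2_BOILING_T

    def __post_init__(self):
        if not (0.0 < self.p_rel < 1.0):
            raise InvalidInputError("p_rel must lie strictly in (0, 1)")
        if min(self.sigma, self.Vm, self.T) <= 0:
            raise InvalidInputError("sigma, Vm and T must be positive")


@dataclass(frozen=True)
class CompactRecord:
    """Diametral-compression test of one powder compact."""

    P: float  # crushing load, N
    D: float  # compact diameter, mm
    t: float  # compact thickness, mm

    def __post_init__(self):
        if self.P < 0:
            raise InvalidInputError("load must be nonnegative")
        if self.D <= 0 or self.t <= 0:
            raise InvalidInputError("diameter and thickness must be positive")


@dataclass(frozen=True)
class RheologyProfile:
    """One FT4-style response profile over applied normal stresses.

    ``quantity`` is SSi (incipient shear stress, kPa), CPS (change in volume
    after compression, %) or PD (pressure drop across the bed).
    """

    quantity: str
    levels: tuple  # applied normal stresses, kPa, strictly increasing
    values: tuple

    def __post_init__(self):
        if self.quantity not in ("SSi", "CPS", "PD"):
            raise InvalidInputError(f"unknown rheology quantity {self.quantity!r}")
        lv = np.asarray(self.levels, dtype=float)
        if len(lv) != len(self.values):
            raise InvalidInputError("levels and values must have equal length")
        if len(lv) and np.any(np.diff(lv) <= 0):
            raise InvalidInputError("levels must be strictly increasing")


@dataclass(frozen=True)
class TitrationSeries:
    """Laser-diffraction pressure titration of a powder or blend."""

    pdp: tuple  # primary dispersion pressures, bar, strictly increasing
    dv01: tuple  # Dv0.1, um
    fines: tuple  # fraction < 10 um, %

    def __post_init__(self):
        p = np.asarray(self.pdp, dtype=float)
        if len(p) != len(self.dv01) or len(p) != len(self.fines):
            raise InvalidInputError("pdp, dv01 and fines must have equal length")
        if len(p) and np.any(np.diff(p) <= 0):
            raise InvalidInputError("pdp must be strictly increasing")


def kelvin_radius(inp: KelvinInput) -> float:
    """Kelvin radius r_k (m) of the meniscus condensing at relative pressure p/p0.

    The pore radius follows by adding the adsorbed-layer thickness, which the
    caller supplies (the instrument's full BJH reduction is not reproduced).
    """
    ln_inv = math.log(1.0 / inp.p_rel)
    return 2.0 * inp.sigma * inp.Vm / (R_GAS * inp.T * ln_inv)


def heywood_diameter(W: float, L: float) -> float:
    """Heywood equivalent diameter de = sqrt(3.08*W*L/pi) (same units as W, L)."""
    if W <= 0 or L <= 0:
        raise InvalidInputError("width and length must be positive")
    return math.sqrt(3.08 * W * L / math.pi)


def shape_coefficient(
    SSA: float, rho_s: float, de: float, N: float, *, variant: str = "additive"
) -> float:
    """Wong-Pipel shape coefficient alpha = SSA*rho_s*de + N.

    SSA in m^2/kg, rho_s in kg/m^3, de in m; N = L/W is the mean elongation
    ratio.  ``variant="multiplicative"`` computes SSA*rho_s*de*N instead (an
    alternative reading of the source formula, off by default).
    """
    if min(SSA, rho_s, de) <= 0 or N < 1:
        raise InvalidInputError("SSA, rho_s, de must be positive and N >= 1")
    term = SSA * rho_s * de
    if variant == "additive":
        return term + N
    if variant == "multiplicative":
        return term * N
    raise InvalidInputError(f"unknown variant {variant!r}")


def tensile_strength(c: CompactRecord) -> float:
    """Diametral-compression tensile strength TS = 2P/(pi*D*t) in N/mm^2."""
    return 2.0 * c.P / (math.pi * c.D * c.t)


def rheology_summary(p: RheologyProfile, lo: float, hi: float) -> tuple:
    """(sigma_mean, delta_abs) over the applied-stress window [lo, hi] kPa.

    sigma_mean is the arithmetic mean of values at levels inside the window;
    delta_abs is |value(hi) - value(lo)|.  Both endpoint levels must have been
    measured.
    """
    levels = np.asarray(p.levels, dtype=float)
    values = np.asarray(p.values, dtype=float)
    for endpoint in (lo, hi):
        if not np.any(np.isclose(levels, endpoint)):
            raise MissingLevelError(f"level {endpoint} kPa not measured")
    inside = (levels >= lo - 1e-12) & (levels <= hi + 1e-12)
    sigma_mean = float(values[inside].mean())
    v_lo = float(values[np.isclose(levels, lo)][0])
    v_hi = float(values[np.isclose(levels, hi)][0])
    return sigma_mean, abs(v_hi - v_lo)


def titration_deltas(t: TitrationSeries, to_pdp: float) -> tuple:
    """(delta_dv01, delta_fines) from the lowest measured pressure to ``to_pdp``.

    Signed so that de-agglomeration is positive: Dv0.1 falls and the fines
    fraction rises as agglomerates break up.
    """
    pdp = np.asarray(t.pdp, dtype=float)
    if not np.any(np.isclose(pdp, to_pdp)):
        raise MissingLevelError(f"PDP {to_pdp} bar not measured")
    i = int(np.argmax(np.isclose(pdp, to_pdp)))
    delta_dv01 = float(t.dv01[0] - t.dv01[i])
    delta_fines = float(t.fines[i] - t.fines[0])
    return delta_dv01, delta_fines


#: Canonical descriptor column names consumed by the correlation module.
DESCRIPTOR_COLUMNS = (
    "Dv0.5",
    "FinesPct",
    "SSA",
    "PoreV",
    "PoreS",
    "Alpha",
    "TS",
    "Coh",
    "FF",
    "sSSi",
    "dSSi",
    "sCPS",
    "dCPS",
    "sPD",
    "dPD",
    "dDv01_0.5",
    "dDv01_1.5",
    "dFines0.3",
    "dFines0.5",
)
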