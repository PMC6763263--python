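"""Physical constants and free-energy / coupling-factor algebra.

Unit conventions used throughout the package: voltages in mV, time in ms
(rates in ms^-1), Ca2+ concentrations in uM, energies in kJ/mol, gating
charges dimensionless (units of e0).  Conversions happen inside functions;
every public interface speaks these units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from bkgating.errors import InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from bkgating.qv import BoltzmannParams

#: Faraday constant, C/mol.
FARADAY = 96485.0
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314
#: Default absolute temperature, K (room temperature recordings).
DEFAULT_TEMPERATURE = 295.0


def thermal_voltage_mv(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT/F in millivolts (~25.4 mV at 295 K)."""
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature / FARADAY * 1000.0


@dataclass(frozen=True)
class EnergyResult:
    """Energetic summary of a ligand-induced shift of the voltage-sensor
    resting/active (R-A) equilibrium.

    Attributes
    ----------
    delta_vh : float
        Shift of the Q-V half-activation voltage, mV (negative = leftward).
    ddg_vca : float
        Change in Gibbs free energy of the R-A equilibrium, kJ/mol.
    coupling_E : float
        Dimensionless allosteric factor E = exp(-ddG/RT) by which the
        R-A equilibrium constant J is amplified at ligand saturation.
    """

    delta_vh: float
    ddg_vca: float
    coupling_E: float


def delta_g_vca(
    params_zero: "BoltzmannParams",
    params_ca: "BoltzmannParams",
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Ca2+-induced Gibbs free-energy change of the R-A equilibrium, kJ/mol.

    Computed from Boltzmann fits of the fast gating charge at two Ca2+
    conditions as ``F * (zQ_ca * VH_ca - zQ_0 * VH_0)`` with VH converted to
    volts.  Negative when Ca2+ left-shifts the Q-V curve (activation becomes
    energetically cheaper).

    Parameters
    ----------
    params_zero, params_ca : BoltzmannParams
        Fits at the reference (nominally zero Ca2+) and test conditions.
    temperature : float
        Kept for signature symmetry with the rest of the module; the
        energy difference itself is temperature-free.
    """
    if params_zero.zq <= 0 or params_ca.zq <= 0:
        raise InvalidParameterError(
            f"zq must be positive (got {params_zero.zq}, {params_ca.zq})"
        )
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    # mV -> V, J/mol -> kJ/mol
    return FARADAY * (params_ca.zq * params_ca.vh - params_zero.zq * params_zero.vh) / 1e6


def coupling_factor(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Allosteric factor E = exp(-ddG/RT) from an energy in kJ/mol.

    E > 1 whenever the ligand stabilizes the active voltage-sensor state
    (ddg < 0); E = 1 at ddg = 0.
    """
    if not math.isfinite(ddg):
        raise InvalidParameterError(f"ddg must be finite, got {ddg}")
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    return math.exp(-ddg * 1000.0 / (GAS_CONSTANT * temperature))


def energy_from_factor(E: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`coupling_factor`: ddG = -RT ln(E), kJ/mol."""
    if E <= 0:
        raise InvalidParameterError(f"E must be positive, got {E}")
    return -GAS_CONSTANT * temperature * math.log(E) / 1000.0


def per_event_factor(E: float, n_subunits: int = 4) -> float:
    """Per-binding-event factor for a concerted coupling scheme.

    When each bound Ca2+ multiplies the R-A equilibrium constant of all
    ``n_subunits`` voltage sensors equally, full occupancy amplifies J by the
    per-event factor raised to ``n_subunits``; the per-event factor is
    therefore the n-th root of the saturating factor E (e.g. 26.4**0.25 =
    2.27 for the tetramer).
    """
    if E <= 0:
        raise InvalidParameterError(f"E must be positive, got {E}")
    if n_subunits < 1:
        raise InvalidParameterError(f"n_subunits must be >= 1, got {n_subunits}")
    return E ** (1.0 / n_subunits)


def energetics_summary(
    params_zero: "BoltzmannParams",
    params_ca: "BoltzmannParams",
    temperature: float = DEFAULT_TEMPERATURE,
    n_subunits: int = 4,
) -> EnergyResult:
    """Bundle delta-VH, ddG and the coupling factor for a pair of fits."""
    ddg = delta_g_vca(params_zero, params_ca, temperature)
    return EnergyResult(
        delta_vh=params_ca.vh - params_zero.vh,
        ddg_vca=ddg,
        coupling_E=coupling_factor(ddg, temperature),
    )
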