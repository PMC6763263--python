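"""Two-state voltage-sensor kinetics: rate laws and tau(V) fitting.

The voltage-sensing domain is modelled as a single resting/active (R-A)
transition with Eyring-type voltage-dependent rates

    alpha(V) = alpha0 * exp( zJ * delta * F V / RT)
    beta(V)  = beta0  * exp( zJ * (delta - 1) * F V / RT)

where delta is the electrical distance of the transition-state barrier and
zJ the gating charge per sensor.  The gating-current relaxation time constant
is tau(V) = 1 / (alpha + beta), bell-shaped in voltage, and the equilibrium
constant is J(V) = alpha/beta = (alpha0/beta0) exp(zJ F V / RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from bkgating.errors import FitFailureError, InvalidParameterError
from bkgating.thermo import DEFAULT_TEMPERATURE, thermal_voltage_mv

__all__ = [
    "TwoStateRates",
    "TauCurve",
    "rates_at",
    "tau_two_state",
    "equilibrium_J",
    "fit_tau_curve",
    "read_tau_csv",
    "write_tau_csv",
]


@dataclass
class TwoStateRates:
    """Rate parameters of the two-state voltage-sensor model.

    alpha0, beta0 : forward / backward rates at 0 mV, ms^-1.
    delta : electrical distance of the barrier, in (0, 1).
    zj : gating charge per voltage sensor, e0.
    """

    alpha0: float
    beta0: float
    delta: float
    zj: float

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise InvalidParameterError(
                f"rates must be positive (alpha0={self.alpha0}, beta0={self.beta0})"
            )
        if not (0.0 < self.delta < 1.0):
            raise InvalidParameterError(f"delta must be in (0, 1), got {self.delta}")
        if self.zj <= 0:
            raise InvalidParameterError(f"zj must be positive, got {self.zj}")


@dataclass
class TauCurve:
    """Gating-current time constants versus voltage.

    v : voltages, mV.  tau : time constants, us.  sem : optional.
    """

    v: np.ndarray
    tau: np.ndarray
    sem: np.ndarray | None = None
    ca: float = np.nan

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.v.shape != self.tau.shape:
            raise InvalidParameterError("v and tau must have the same shape")
        if np.any(self.tau <= 0):
            raise InvalidParameterError("tau values must be positive")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)


def rates_at(
    v: np.ndarray | float,
    r: TwoStateRates,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Forward and backward rates (ms^-1) at voltage(s) ``v`` (mV)."""
    vt = thermal_voltage_mv(temperature)
    x = np.asarray(v, dtype=float)
    alpha = r.alpha0 * np.exp(r.zj * r.delta * x / vt)
    beta = r.beta0 * np.exp(r.zj * (r.delta - 1.0) * x / vt)
    if np.isscalar(v):
        return float(alpha), float(beta)
    return alpha, beta


def tau_two_state(
    v: np.ndarray | float,
    r: TwoStateRates,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Relaxation time constant tau(V) = 1/(alpha + beta), in microseconds."""
    alpha, beta = rates_at(v, r, temperature)
    tau_ms = 1.0 / (np.asarray(alpha) + np.asarray(beta))
    out = tau_ms * 1000.0
    return float(out) if np.isscalar(v) else out


def equilibrium_J(
    v: np.ndarray | float,
    r: TwoStateRates,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Voltage-sensor equilibrium constant J(V) = alpha/beta."""
    vt = thermal_voltage_mv(temperature)
    x = np.asarray(v, dtype=float)
    out = (r.alpha0 / r.beta0) * np.exp(r.zj * x / vt)
    return float(out) if np.isscalar(v) else out


def fit_tau_curve(
    data: TauCurve,
    zj_fixed: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> TwoStateRates:
    """Fit (alpha0, beta0, delta) to tau(V) data with zJ held fixed.

    zJ is constrained to the valence found from the Q-V Boltzmann fit, as the
    time constants alone do not determine it well.  The fit runs in log-rate
    space from a few spread-out starts and keeps the best residual.

    Raises
    ------
    FitFailureError if no start converges to a sane optimum.
    InvalidParameterError for fewer than 5 voltages.
    """
    if data.v.size < 5:
        raise InvalidParameterError(f"need >= 5 voltages, got {data.v.size}")
    if zj_fixed <= 0:
        raise InvalidParameterError(f"zj_fixed must be positive, got {zj_fixed}")
    vt = thermal_voltage_mv(temperature)
    v, tau_us = data.v, data.tau

    def resid(theta):
        la, lb, delta = theta
        alpha = np.exp(la + zj_fixed * delta * v / vt)
        beta = np.exp(lb + zj_fixed * (delta - 1.0) * v / vt)
        model_us = 1000.0 / (alpha + beta)
        # relative residuals: tau spans orders of magnitude over the grid
        return np.log(model_us) - np.log(tau_us)

    # crude scale guess: tau max ~ 1/(2 sqrt(a0 b0)) near its peak
    rate_scale = 1000.0 / float(np.max(tau_us))  # ms^-1
    best = None
    for delta0 in (0.2, 0.4, 0.6, 0.8):
        for ratio in (0.1, 1.0, 10.0):
            x0 = [np.log(rate_scale * ratio), np.log(rate_scale / ratio), delta0]
            try:
                sol = least_squares(
                    resid, x0,
                    bounds=([-20, -20, 1e-3], [20, 20, 1 - 1e-3]),
                    max_nfev=5000,
                )
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("tau(V) fit did not converge", {"zj": zj_fixed})
    la, lb, delta = best.x
    return TwoStateRates(
        alpha0=float(np.exp(la)), beta0=float(np.exp(lb)),
        delta=float(delta), zj=zj_fixed,
    )


# ---------------------------------------------------------------------------
# CSV I/O

def write_tau_csv(data: TauCurve, path) -> None:
    """Write a tau(V) table (columns v_mV, tau_us, sem, ca_uM)."""
    sem = data.sem if data.sem is not None else np.full_like(data.v, np.nan)
    pd.DataFrame(
        {"v_mV": data.v, "tau_us": data.tau, "sem": sem, "ca_uM": data.ca}
    ).to_csv(path, index=False)


def read_tau_csv(path) -> TauCurve:
    """Read a tau(V) table written by :func:`write_tau_csv`."""
    df = pd.read_csv(path).sort_values("v_mV")
    sem = df["sem"].to_numpy() if "sem" in df and df["sem"].notna().all() else None
    ca = float(df["ca_uM"].iloc[0]) if "ca_uM" in df else np.nan
    return TauCurve(v=df["v_mV"].to_numpy(), tau=df["tau_us"].to_numpy(),
                    sem=sem, ca=ca)
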