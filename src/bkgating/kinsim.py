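"""Master-equation simulation of coupled Ca2+ binding and VSD activation.

The equilibrium Q-V models assume occupancy is frozen during the ~100 us
charge measurement.  This module tests that assumption by simulating a
single subunit as a four-state continuous-time Markov chain

    R.unbound  <->  A.unbound        (alpha, beta)
       ^               ^
       |               |             (kon*ca, koff ; koff/E on the A side)
       v               v
    R.bound    <->  A.bound          (alpha, beta/E)

The bound voltage sensor equilibrates with J*E; by default the whole factor
is allocated to the backward rate (beta/E), matching the kinetic observation
that Ca2+ mainly slows the sensor's return.  Microscopic reversibility then
forces the active-state site to bind more tightly: the A-side dissociation
rate is koff/E regardless of the allocation.  Because Scheme I subunits are
independent, channel-level gating charge follows from this single-subunit
chain; an ensemble gating current is proportional to zj * d<P(A)>/dt.

Scanning the Ca2+ on-rate through the measurement pipeline shows how fast
re-equilibration would have to be before a same-subunit mechanism could
masquerade as a concerted one (single Boltzmann with full valence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from bkgating.errors import InvalidParameterError
from bkgating.kinetics import TwoStateRates, rates_at
from bkgating.qv import QVCurve, fit_boltzmann
from bkgating.signals import GatingTrace, charge_from_fit, fit_fast_exponential
from bkgating.thermo import DEFAULT_TEMPERATURE

__all__ = [
    "STATES",
    "KineticParams",
    "SubunitGenerator",
    "build_generator",
    "stationary_distribution",
    "simulate_gating_current",
    "apparent_zq_scan",
]

#: State order of the subunit chain.
STATES = ("R.unbound", "A.unbound", "R.bound", "A.bound")

#: Reported Ca2+ association rate constant for BK, M^-1 s^-1.
DEFAULT_KON = 1.8e8


@dataclass
class KineticParams:
    """Kinetic parameters of the coupled binding / voltage-sensing subunit.

    rates : unliganded two-state VSD rates.
    coupling_E : per-subunit allosteric factor (bound-state J -> J*E).
    kon : Ca2+ association rate constant, M^-1 s^-1.
    kd : dissociation constant of the resting-state site, uM
        (koff = kon * kd; the active-state site binds E-fold tighter).
    beta_allocation : fraction of E applied to the backward rate in the
        bound state (1.0 = all of it, the default; the remainder speeds the
        forward rate so that J*E is preserved).
    """

    rates: TwoStateRates
    coupling_E: float
    kon: float = DEFAULT_KON
    kd: float = 11.0
    beta_allocation: float = 1.0

    def __post_init__(self) -> None:
        if self.coupling_E <= 0:
            raise InvalidParameterError(f"coupling_E must be > 0, got {self.coupling_E}")
        if self.kon <= 0 or self.kd <= 0:
            raise InvalidParameterError(
                f"kon and kd must be > 0, got ({self.kon}, {self.kd})"
            )
        if not (0.0 <= self.beta_allocation <= 1.0):
            raise InvalidParameterError(
                f"beta_allocation must be in [0, 1], got {self.beta_allocation}"
            )

    @property
    def koff_ms(self) -> float:
        """Resting-state dissociation rate, ms^-1."""
        # kon [M^-1 s^-1] * kd [uM -> M] -> s^-1 -> ms^-1
        return self.kon * self.kd * 1e-6 * 1e-3


@dataclass
class SubunitGenerator:
    """Transition-rate matrix of the subunit chain at fixed (V, Ca).

    Q : 4x4 generator over STATES, rates in ms^-1; rows sum to zero.
    """

    Q: np.ndarray
    v: float
    ca: float
    zj: float


def build_generator(
    v: float,
    ca: float,
    kp: KineticParams,
    temperature: float = DEFAULT_TEMPERATURE,
) -> SubunitGenerator:
    """Assemble the 4-state generator at one voltage and Ca2+ concentration.

    The stationary distribution equals the equilibrium weights
    {1, J, ca/KD, (ca/KD) J E} (normalized); an internal check asserts the
    thermodynamic cycle closes to machine precision.
    """
    if ca < 0:
        raise InvalidParameterError(f"ca must be >= 0, got {ca}")
    E = kp.coupling_E
    f = kp.beta_allocation
    alpha_u, beta_u = rates_at(v, kp.rates, temperature)
    alpha_b = alpha_u * E ** (1.0 - f)
    beta_b = beta_u / E**f
    kon_ms = kp.kon * ca * 1e-6 * 1e-3  # ms^-1
    koff_r = kp.koff_ms
    koff_a = kp.koff_ms / E  # tighter binding to the active sensor

    Q = np.zeros((4, 4))
    # 0 R.u, 1 A.u, 2 R.b, 3 A.b
    Q[0, 1], Q[1, 0] = alpha_u, beta_u
    Q[2, 3], Q[3, 2] = alpha_b, beta_b
    Q[0, 2], Q[2, 0] = kon_ms, koff_r
    Q[1, 3], Q[3, 1] = kon_ms, koff_a
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    # detailed-balance check on the loop (only meaningful with binding flux)
    if ca > 0:
        fwd = Q[0, 1] * Q[1, 3] * Q[3, 2] * Q[2, 0]
        rev = Q[0, 2] * Q[2, 3] * Q[3, 1] * Q[1, 0]
        if not np.isclose(fwd, rev, rtol=1e-10):
            raise AssertionError(
                f"thermodynamic cycle violates detailed balance: {fwd} vs {rev}"
            )
    return SubunitGenerator(Q=Q, v=v, ca=ca, zj=kp.rates.zj)


def stationary_distribution(gen: SubunitGenerator) -> np.ndarray:
    """Stationary distribution of the chain (equilibrium weights)."""
    w, vecs = np.linalg.eig(gen.Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_gating_current(
    gen: SubunitGenerator,
    t_grid: np.ndarray,
    init: np.ndarray,
) -> GatingTrace:
    """Propagate the master equation and return the ensemble gating current.

    The current is zj * d<P(A)>/dt evaluated exactly from the generator
    (I(t) = zj * (p(t) Q) . mask_A), in charge-per-us units on the t_grid
    (us).  The initial condition is normally the stationary distribution at
    the holding potential and the test Ca2+.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    init = np.asarray(init, dtype=float)
    if not np.isclose(init.sum(), 1.0, atol=1e-9):
        raise InvalidParameterError("init must be a normalized distribution")
    dt_us = np.diff(t_grid)
    if np.any(dt_us <= 0) or not np.allclose(dt_us, dt_us[0], rtol=1e-9):
        raise InvalidParameterError("t_grid must be uniform and increasing")

    # one-step propagator on the uniform grid (rates are per ms)
    P_step = expm(gen.Q * (dt_us[0] / 1000.0))
    mask_A = np.array([0.0, 1.0, 0.0, 1.0])
    p = init.copy()
    current = np.empty_like(t_grid)
    for k in range(t_grid.size):
        if k > 0:
            p = p @ P_step
        # dP(A)/dt in ms^-1 -> per us
        current[k] = gen.zj * float((p @ gen.Q) @ mask_A) / 1000.0
    return GatingTrace(t=t_grid, i=current, v_step=gen.v, ca=gen.ca)


def apparent_zq_scan(
    kp: KineticParams,
    kon_multipliers: np.ndarray,
    ca: float,
    v_grid: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    holding_mv: float = -90.0,
    pulse_ms: float = 1.0,
    fs: float = 500_000.0,
    window_end: float = 100.0,
) -> pd.DataFrame:
    """Apparent (zQ, VH) versus Ca2+ binding speed.

    For each kon multiplier (koff scaled identically, preserving KD), gating
    currents are simulated over ``v_grid`` from the holding-potential
    equilibrium, pushed through the standard measurement pipeline
    (single-exponential fit over the first ``window_end`` us, QC = A*tau,
    free-scale Boltzmann fit), and reduced to apparent (zQ, VH).

    Returns a DataFrame with columns kon_multiplier, ca_uM, zq_app,
    vh_app_mV.
    """
    from dataclasses import replace as _replace

    v_grid = np.asarray(v_grid, dtype=float)
    n_samp = int(round(pulse_ms * 1e-3 * fs))
    t_grid = np.arange(n_samp) / fs * 1e6  # us

    rows = []
    for mult in np.asarray(kon_multipliers, dtype=float):
        if mult <= 0:
            raise InvalidParameterError(f"multipliers must be > 0, got {mult}")
        kp_m = _replace(kp, kon=kp.kon * mult)
        qc, taus, vs = [], [], []
        for v in v_grid:
            gen = build_generator(v, ca, kp_m, temperature)
            init = stationary_distribution(
                build_generator(holding_mv, ca, kp_m, temperature)
            )
            trace = simulate_gating_current(gen, t_grid, init)
            try:
                f = fit_fast_exponential(trace, window_end=window_end,
                                         skip_samples=0)
            except Exception:
                continue
            qc.append(charge_from_fit(f))
            taus.append(f.tau)
            vs.append(v)
        if len(qc) < 5:
            raise InvalidParameterError(
                f"too few usable voltages at multiplier {mult}"
            )
        qc = np.asarray(qc)
        curve = QVCurve(v=np.asarray(vs), q=qc / qc.max(), ca=ca)
        bfit = fit_boltzmann(curve, temperature=temperature)
        rows.append(
            {"kon_multiplier": mult, "ca_uM": ca,
             "zq_app": bfit.zq, "vh_app_mV": bfit.vh}
        )
    return pd.DataFrame(rows)
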