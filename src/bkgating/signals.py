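"""Gating-current transients: exponential fitting and charge integration.

The fast component of the ON-gating current decays as a single exponential
A exp(-t/tau) over the first 50-100 us of a depolarizing step.  The fast
gating charge QC displaced among closed states is the area under that fitted
exponential taken analytically over [0, inf), i.e. QC = A * tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from bkgating.errors import FitFailureError, InvalidParameterError
from bkgating.kinetics import TauCurve
from bkgating.qv import QVCurve, fit_boltzmann
from bkgating.thermo import DEFAULT_TEMPERATURE

__all__ = [
    "GatingTrace",
    "ExpFit",
    "ExtractionResult",
    "fit_fast_exponential",
    "charge_from_fit",
    "extract_qv",
    "read_trace_csv",
    "write_trace_csv",
]

#: Plausible range for the fast gating-current time constant, us.
TAU_BOUNDS_US = (1.0, 10_000.0)


@dataclass
class GatingTrace:
    """A sampled gating-current transient for one voltage step.

    t : sample times, us, uniform grid starting at the step onset.
    i : current samples (any consistent unit, e.g. nA).
    v_step : step potential, mV.
    ca : internal Ca2+, uM.
    fs : sampling rate, Hz.
    """

    t: np.ndarray
    i: np.ndarray
    v_step: float
    ca: float
    fs: float = 500_000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape:
            raise InvalidParameterError("t and i must have the same shape")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InvalidParameterError("t must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidParameterError("t must be a uniform grid")


@dataclass
class ExpFit:
    """Single-exponential fit A exp(-t/tau) of the fast ON-gating decay.

    amplitude : fitted peak current (trace units).
    tau : decay time constant, us.
    window : (t_start, t_end) of the fit, us.
    rss : residual sum of squares within the window.
    """

    amplitude: float
    tau: float
    window: tuple[float, float]
    rss: float


def fit_fast_exponential(
    trace: GatingTrace,
    window_end: float = 100.0,
    skip_samples: int = 2,
) -> ExpFit:
    """Fit A exp(-t/tau) to the initial decay of an ON-gating current.

    Parameters
    ----------
    trace : GatingTrace starting at the step onset.
    window_end : end of the fit window, us (the experimental convention is
        50-100 us; default 100).
    skip_samples : initial samples excluded from the fit (amplifier
        settling); default 2.

    Returns
    -------
    ExpFit with the amplitude extrapolated back to t = 0.

    Raises
    ------
    FitFailureError
        When the decay cannot be resolved: too few samples, non-convergence,
        tau outside (1 us, 10 ms), or a fit that explains almost none of the
        signal variance (pure-noise trace).
    """
    mask = trace.t <= window_end
    t = trace.t[mask][skip_samples:]
    i = trace.i[mask][skip_samples:]
    if t.size < 25:
        raise FitFailureError(
            f"only {t.size} samples in fit window [0, {window_end}] us "
            "(need >= 25)",
            {"window_end": window_end, "n": int(t.size)},
        )

    # log-linear initialization on the positive part of the decay
    pos = i > 0
    if pos.sum() >= 5:
        coef = np.polyfit(t[pos], np.log(i[pos]), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else 50.0
        a0 = float(np.exp(coef[1]))
    else:
        tau0, a0 = 50.0, float(np.max(np.abs(i)) or 1.0)
    tau0 = float(np.clip(tau0, *TAU_BOUNDS_US))
    a0 = max(a0, 1e-12)

    model = lambda tt, a, tau: a * np.exp(-tt / tau)
    try:
        popt, _ = curve_fit(
            model, t, i, p0=[a0, tau0],
            bounds=([0.0, TAU_BOUNDS_US[0]], [np.inf, TAU_BOUNDS_US[1]]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "exponential fit did not converge",
            {"p0": [a0, tau0], "v_step": trace.v_step, "error": str(exc)},
        ) from exc

    a_fit, tau_fit = float(popt[0]), float(popt[1])
    pred = model(t, a_fit, tau_fit)
    rss = float(np.sum((i - pred) ** 2))
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    edge = 1e-6 * (TAU_BOUNDS_US[1] - TAU_BOUNDS_US[0])
    at_bound = (
        tau_fit <= TAU_BOUNDS_US[0] + edge or tau_fit >= TAU_BOUNDS_US[1] - edge
    )
    if r2 < 0.2 or at_bound or a_fit <= 0:
        raise FitFailureError(
            "exponential fit rejected: no resolvable decay",
            {"amplitude": a_fit, "tau": tau_fit, "r2": r2,
             "v_step": trace.v_step},
        )
    return ExpFit(
        amplitude=a_fit, tau=tau_fit,
        window=(float(t[0]), float(window_end)), rss=rss,
    )


def charge_from_fit(fit: ExpFit) -> float:
    """Fast gating charge QC = A * tau, the analytic area of the fitted
    exponential over [0, inf).  Units: current unit x us (nA*us = fC)."""
    return fit.amplitude * fit.tau


@dataclass
class ExtractionResult:
    """Output of the per-Ca extraction pipeline.

    qv : normalized QC(V) curve (divided by the fitted Boltzmann maximum).
    tau : per-voltage fast time constants, for the kinetics stage.
    qc_raw : un-normalized charges, same order as ``qv.v``.
    boltzmann : the normalization fit (qmax free).
    """

    qv: QVCurve
    tau: TauCurve
    qc_raw: np.ndarray
    boltzmann: "object"


def extract_qv(
    traces: Sequence[GatingTrace],
    window_end: float = 100.0,
    skip_samples: int = 2,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ExtractionResult:
    """Batch-fit a voltage family of traces at one Ca2+ and build its Q-V.

    Each trace is fitted with :func:`fit_fast_exponential`; QC = A*tau per
    voltage; the QC(V) family is normalized by the maximum of a free-scale
    Boltzmann fit (not by the largest observed point, which would inherit its
    noise).  Traces whose exponential fit fails are dropped with a warning.
    """
    if len(traces) < 5 or len({tr.v_step for tr in traces}) < 5:
        raise InvalidParameterError(
            f"need >= 5 distinct voltages, got {len({tr.v_step for tr in traces})}"
        )
    cas = {tr.ca for tr in traces}
    if len(cas) != 1:
        raise InvalidParameterError(f"traces span several Ca conditions: {sorted(cas)}")
    ca = cas.pop()

    rows = []
    for tr in sorted(traces, key=lambda x: x.v_step):
        try:
            f = fit_fast_exponential(tr, window_end=window_end,
                                     skip_samples=skip_samples)
        except FitFailureError as exc:
            warnings.warn(
                f"dropping trace at {tr.v_step:+.0f} mV (ca={ca} uM): {exc}",
                stacklevel=2,
            )
            continue
        rows.append((tr.v_step, charge_from_fit(f), f.tau))
    if len(rows) < 5:
        raise FitFailureError(
            f"only {len(rows)} voltages survived exponential fitting",
            {"ca": ca},
        )

    v = np.array([r[0] for r in rows])
    qc = np.array([r[1] for r in rows])
    tau = np.array([r[2] for r in rows])

    raw_curve = QVCurve(v=v, q=qc / qc.max(), ca=ca)
    bfit = fit_boltzmann(raw_curve, temperature=temperature)
    scale = qc.max() * bfit.qmax
    return ExtractionResult(
        qv=QVCurve(v=v, q=qc / scale, ca=ca),
        tau=TauCurve(v=v, tau=tau, ca=ca),
        qc_raw=qc,
        boltzmann=bfit,
    )


# ---------------------------------------------------------------------------
# CSV I/O (long format: time_us, current, v_mV, ca_uM)

def write_trace_csv(traces: Sequence[GatingTrace], path) -> None:
    """Write traces to a long-format CSV (time_us, current, v_mV, ca_uM)."""
    frames = [
        pd.DataFrame(
            {"time_us": tr.t, "current": tr.i, "v_mV": tr.v_step, "ca_uM": tr.ca}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path, fs: float = 500_000.0) -> list[GatingTrace]:
    """Read traces from the long-format CSV written by
    :func:`write_trace_csv`."""
    df = pd.read_csv(path)
    missing = {"time_us", "current", "v_mV", "ca_uM"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for (v, ca), grp in df.groupby(["v_mV", "ca_uM"], sort=True):
        grp = grp.sort_values("time_us")
        out.append(
            GatingTrace(t=grp["time_us"].to_numpy(), i=grp["current"].to_numpy(),
                        v_step=float(v), ca=float(ca), fs=fs)
        )
    return out
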