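"""Synthetic datasets emulating the gating-current experimental design.

The generator mirrors the recording protocol: 1-ms voltage steps from -90 to
+350 mV in 10-mV increments sampled at 500 kHz, internal Ca2+ spanning
nominally-zero (~0.8 nM, the contaminant level under strong chelation)
through saturating 100 uM.  Q-V datasets are drawn from a chosen allosteric
model with per-point Gaussian noise and a per-patch voltage-axis jitter that
exercises the alignment procedure; gating traces are exponential ON-current
decays with additive Gaussian noise; tau(V) datasets carry multiplicative
lognormal noise.

All randomness flows through one explicitly passed, seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from bkgating.camodels import AllostericModelSpec, qc_curve
from bkgating.errors import InvalidParameterError
from bkgating.kinetics import TauCurve, TwoStateRates, tau_two_state
from bkgating.qv import QVCurve
from bkgating.signals import GatingTrace
from bkgating.thermo import DEFAULT_TEMPERATURE

__all__ = [
    "ProtocolSpec",
    "generate_qv_dataset",
    "generate_gating_trace",
    "generate_trace_family",
    "generate_tau_dataset",
    "write_ground_truth",
]

#: Nominal 'zero Ca2+' of a strongly chelated internal solution, uM.
ZERO_CA_UM = 0.0008

#: Internal Ca2+ conditions of the dose-response design, uM.
DEFAULT_CA_SET = (ZERO_CA_UM, 0.1, 0.5, 1.0, 5.0, 10.0, 100.0)


@dataclass
class ProtocolSpec:
    """Recording protocol and noise model for synthetic data.

    v_grid : step potentials, mV (default -90..350 in 10-mV increments).
    pulse_ms : step duration, ms.
    fs : sampling rate, Hz.
    ca_set : internal Ca2+ conditions, uM.
    n_patches : replicates per condition.
    sigma_q : per-point Gaussian SD of normalized charge.
    sigma_trace : additive current noise SD (trace units).
    sigma_vh : per-patch voltage-axis jitter SD, mV.
    seed : base seed for the dataset-level generator.
    """

    v_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-90.0, 351.0, 10.0)
    )
    pulse_ms: float = 1.0
    fs: float = 500_000.0
    ca_set: tuple = DEFAULT_CA_SET
    n_patches: int = 5
    sigma_q: float = 0.015
    sigma_trace: float = 0.05
    sigma_vh: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.v_grid = np.asarray(self.v_grid, dtype=float)
        if self.fs * self.pulse_ms * 1e-3 < 100:
            raise InvalidParameterError(
                "protocol must yield >= 100 samples per pulse"
            )

    @property
    def t_grid_us(self) -> np.ndarray:
        """Sample times over one pulse, us."""
        n = int(round(self.pulse_ms * 1e-3 * self.fs))
        return np.arange(n) / self.fs * 1e6

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_qv_dataset(
    model: AllostericModelSpec,
    proto: ProtocolSpec,
    temperature: float = DEFAULT_TEMPERATURE,
    rng: np.random.Generator | None = None,
) -> list[QVCurve]:
    """Draw per-patch Q-V curves from an allosteric model.

    For each (ca, patch): q(v) = model curve evaluated on a voltage axis
    offset by N(0, sigma_vh), plus N(0, sigma_q) per point.  The offset
    emulates patch-to-patch variability in VH and is what the alignment
    step corrects.
    """
    rng = proto.rng() if rng is None else rng
    curves = []
    for ca in proto.ca_set:
        for patch in range(proto.n_patches):
            dv = rng.normal(0.0, proto.sigma_vh) if proto.sigma_vh > 0 else 0.0
            q = np.asarray(qc_curve(proto.v_grid - dv, ca, model, temperature))
            if proto.sigma_q > 0:
                q = q + rng.normal(0.0, proto.sigma_q, size=q.shape)
            curves.append(
                QVCurve(v=proto.v_grid.copy(), q=q, ca=ca,
                        patch_id=f"ca{ca:g}_p{patch}")
            )
    return curves


def generate_gating_trace(
    qc: float,
    tau: float,
    proto: ProtocolSpec,
    v_step: float = 0.0,
    ca: float = ZERO_CA_UM,
    rng: np.random.Generator | None = None,
) -> GatingTrace:
    """Synthesize one ON-gating-current transient.

    I(t) = (qc/tau) exp(-t/tau) + N(0, sigma_trace), sampled on the protocol
    grid; the noiseless integral over the pulse is qc (1 - exp(-pulse/tau)).

    qc is in charge units (current x us), tau in us.
    """
    if qc < 0:
        raise InvalidParameterError(f"qc must be >= 0, got {qc}")
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    rng = proto.rng() if rng is None else rng
    t = proto.t_grid_us
    i = (qc / tau) * np.exp(-t / tau)
    if proto.sigma_trace > 0:
        i = i + rng.normal(0.0, proto.sigma_trace * i[0], size=i.shape)
    return GatingTrace(t=t, i=i, v_step=v_step, ca=ca, fs=proto.fs)


def generate_trace_family(
    model: AllostericModelSpec,
    rates: TwoStateRates,
    proto: ProtocolSpec,
    ca: float,
    qc_max: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    rng: np.random.Generator | None = None,
) -> list[GatingTrace]:
    """One trace per protocol voltage, with QC(V) from the model and tau(V)
    from the two-state kinetics (a convenience for pipeline round trips)."""
    rng = proto.rng() if rng is None else rng
    traces = []
    for v in proto.v_grid:
        qc = qc_max * float(qc_curve(v, ca, model, temperature))
        tau = float(tau_two_state(v, rates, temperature))
        traces.append(
            generate_gating_trace(qc, tau, proto, v_step=v, ca=ca, rng=rng)
        )
    return traces


def generate_tau_dataset(
    rates: TwoStateRates,
    proto: ProtocolSpec,
    noise_frac: float = 0.1,
    temperature: float = DEFAULT_TEMPERATURE,
    rng: np.random.Generator | None = None,
) -> TauCurve:
    """tau(V) on the protocol grid with multiplicative lognormal noise."""
    if noise_frac < 0:
        raise InvalidParameterError(f"noise_frac must be >= 0, got {noise_frac}")
    rng = proto.rng() if rng is None else rng
    tau = np.asarray(tau_two_state(proto.v_grid, rates, temperature))
    if noise_frac > 0:
        tau = tau * np.exp(rng.normal(0.0, noise_frac, size=tau.shape))
    return TauCurve(v=proto.v_grid.copy(), tau=tau)


def write_ground_truth(model: AllostericModelSpec, proto: ProtocolSpec, path) -> None:
    """JSON sidecar recording the generating model and protocol."""
    payload = {
        "model": model.to_dict(),
        "protocol": {
            "v_grid_mV": proto.v_grid.tolist(),
            "pulse_ms": proto.pulse_ms,
            "fs_Hz": proto.fs,
            "ca_set_uM": list(proto.ca_set),
            "n_patches": proto.n_patches,
            "sigma_q": proto.sigma_q,
            "sigma_trace": proto.sigma_trace,
            "sigma_vh_mV": proto.sigma_vh,
            "seed": proto.seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
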