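"""Boltzmann representation and fitting of fast gating-charge Q-V curves.

The fast gating charge QC moved among closed states follows a single
Boltzmann in voltage at fixed Ca2+:

    QC(V) = QC_MAX / (1 + exp(-zQ F (V - VH) / RT))

with half-activation voltage VH (mV) and apparent valence zQ (e0).  This
module fits that form, aligns replicate curves along the voltage axis, and
extracts apparent (VH, zQ) from arbitrary model-generated curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from bkgating.errors import FitFailureError, InvalidParameterError
from bkgating.thermo import DEFAULT_TEMPERATURE, thermal_voltage_mv

__all__ = [
    "QVCurve",
    "BoltzmannParams",
    "boltzmann_fraction",
    "fit_boltzmann",
    "align_qv_curves",
    "apparent_params",
    "read_qv_csv",
    "write_qv_csv",
]


@dataclass
class BoltzmannParams:
    """Parameters of a single-component Boltzmann Q-V curve.

    vh : half-activation voltage, mV.
    zq : apparent gating charge, e0 (> 0).
    qmax : scale factor (1 for normalized data).
    se_vh, se_zq : standard errors from the fit Jacobian, when available.
    """

    vh: float
    zq: float
    qmax: float = 1.0
    se_vh: float | None = None
    se_zq: float | None = None

    def __post_init__(self) -> None:
        if self.zq <= 0:
            raise InvalidParameterError(f"zq must be positive, got {self.zq}")
        if self.qmax <= 0:
            raise InvalidParameterError(f"qmax must be positive, got {self.qmax}")


@dataclass
class QVCurve:
    """Normalized fast gating charge versus voltage at one Ca2+ concentration.

    v : voltages, mV, strictly increasing.
    q : normalized charge (dimensionless, ~[0, 1] up to noise).
    sem : optional per-point uncertainty.
    ca : internal Ca2+, uM.
    n : replicate count behind each point.
    patch_id : identifier of the source patch (synthetic or experimental).
    """

    v: np.ndarray
    q: np.ndarray
    ca: float
    sem: np.ndarray | None = None
    n: int = 1
    patch_id: str = ""

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.v.shape != self.q.shape:
            raise InvalidParameterError("v and q must have the same shape")
        if np.any(np.diff(self.v) <= 0):
            raise InvalidParameterError("voltages must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.v.shape:
                raise InvalidParameterError("sem must match v in shape")

    def shifted(self, dv: float) -> "QVCurve":
        """Copy of the curve translated by ``dv`` along the voltage axis."""
        return QVCurve(
            v=self.v + dv, q=self.q.copy(), ca=self.ca,
            sem=None if self.sem is None else self.sem.copy(),
            n=self.n, patch_id=self.patch_id,
        )


def boltzmann_fraction(
    v: np.ndarray | float,
    p: BoltzmannParams,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Evaluate the Boltzmann Q-V curve at voltage(s) ``v`` (mV)."""
    vt = thermal_voltage_mv(temperature)
    x = np.asarray(v, dtype=float)
    out = p.qmax / (1.0 + np.exp(-p.zq * (x - p.vh) / vt))
    return float(out) if np.isscalar(v) else out


def _boltzmann_model(v, vh, zq, qmax, vt):
    return qmax / (1.0 + np.exp(-zq * (v - vh) / vt))


def fit_boltzmann(
    curve: QVCurve,
    temperature: float = DEFAULT_TEMPERATURE,
    weights: str = "none",
    fix_qmax: float | None = None,
) -> BoltzmannParams:
    """Least-squares Boltzmann fit of a Q-V curve.

    Parameters
    ----------
    curve : QVCurve
        At least 5 points spanning the inflection.
    weights : {"none", "sem"}
        ``"sem"`` weights residuals by 1/sem^2 when the curve carries
        per-point uncertainties; default unweighted.
    fix_qmax : float, optional
        Hold the scale fixed (e.g. 1.0 for pre-normalized data) instead of
        fitting it.

    Returns
    -------
    BoltzmannParams with Jacobian-based standard errors.

    Raises
    ------
    FitFailureError
        On non-convergence or when the fitted curve explains almost none of
        the variance (e.g. monotone-decreasing input, which would need a
        negative valence).
    """
    v, q = curve.v, curve.q
    if v.size < 5:
        raise InvalidParameterError(f"need >= 5 points, got {v.size}")
    vt = thermal_voltage_mv(temperature)

    sigma = None
    if weights == "sem" and curve.sem is not None:
        sigma = np.where(curve.sem > 0, curve.sem, np.nanmax(curve.sem) or 1.0)

    qmax0 = fix_qmax if fix_qmax is not None else max(float(np.max(q)), 1e-6)
    half = 0.5 * qmax0
    vh0 = float(v[np.argmin(np.abs(q - half))])
    p0 = [vh0, 0.6]
    lo = [v.min() - 500.0, 1e-3]
    hi = [v.max() + 500.0, 10.0]
    if fix_qmax is None:
        p0.append(qmax0)
        lo.append(1e-3)
        hi.append(10.0 * qmax0 + 1.0)

    if fix_qmax is None:
        model = lambda vv, vh, zq, qmax: _boltzmann_model(vv, vh, zq, qmax, vt)
    else:
        model = lambda vv, vh, zq: _boltzmann_model(vv, vh, zq, fix_qmax, vt)

    try:
        popt, pcov = curve_fit(
            model, v, q, p0=p0, sigma=sigma, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "Boltzmann fit did not converge",
            {"p0": p0, "error": str(exc), "ca": curve.ca},
        ) from exc

    pred = model(v, *popt)
    ss_res = float(np.sum((q - pred) ** 2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    if ss_tot > 0 and 1.0 - ss_res / ss_tot < 0.5:
        raise FitFailureError(
            "Boltzmann fit explains <50% of variance; data are not an "
            "increasing sigmoid",
            {"popt": list(popt), "r2": 1.0 - ss_res / ss_tot, "ca": curve.ca},
        )

    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    qmax_fit = fix_qmax if fix_qmax is not None else float(popt[2])
    params = BoltzmannParams(
        vh=float(popt[0]), zq=float(popt[1]), qmax=qmax_fit,
        se_vh=float(se[0]), se_zq=float(se[1]),
    )
    if not (v.min() <= params.vh <= v.max()):
        warnings.warn(
            f"fitted VH={params.vh:.1f} mV lies outside the sampled voltage "
            f"range [{v.min():.0f}, {v.max():.0f}] mV",
            stacklevel=2,
        )
    return params


def align_qv_curves(
    curves: Sequence[QVCurve],
    fits: Sequence[BoltzmannParams],
) -> list[QVCurve]:
    """Shift replicate curves along V so each fitted VH lands on the mean VH.

    Each curve is translated by dV = <VH> - VH, a pure shift that leaves its
    valence zQ untouched; refitting any aligned curve returns <VH>.
    """
    if len(curves) != len(fits):
        raise InvalidParameterError(
            f"curves ({len(curves)}) and fits ({len(fits)}) differ in length"
        )
    mean_vh = float(np.mean([f.vh for f in fits]))
    return [c.shifted(mean_vh - f.vh) for c, f in zip(curves, fits)]


def apparent_params(
    model_curve_fn: Callable[[np.ndarray], np.ndarray],
    v_grid: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BoltzmannParams:
    """Single-Boltzmann fit of a model-generated Q-V curve.

    Multi-component model curves (mixtures over ligation states) are reduced
    to apparent (VH, zQ) exactly the way experimental curves are, which is
    what makes model-predicted VH(Ca) and zQ(Ca) dose curves comparable with
    data.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    q = np.asarray(model_curve_fn(v_grid), dtype=float)
    curve = QVCurve(v=v_grid, q=q, ca=np.nan)
    return fit_boltzmann(curve, temperature=temperature)


# ---------------------------------------------------------------------------
# CSV I/O (long format: one row per point)

QV_COLUMNS = ["v_mV", "q_norm", "sem", "ca_uM", "patch_id"]


def write_qv_csv(curves: Sequence[QVCurve], path) -> None:
    """Write curves to a long-format CSV (columns v_mV, q_norm, sem, ca_uM,
    patch_id)."""
    rows = []
    for c in curves:
        sem = c.sem if c.sem is not None else np.full_like(c.v, np.nan)
        for vi, qi, si in zip(c.v, c.q, sem):
            rows.append(
                {"v_mV": vi, "q_norm": qi, "sem": si, "ca_uM": c.ca,
                 "patch_id": c.patch_id}
            )
    pd.DataFrame(rows, columns=QV_COLUMNS).to_csv(path, index=False)


def read_qv_csv(path) -> list[QVCurve]:
    """Read curves from the long-format CSV written by :func:`write_qv_csv`."""
    df = pd.read_csv(path)
    missing = {"v_mV", "q_norm", "ca_uM"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"QV CSV missing columns: {sorted(missing)}")
    if "patch_id" not in df.columns:
        df["patch_id"] = ""
    df["patch_id"] = df["patch_id"].fillna("")
    curves = []
    for (ca, patch), grp in df.groupby(["ca_uM", "patch_id"], sort=True):
        grp = grp.sort_values("v_mV")
        sem = None
        if "sem" in grp.columns and grp["sem"].notna().all():
            sem = grp["sem"].to_numpy()
        curves.append(
            QVCurve(v=grp["v_mV"].to_numpy(), q=grp["q_norm"].to_numpy(),
                    ca=float(ca), sem=sem, patch_id=str(patch))
        )
    return curves
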