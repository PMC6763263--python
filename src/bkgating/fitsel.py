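"""Constrained global fitting of QC(V, Ca) data and AIC model selection.

Each candidate coupling model is fitted to the full (V, Ca) dataset by least
squares with the allosteric coupling factors held fixed at their
experimentally determined values (from the 0 vs saturating-Ca2+ energetics,
or from the single-site mutants for two-site models); only zJ, J0 and the
dissociation constants (plus optionally the intrasubunit cooperativity G)
vary.  Models are compared through the Akaike Information Criterion

    AIC_i = 2 p_i - 2 ln L_i

with the maximized log-likelihood taken from the concentrated Gaussian form
ln L = -(n/2) (ln(2 pi RSS/n) + 1), and summarized as relative likelihoods
L_i = exp(-dAIC_i/2) and Akaike weights w_i = L_i / sum_k L_k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from bkgating.camodels import AllostericModelSpec, SiteConfig, qc_curve
from bkgating.errors import FitFailureError, InvalidParameterError
from bkgating.qv import QVCurve
from bkgating.thermo import DEFAULT_TEMPERATURE

__all__ = [
    "FitResult",
    "ModelComparison",
    "gaussian_loglik",
    "aic",
    "akaike_compare",
    "global_fit",
    "model_selection",
]


def gaussian_loglik(rss: float, n: int) -> float:
    """Concentrated Gaussian log-likelihood of a least-squares fit.

    With the residual variance profiled out at its MLE rss/n,
    ln L = -(n/2) (ln(2 pi rss/n) + 1).  A zero RSS (exactly interpolating
    fit) is degenerate; +inf is returned with a warning so callers can flag
    the model rather than crash.
    """
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 data points, got {n}")
    if rss < 0:
        raise InvalidParameterError(f"rss must be >= 0, got {rss}")
    if rss == 0.0:
        warnings.warn("rss = 0: degenerate fit, log-likelihood unbounded",
                      stacklevel=2)
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def aic(p: int, loglik: float) -> float:
    """Akaike Information Criterion: AIC = 2p - 2 ln L."""
    if p < 0:
        raise InvalidParameterError(f"p must be >= 0, got {p}")
    return 2.0 * p - 2.0 * loglik


@dataclass
class ModelComparison:
    """AIC comparison across candidate models.

    table : DataFrame with columns model, aic, delta_aic, rel_likelihood,
        weight, sorted in input order.
    best : label of the minimum-AIC model.
    """

    table: pd.DataFrame
    best: str

    def weight(self, label: str) -> float:
        row = self.table[self.table["model"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["weight"].iloc[0])


def akaike_compare(aics: Sequence[float], labels: Sequence[str]) -> ModelComparison:
    """Relative likelihoods and Akaike weights from a set of AIC values.

    dAIC_i = AIC_i - min(AIC); L_i = exp(-dAIC_i/2); w_i normalizes L_i to
    sum to one.  Invariant under adding any constant to all AICs.
    """
    if len(aics) != len(labels):
        raise InvalidParameterError("aics and labels must have equal length")
    if len(aics) < 1:
        raise InvalidParameterError("need at least one model")
    a = np.asarray(aics, dtype=float)
    delta = a - a.min()
    rel = np.exp(-0.5 * delta)
    w = rel / rel.sum()
    table = pd.DataFrame(
        {"model": list(labels), "aic": a, "delta_aic": delta,
         "rel_likelihood": rel, "weight": w}
    )
    return ModelComparison(table=table, best=labels[int(np.argmin(a))])


@dataclass
class FitResult:
    """Outcome of a constrained global fit of one candidate model.

    model : the fitted AllostericModelSpec (free parameters at their
        estimates, fixed factors untouched).
    free_params : {name: estimate}.
    fixed_params : {name: value} — always includes the coupling factors.
    se : {name: standard error} from the Jacobian, NaN when singular.
    rss : residual sum of squares.  n : number of points.
    p : number of free parameters.  loglik, aic : Gaussian likelihood / AIC.
    """

    model: AllostericModelSpec
    free_params: dict
    fixed_params: dict
    se: dict
    rss: float
    n: int
    p: int
    loglik: float
    aic: float

    def to_dict(self) -> dict:
        return {
            "label": self.model.label,
            "free_params": self.free_params,
            "fixed_params": self.fixed_params,
            "se": self.se,
            "rss": self.rss,
            "n": self.n,
            "p": self.p,
            "loglik": self.loglik,
            "aic": self.aic,
        }


def _free_param_names(template: AllostericModelSpec, free_g: bool) -> list[str]:
    if template.sites.n_sites == 1:
        return ["zj", "j0", "kd"]
    names = ["zj", "j0", "kd1", "kd2"]
    if free_g:
        names.append("g")
    return names


def _spec_with(template: AllostericModelSpec, values: dict) -> AllostericModelSpec:
    sites = template.sites
    if sites.n_sites == 1:
        sites = SiteConfig(n_sites=1, kd=values.get("kd", sites.kd), g=sites.g)
    else:
        sites = SiteConfig(
            n_sites=2,
            kd1=values.get("kd1", sites.kd1),
            kd2=values.get("kd2", sites.kd2),
            g=values.get("g", sites.g),
        )
    return replace(template, sites=sites,
                   zj=values.get("zj", template.zj),
                   j0=values.get("j0", template.j0))


def global_fit(
    dataset: Sequence[QVCurve],
    spec_template: AllostericModelSpec,
    temperature: float = DEFAULT_TEMPERATURE,
    free_g: bool = False,
    weights: str = "none",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit one coupling model to a multi-Ca QC(V) dataset.

    The coupling factors carried by ``spec_template`` stay fixed; zJ, J0 and
    the KD(s) (log-parameterized) are estimated by bounded least squares from
    ``n_starts`` seeded starts, keeping the best residual.

    Requires at least 3 Ca conditions spanning near-zero to saturating —
    a single condition cannot constrain KD.
    """
    cas = sorted({c.ca for c in dataset})
    if len(cas) < 3:
        raise InvalidParameterError(
            f"need >= 3 Ca conditions to constrain binding, got {len(cas)}"
        )
    names = _free_param_names(spec_template, free_g)

    v_all = np.concatenate([c.v for c in dataset])
    q_all = np.concatenate([c.q for c in dataset])
    if weights == "sem":
        w_all = np.concatenate([
            1.0 / np.maximum(c.sem, 1e-6) if c.sem is not None
            else np.ones_like(c.v)
            for c in dataset
        ])
    else:
        w_all = np.ones_like(v_all)

    # log-parameterization for positive scale parameters
    log_names = {n for n in names if n != "zj"}

    def unpack(theta):
        return {
            name: (math.exp(t) if name in log_names else t)
            for name, t in zip(names, theta)
        }

    def resid_flat(theta):
        spec = _spec_with(spec_template, unpack(theta))
        pred = np.concatenate([
            np.asarray(qc_curve(c.v, c.ca, spec, temperature)) for c in dataset
        ])
        return (pred - q_all) * w_all

    base = {
        "zj": spec_template.zj, "j0": spec_template.j0,
        "kd": spec_template.sites.kd, "kd1": spec_template.sites.kd1,
        "kd2": spec_template.sites.kd2, "g": spec_template.sites.g,
    }
    x0 = np.array([
        math.log(base[n]) if n in log_names else base[n] for n in names
    ])
    lo = np.array([
        0.05 if n == "zj" else math.log(1e-6) for n in names
    ])
    hi = np.array([
        5.0 if n == "zj" else math.log(1e6) for n in names
    ])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.5, size=x0.size)
        xs = np.clip(xs, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid_flat, xs, bounds=(lo, hi), max_nfev=10000)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("global fit failed from every start",
                              {"model": spec_template.label})

    est = unpack(best.x)
    rss = float(np.sum(best.fun**2))
    n = int(q_all.size)
    p = len(names)
    ll = gaussian_loglik(rss, n)

    # delta-method standard errors back on the natural scale
    se = {}
    try:
        J = best.jac
        dof = max(n - p, 1)
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        for i, name in enumerate(names):
            s = math.sqrt(max(cov[i, i], 0.0))
            se[name] = s * est[name] if name in log_names else s
    except np.linalg.LinAlgError:
        se = {name: float("nan") for name in names}

    at_bound = np.any(np.isclose(best.x, lo, atol=1e-6) |
                      np.isclose(best.x, hi, atol=1e-6))
    if at_bound:
        warnings.warn(
            f"{spec_template.label or spec_template.scheme}: a parameter "
            "sits at its bound; estimates may be unreliable",
            stacklevel=2,
        )

    fitted = _spec_with(spec_template, est)
    fixed = {}
    if spec_template.sites.n_sites == 1:
        fixed["e_factor"] = spec_template.e_factor
    else:
        fixed["e_s1"] = spec_template.e_s1
        fixed["e_s2"] = spec_template.e_s2
        if not free_g:
            fixed["g"] = spec_template.sites.g
    return FitResult(
        model=fitted, free_params=est, fixed_params=fixed, se=se,
        rss=rss, n=n, p=p, loglik=ll, aic=aic(p, ll),
    )


def model_selection(
    dataset: Sequence[QVCurve],
    candidates: Sequence[AllostericModelSpec],
    temperature: float = DEFAULT_TEMPERATURE,
    free_g: bool = False,
    weights: str = "none",
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[ModelComparison, list[FitResult]]:
    """Fit every candidate model and assemble the AIC comparison table."""
    if len(candidates) < 1:
        raise InvalidParameterError("need at least one candidate model")
    fits = []
    for i, cand in enumerate(candidates):
        fits.append(
            global_fit(dataset, cand, temperature=temperature, free_g=free_g,
                       weights=weights, n_starts=n_starts, seed=seed + i)
        )
    labels = [
        f.model.label or f"scheme {f.model.scheme} / {f.model.sites.n_sites} site(s)"
        for f in fits
    ]
    comparison = akaike_compare([f.aic for f in fits], labels)
    return comparison, fits
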