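"""Closed-form equilibrium QC(V, Ca) curves for Ca2+ / voltage-sensor coupling.

Two coupling topologies are implemented for the BK homotetramer, each with
one or two high-affinity Ca2+ sites per alpha-subunit:

* **Scheme I (same-subunit coupling).**  Ca2+ bound to a subunit amplifies
  the R-A equilibrium constant J of the voltage sensor of *that* subunit
  only, by the allosteric factor E.  Because the total gating charge is the
  sum of four independent sensors, the normalized charge is the per-subunit
  mixture over binding states:

      QC/QC_MAX = sum_s P(s) * J*E_s / (1 + J*E_s)

  with E_s the product of the factors of the occupied sites of that subunit
  (one site: E; two sites: E_S1**s1 * E_S2**s2).

* **Scheme II (concerted coupling).**  Each bound Ca2+, on any subunit,
  amplifies J of *all four* sensors by the per-event factor e = E**(1/4), so
  full occupancy reproduces the per-subunit factor (e**4 = E).  With k ions
  bound channel-wide,

      QC/QC_MAX = sum_k P(k) * J*e**k / (1 + J*e**k)

  a five-component Boltzmann for one site per subunit; the two-site version
  sums over the joint (n1, n2) count distribution with factor
  e_S1**n1 * e_S2**n2.

Both schemes assume frozen occupancy: Ca2+ equilibrates with closed,
resting-sensor channels before the pulse and does not re-equilibrate during
the ~100 us charge measurement (the kinetic validity of this assumption is
examined in :mod:`bkgating.kinsim`).  Site occupancy is therefore ligand-only:
one site binds with probability x = ca/(ca + KD); two sites within a subunit
carry statistical weights 1 : ca/KD1 : ca/KD2 : G*ca^2/(KD1*KD2), where G is
an intrasubunit cooperativity factor (G = 1, independent sites).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bkgating.errors import InvalidParameterError
from bkgating.qv import BoltzmannParams, apparent_params
from bkgating.thermo import DEFAULT_TEMPERATURE, thermal_voltage_mv

__all__ = [
    "N_SUBUNITS",
    "SiteConfig",
    "AllostericModelSpec",
    "OccupancyState",
    "subunit_occupancy",
    "channel_occupancy_distribution",
    "qc_scheme1",
    "qc_scheme2",
    "qc_curve",
    "predicted_dose_curves",
]

#: BK channels are homotetramers: four voltage sensors, four CTDs.
N_SUBUNITS = 4


@dataclass(frozen=True)
class SiteConfig:
    """High-affinity Ca2+ sites carried by one alpha-subunit.

    n_sites : 1 (single lumped site) or 2 (RCK1 and RCK2).
    kd : dissociation constant, uM (one-site models).
    kd1, kd2 : per-site dissociation constants, uM (two-site models).
    g : intrasubunit cooperativity factor between the two sites
        (1 = independent binding; >1 = positive cooperativity).
    """

    n_sites: int = 1
    kd: float | None = None
    kd1: float | None = None
    kd2: float | None = None
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites == 1:
            if self.kd is None or self.kd <= 0:
                raise InvalidParameterError(f"one-site config needs kd > 0, got {self.kd}")
        elif self.n_sites == 2:
            if self.kd1 is None or self.kd2 is None or self.kd1 <= 0 or self.kd2 <= 0:
                raise InvalidParameterError(
                    f"two-site config needs kd1, kd2 > 0, got ({self.kd1}, {self.kd2})"
                )
        else:
            raise InvalidParameterError(f"n_sites must be 1 or 2, got {self.n_sites}")
        if self.g <= 0:
            raise InvalidParameterError(f"g must be positive, got {self.g}")


@dataclass(frozen=True)
class AllostericModelSpec:
    """A Ca2+ / voltage-sensor interaction model.

    scheme : "I" (same-subunit) or "II" (concerted).
    sites : SiteConfig.
    zj : gating charge per voltage sensor, e0.
    j0 : zero-voltage R-A equilibrium constant.
    e_factor : per-subunit saturating allosteric factor E (one-site models).
    e_s1, e_s2 : per-subunit factors of the RCK1 / RCK2 sites (two-site
        models); at saturation E = E_S1 * E_S2.

    Factors are stored on the per-subunit scale for both schemes; Scheme II
    converts internally to per-event factors E**(1/N_SUBUNITS).
    """

    scheme: str
    sites: SiteConfig
    zj: float
    j0: float
    e_factor: float | None = None
    e_s1: float | None = None
    e_s2: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in ("I", "II"):
            raise InvalidParameterError(f"scheme must be 'I' or 'II', got {self.scheme!r}")
        if self.zj <= 0 or self.j0 <= 0:
            raise InvalidParameterError(
                f"zj and j0 must be positive, got ({self.zj}, {self.j0})"
            )
        if self.sites.n_sites == 1:
            if self.e_factor is None or self.e_factor <= 0:
                raise InvalidParameterError(
                    f"one-site model needs e_factor > 0, got {self.e_factor}"
                )
        else:
            if (
                self.e_s1 is None or self.e_s2 is None
                or self.e_s1 <= 0 or self.e_s2 <= 0
            ):
                raise InvalidParameterError(
                    f"two-site model needs e_s1, e_s2 > 0, got ({self.e_s1}, {self.e_s2})"
                )

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme, "zj": self.zj, "j0": self.j0, "label": self.label,
            "n_sites": self.sites.n_sites, "g": self.sites.g,
        }
        if self.sites.n_sites == 1:
            d.update(kd=self.sites.kd, e_factor=self.e_factor)
        else:
            d.update(kd1=self.sites.kd1, kd2=self.sites.kd2,
                     e_s1=self.e_s1, e_s2=self.e_s2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AllostericModelSpec":
        n = int(d.get("n_sites", 1))
        if n == 1:
            sites = SiteConfig(n_sites=1, kd=d["kd"], g=d.get("g", 1.0))
            return cls(scheme=d["scheme"], sites=sites, zj=d["zj"], j0=d["j0"],
                       e_factor=d["e_factor"], label=d.get("label", ""))
        sites = SiteConfig(n_sites=2, kd1=d["kd1"], kd2=d["kd2"], g=d.get("g", 1.0))
        return cls(scheme=d["scheme"], sites=sites, zj=d["zj"], j0=d["j0"],
                   e_s1=d["e_s1"], e_s2=d["e_s2"], label=d.get("label", ""))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AllostericModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class OccupancyState:
    """Equilibrium distribution of one subunit over its binding states.

    One-site: probs over (unbound, bound); x = ca/(ca + kd).
    Two-site: probs over (00, 10, 01, 11) with s1 the RCK1 site and s2 the
    RCK2 site.
    """

    probs: np.ndarray
    n_sites: int

    @property
    def x(self) -> float:
        """One-site occupancy (probability the site is bound)."""
        if self.n_sites == 1:
            return float(self.probs[1])
        # marginal total occupancy is not a single number for two sites
        raise InvalidParameterError("x is defined for one-site configs only")


def subunit_occupancy(ca: float, s: SiteConfig) -> OccupancyState:
    """Equilibrium binding-state distribution of a single subunit.

    One-site: (1-x, x) with x = ca/(ca + kd).  Two-site: normalized weights
    1 : ca/kd1 : ca/kd2 : g*ca^2/(kd1*kd2) over states (00, 10, 01, 11);
    g = 1 factorizes into independent one-site occupancies.
    """
    if ca < 0:
        raise InvalidParameterError(f"ca must be >= 0, got {ca}")
    if s.n_sites == 1:
        x = ca / (ca + s.kd)
        return OccupancyState(probs=np.array([1.0 - x, x]), n_sites=1)
    w = np.array([
        1.0,
        ca / s.kd1,
        ca / s.kd2,
        s.g * ca * ca / (s.kd1 * s.kd2),
    ])
    return OccupancyState(probs=w / w.sum(), n_sites=2)


def channel_occupancy_distribution(occ: OccupancyState) -> np.ndarray:
    """Distribution of channel-level bound counts over the four subunits.

    One-site: binomial(4, x) over k = 0..4, returned as a length-5 vector.
    Two-site: joint distribution over (n1, n2) in {0..4}^2 from the 4-fold
    convolution of the subunit (s1, s2) distribution, returned as a 5x5
    matrix P[n1, n2].
    """
    if occ.n_sites == 1:
        x = occ.probs[1]
        k = np.arange(N_SUBUNITS + 1)
        from scipy.stats import binom

        return binom.pmf(k, N_SUBUNITS, x)
    # 4-fold convolution of the per-subunit (s1, s2) in {0,1}^2 distribution
    p = occ.probs  # order: 00, 10, 01, 11
    sub = np.zeros((2, 2))
    sub[0, 0], sub[1, 0], sub[0, 1], sub[1, 1] = p[0], p[1], p[2], p[3]
    joint = np.array([[1.0]])
    for _ in range(N_SUBUNITS):
        new = np.zeros((joint.shape[0] + 1, joint.shape[1] + 1))
        for ds1 in range(2):
            for ds2 in range(2):
                new[ds1: ds1 + joint.shape[0], ds2: ds2 + joint.shape[1]] += (
                    sub[ds1, ds2] * joint
                )
        joint = new
    return joint


def _equilibrium_j(v, zj, j0, temperature):
    vt = thermal_voltage_mv(temperature)
    return j0 * np.exp(zj * np.asarray(v, dtype=float) / vt)


def qc_scheme1(
    v: np.ndarray | float,
    ca: float,
    m: AllostericModelSpec,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Normalized fast gating charge under Scheme I (same-subunit coupling).

    Per-subunit mixture over binding states: each state s activates its own
    sensor with equilibrium J*E_s.  Reduces to J/(1+J) at ca = 0 and to
    J*E/(1+J*E) at saturation.
    """
    if m.scheme != "I":
        raise InvalidParameterError(f"qc_scheme1 requires scheme 'I', got {m.scheme!r}")
    occ = subunit_occupancy(ca, m.sites)
    J = _equilibrium_j(v, m.zj, m.j0, temperature)
    if m.sites.n_sites == 1:
        factors = np.array([1.0, m.e_factor])
    else:
        factors = np.array([1.0, m.e_s1, m.e_s2, m.e_s1 * m.e_s2])
    out = np.zeros_like(np.asarray(J, dtype=float))
    for p_s, e_s in zip(occ.probs, factors):
        je = J * e_s
        out = out + p_s * je / (1.0 + je)
    return float(out) if np.isscalar(v) else out


def qc_scheme2(
    v: np.ndarray | float,
    ca: float,
    m: AllostericModelSpec,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Normalized fast gating charge under Scheme II (concerted coupling).

    Mixture over channel-level bound counts: k bound ions amplify every
    sensor's J by e**k with per-event factor e = E**(1/4) (two sites:
    e_S1**n1 * e_S2**n2).  One site per subunit gives the five-component
    Boltzmann; both limits (ca = 0, ca -> inf) match Scheme I exactly.
    """
    if m.scheme != "II":
        raise InvalidParameterError(f"qc_scheme2 requires scheme 'II', got {m.scheme!r}")
    occ = subunit_occupancy(ca, m.sites)
    dist = channel_occupancy_distribution(occ)
    J = _equilibrium_j(v, m.zj, m.j0, temperature)
    out = np.zeros_like(np.asarray(J, dtype=float))
    if m.sites.n_sites == 1:
        e = m.e_factor ** (1.0 / N_SUBUNITS)
        for k in range(N_SUBUNITS + 1):
            je = J * e ** k
            out = out + dist[k] * je / (1.0 + je)
    else:
        e1 = m.e_s1 ** (1.0 / N_SUBUNITS)
        e2 = m.e_s2 ** (1.0 / N_SUBUNITS)
        for n1 in range(N_SUBUNITS + 1):
            for n2 in range(N_SUBUNITS + 1):
                je = J * e1 ** n1 * e2 ** n2
                out = out + dist[n1, n2] * je / (1.0 + je)
    return float(out) if np.isscalar(v) else out


def qc_curve(
    v: np.ndarray | float,
    ca: float,
    m: AllostericModelSpec,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray | float:
    """Dispatch to the scheme-appropriate QC(V, Ca) closed form."""
    if m.scheme == "I":
        return qc_scheme1(v, ca, m, temperature)
    return qc_scheme2(v, ca, m, temperature)


def predicted_dose_curves(
    m: AllostericModelSpec,
    ca_grid: np.ndarray,
    v_grid: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Apparent (VH, zQ) versus Ca2+ predicted by a model.

    For each concentration the model curve is reduced to a single-Boltzmann
    fit exactly as experimental curves are, yielding the VH-log(Ca) and
    zQ-log(Ca) dose curves used to discriminate the schemes.

    Returns a DataFrame with columns ca_uM, vh_mV, zq.
    """
    rows = []
    for ca in np.asarray(ca_grid, dtype=float):
        fit = apparent_params(
            lambda vv, _ca=ca: qc_curve(vv, _ca, m, temperature),
            np.asarray(v_grid, dtype=float),
            temperature=temperature,
        )
        rows.append({"ca_uM": ca, "vh_mV": fit.vh, "zq": fit.zq})
    return pd.DataFrame(rows)
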