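# bkgating

Analysis of BK-channel gating currents and of the allosteric coupling
between intracellular Ca²⁺ binding and voltage-sensor activation.

Large-conductance Ca²⁺- and voltage-activated K⁺ (BK) channels are
homotetramers in which each α-subunit carries a transmembrane voltage-sensing
domain (VSD) and a cytosolic C-terminal domain with two high-affinity Ca²⁺
sites (RCK1 and RCK2). Ca²⁺ binding facilitates VSD activation: the fast
gating charge–voltage curve QC(V), measured from ON-gating currents while the
channel is still closed, shifts strongly leftward as internal Ca²⁺ rises.
This package implements the full analysis chain used to quantify that
coupling and to discriminate between competing coupling topologies, exercised
end-to-end on synthetic data with known ground truth (no raw recordings are
publicly deposited for this experimental design).

## What it computes

**From gating-current transients** (`signals`): the fast ON-gating decay is
fitted with a single exponential A·exp(−t/τ) over the first 50–100 µs and the
fast charge is its analytic area, Q_C = A·τ.

**Boltzmann Q-V analysis** (`qv`): Q_C(V)/Q_C,MAX = 1/(1 + e^(−z_Q F(V−V_H)/RT)),
with per-patch alignment along the voltage axis and reduction of arbitrary
model curves to apparent (V_H, z_Q).

**Two-state VSD kinetics** (`kinetics`): τ(V) = 1/(α(V)+β(V)) with
α = α₀e^(z_J δFV/RT), β = β₀e^(z_J(δ−1)FV/RT), fitted with z_J constrained to
the Q-V valence.

**Coupling energetics** (`thermo`): ΔΔG_VCa = F(z_Q,Ca·V_H,Ca − z_Q,0·V_H,0),
the allosteric factor E = e^(−ΔΔG_VCa/RT), and per-binding-event factors
E^(1/4) for concerted schemes.

**Allosteric coupling models** (`camodels`): closed-form equilibrium
QC(V, Ca) curves for two topologies — Scheme I, where Ca²⁺ bound to a subunit
amplifies only that subunit's VSD equilibrium J by E, giving a per-subunit
mixture Σ P(state)·JE_state/(1+JE_state); and Scheme II, where every bound
Ca²⁺ amplifies all four VSDs by E^(1/4), giving a five-component Boltzmann
over channel-level occupancy. Both come in one-site and two-site (RCK1/RCK2,
optional intrasubunit cooperativity G) variants.

**Global fitting and model selection** (`fitsel`): constrained least-squares
fits of QC(V, Ca) families with the coupling factors fixed to experimental
values, compared by AIC_i = 2p_i − 2 ln L_i, relative likelihoods
ℒ_i = e^(−ΔAIC_i/2) and Akaike weights.

**Binding-kinetics simulation** (`kinsim`): a master-equation model of
coupled Ca²⁺ binding and VSD activation that tests whether Ca²⁺
re-equilibration during the ~100 µs measurement could make a same-subunit
mechanism mimic a concerted one.

**Synthetic data** (`synthgen`): datasets drawn from any of the above models
under the recording protocol (1-ms steps, −90…350 mV in 10-mV increments,
500 kHz sampling, Ca²⁺ from ~0.8 nM to 100 µM).

## Worked example

Coupling energetics from the Boltzmann fits of the wild-type Q-V at the two
extreme Ca²⁺ conditions (V_H = 174.5 mV, z_Q = 0.60 at ~0 Ca²⁺;
V_H = 31.9 mV, z_Q = 0.66 at 100 µM):

```python
from bkgating import thermo
from bkgating.qv import BoltzmannParams

p0 = BoltzmannParams(vh=174.5, zq=0.60)
p100 = BoltzmannParams(vh=31.9, zq=0.66)
res = thermo.energetics_summary(p0, p100)
print(f"dVH  = {res.delta_vh:.1f} mV")
print(f"ddG  = {res.ddg_vca:.2f} kJ/mol")
print(f"E    = {res.coupling_E:.1f}")
print(f"e    = {thermo.per_event_factor(res.coupling_E):.2f}")
```

```
dVH  = -142.6 mV
ddG  = -8.07 kJ/mol
E    = 26.9
e    = 2.28
```

Saturating Ca²⁺ shifts the voltage-sensor equilibrium by −142.6 mV,
equivalent to −8.07 kJ/mol of stabilization of the active state; the R-A
equilibrium constant is amplified ~27-fold at saturation, i.e. ~2.3-fold per
binding event if the four sensors share the effect equally.

Model selection on a synthetic dose-response dataset generated under the
concerted scheme (z_J = 0.61, J₀ = 0.018, K_D = 6.1 µM, per-event factor
2.27, σ_q = 0.01):

```python
import numpy as np
from bkgating import fitsel, synthgen
from bkgating.camodels import AllostericModelSpec, SiteConfig

truth = AllostericModelSpec(scheme="II", sites=SiteConfig(kd=6.1), zj=0.61,
                            j0=0.018, e_factor=2.27**4, label="concerted/1-site")
c1 = AllostericModelSpec(scheme="I", sites=SiteConfig(kd=10.0), zj=0.6, j0=0.02,
                         e_factor=26.4, label="same-subunit/1-site")
c2 = AllostericModelSpec(scheme="II", sites=SiteConfig(kd=10.0), zj=0.6, j0=0.02,
                         e_factor=2.27**4, label="concerted/1-site")
proto = synthgen.ProtocolSpec(n_patches=1, sigma_q=0.01, sigma_vh=0.0, seed=7)
data = synthgen.generate_qv_dataset(truth, proto)
comparison, fits = fitsel.model_selection(data, [c1, c2], seed=0)
print(comparison.table.to_string(index=False))
```

```
              model          aic  delta_aic  rel_likelihood        weight
same-subunit/1-site -1505.086385  555.27723   2.648998e-121 2.648998e-121
   concerted/1-site -2060.363615    0.00000    1.000000e+00  1.000000e+00
```

The generating scheme is recovered decisively, with free-parameter estimates
(z_J = 0.608, J₀ = 0.0179, K_D = 6.0 µM) within 2% of the ground truth.

A command-line interface mirrors the workflow (`bkgating synth / extract /
fit-qv / fit-tau / fit-global / select / kinsim-scan / energetics`); see
`bkgating --help`.

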