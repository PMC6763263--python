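# Methods

## Scope and units

The package analyzes fast gating-charge movement of closed BK channels and
its modulation by intracellular Ca²⁺. All public interfaces use a single
unit convention: voltages in mV, time in ms (time constants reported in µs
where the experimental literature does), rates in ms⁻¹, Ca²⁺ in µM, energies
in kJ/mol, gating charge in units of e₀. Constants are fixed literals
(F = 96485 C/mol, R = 8.314 J mol⁻¹ K⁻¹) and the temperature defaults to
295 K (RT/F ≈ 25.4 mV), configurable per call.

## Signal analysis

ON-gating currents are modeled as a single exponential A·e^(−t/τ) over the
first 50–100 µs of the step (default window 100 µs, first 2 samples excluded
for amplifier settling; both configurable). The nonlinear fit is initialized
by log-linear regression of the positive samples and bounded to
τ ∈ [1 µs, 10 ms]. A fit is rejected — raising a diagnostic error rather
than returning garbage — when the window holds fewer than 25 samples, the
optimizer fails, τ sticks at a bound, or the fitted curve explains less than
20% of the signal variance (the pure-noise case).

The fast charge is the analytic area of the fitted exponential over
[0, ∞): Q_C = A·τ. Integrating the fit rather than the raw trace avoids
contamination by the slower charge components that follow channel opening.
Q-V families are normalized by the maximum of a free-scale Boltzmann fit,
not by the largest observed point, so normalization does not inherit
single-point noise.

## Boltzmann analysis and curve alignment

Q_C(V) at fixed Ca²⁺ follows Q_C,MAX/(1 + e^(−z_Q F(V−V_H)/RT)). Fits are
unweighted by default; 1/sem² weighting is available since pooled
experimental points carry SEMs (which convention the original analysis used
is not stated). Replicate curves are aligned by translating each along V by
⟨V_H⟩ − V_H, a pure shift that provably leaves z_Q unchanged; alignment
precedes pooling. Apparent (V_H, z_Q) of arbitrary model-generated curves
are obtained by the same single-Boltzmann reduction applied to data, which
is what makes model-predicted dose curves comparable with experimental ones.

## Two-state voltage-sensor kinetics

The VSD resting↔active transition has Eyring-type rates
α = α₀e^(z_J δFV/RT), β = β₀e^(z_J(δ−1)FV/RT); τ(V) = 1/(α+β) is bell-shaped
and J(V) = α/β. τ(V) data are fitted in log-residual space (τ spans orders
of magnitude over the protocol) with z_J fixed to the Q-V valence, from a
small grid of starts over δ and the rate scale. The fit does not enforce
J(V_H) = 1; the published rate and Q-V fits violate that identity mildly,
so consistency is left to the user as a diagnostic.

## Allosteric coupling models

Binding is assumed equilibrated before the pulse and frozen during the
~100 µs measurement (see the kinetic simulation below for the test of this
assumption). Subunit occupancy is therefore ligand-only: a single site binds
with probability x = Ca/(Ca+K_D); the two sites of one subunit carry weights
1 : Ca/K_D1 : Ca/K_D2 : G·Ca²/(K_D1 K_D2), with G an intrasubunit
cooperativity factor (G = 1 ⇒ independent sites). Channels are tetramers of
independent subunits; no intersubunit binding cooperativity is modeled.

**Scheme I (same-subunit coupling).** A bound subunit's own VSD equilibrium
is amplified: J → J·E_state with E_state the product of factors of its
occupied sites. Because total charge is the sum of four independent sensors,
the normalized charge is the per-subunit mixture
Σ_states P(state)·J E_state/(1+J E_state).

**Scheme II (concerted coupling).** Each bound Ca²⁺, anywhere in the
channel, multiplies all four J by the per-event factor e = E^(1/4), chosen
so that full occupancy reproduces the per-subunit saturating factor
(e⁴ = E). The charge is the mixture over channel-level bound counts,
Σ_k P(k)·J e^k/(1+J e^k) with P(k) binomial for one site per subunit and
the 4-fold convolution of the subunit distribution for two. With two sites,
G enters the occupancy weights only; the voltage-sensor factors are never
rescaled by it.

Both schemes coincide at Ca = 0 and at saturation, and both are validated
in the test suite against a brute-force oracle that enumerates every subunit
binding configuration of the tetramer and Boltzmann-averages the activated
fraction (agreement to 1e−12).

A quantitative caveat documented here because it is easy to over-read the
qualitative literature: the concerted scheme is only *approximately* a
single Boltzmann at intermediate Ca²⁺. Its five components are spaced
RT·ln(e)/(z_J F) ≈ 35 mV apart for e ≈ 2.27, so the single-Boltzmann
reduction of the mixture dips to about 89% of z_J near Ca = K_D (two-site
variants, with finer spacing, dip ~6%). The same-subunit scheme dips to
~65% of z_J under the same conditions. The scheme signature is therefore a
pronounced-versus-modest dip, not a dip-versus-none.

## Coupling energetics

ΔΔG_VCa = F(z_Q,Ca·V_H,Ca − z_Q,0·V_H,0) quantifies the Ca²⁺-induced change
in the R-A free energy, and E = e^(−ΔΔG_VCa/RT) the amplification of J at
saturation. E used as a fixed constraint in global fits is accepted as an
independent input rather than recomputed from a single ΔΔG value, because
experimentally it is averaged across patches and the two routes differ at
the percent level.

## Global fitting and model selection

Candidate models are fitted to the full (V, Ca) dataset with coupling
factors fixed; free parameters are z_J, J₀ and the K_D(s) (G optionally).
Scale parameters are log-parameterized, bounds are wide, and the bounded
least-squares fit is repeated from 5 seeded starts (the K_D/G landscape has
local minima), keeping the best residual; ties resolve to the first start.
The maximized log-likelihood uses the concentrated Gaussian form
ln L = −(n/2)(ln(2π·RSS/n) + 1), the standard bridge from least squares to
AIC when the noise model is unspecified; consequently absolute AIC values
depend on this convention and only AIC differences, relative likelihoods
ℒ_i = e^(−ΔAIC_i/2) and Akaike weights are meaningful across studies.
Free-parameter counts: 3 (one site), 4 (two sites), 5 (two sites with G
free); fixed factors are never counted. K_D estimates are reported as found
and never clipped to literature ranges.

## Kinetic simulation of Ca²⁺ re-equilibration

A subunit is a 4-state chain {R·unbound, A·unbound, R·bound, A·bound}.
VSD rates come from the two-state model; in the bound state the full
allosteric factor is applied to the backward rate by default
(β → β/E, matching the kinetic observation that Ca²⁺ mainly slows sensor
return), with the allocation exposed as a parameter. Binding uses
k_on = 1.8×10⁸ M⁻¹s⁻¹ and k_off = k_on·K_D; microscopic reversibility then
forces the active-state site to bind E-fold tighter (A-side dissociation
k_off/E), and the generator asserts cycle closure at build time. Scheme I
subunits are independent, so channel-level charge needs no 4⁴-state
simulation. Propagation uses the matrix exponential of the 4×4 generator on
the 2-µs sampling grid; the ensemble gating current is z_J·d⟨P(A)⟩/dt
evaluated exactly from the generator.

The binding-speed scan scales k_on and k_off together (preserving K_D),
simulates the full protocol from the −90 mV holding equilibrium, and pushes
every trace through the identical measurement pipeline. One subtlety: the
measured charge is referenced to the holding equilibrium, and at Ca ≈ K_D a
non-negligible fraction of sensors is already active at −90 mV; even an
exactly single-Boltzmann sensor measured this way reads an apparent valence
a few percent above z_J. Scan results are therefore interpreted against the
pipeline-consistent single-Boltzmann reference (the large-multiplier
asymptote of the same scan), not against bare z_J. With the reported k_on,
binding relaxes with τ ≈ 250 µs at Ca = K_D — slower than both the fit
window and the sensor (τ ≈ 60 µs near V_H) — so apparent z_Q stays near the
frozen-occupancy value; it approaches the concerted-like single-Boltzmann
reading only when binding is made ≳100-fold faster.

## Synthetic data

The generator emulates the recording design: 45 voltages (−90…350 mV,
10-mV steps), 1-ms pulses at 500 kHz, Ca²⁺ ∈ {0.0008, 0.1, 0.5, 1, 5, 10,
100} µM, where 0.8 nM stands in for the nominally Ca²⁺-free chelated
solution (model curves are continuous at Ca → 0, so the distinction is
cosmetic but kept for fidelity). Q-V noise is Gaussian per point with
σ_q = 0.015 by default — a repo convention chosen to resemble the scale of
published error bars, not a measured value — plus a per-patch voltage-axis
jitter of 5 mV SD (unreported experimentally; configurable) that exercises
the alignment step. Trace noise is additive Gaussian with SD equal to a
fraction (default 0.05) of each trace's peak amplitude, i.e. constant
per-trace SNR. τ datasets carry multiplicative lognormal noise. All
randomness flows through one explicitly passed seeded generator; identical
seeds reproduce datasets bit-for-bit.

What the synthetic data do **not** emulate: leak and capacitive artifacts,
P/4 subtraction residues, series-resistance and filtering distortions,
voltage-dependent noise, OFF-gating currents, and any slow charge component
from channel opening. Passing round-trip tests therefore demonstrates the
correctness and statistical behavior of the analysis chain under its own
assumptions, not robustness to every artifact of real recordings.

## Problem sizes in the test suite

Statistical tests use sizes chosen to make their conclusions stable at
fixed seeds: 200 replicates for estimator-bias and SEM-scaling checks,
20 replicates for parameter recovery (median error < 10%), 50 replicates
per generating scheme for selection consistency, and 5–6 multipliers for
the binding-speed scan. The full suite runs in well under a minute except
for the replicated fitting studies, which take a few seconds each.

## Known limitations

* The channel-opening layer of the full allosteric gating model (C–O
  equilibrium L and its couplings) is out of scope; only closed-state
  charge movement is modeled.
* Scheme II kinetics are not simulated (the channel-level chain has
  5×2⁴ states); the simulation argument only requires Scheme I kinetics
  plus the frozen-occupancy equilibria.
* OFF-gating analysis and multi-exponential decompositions are not
  implemented.
* AIC absolute values depend on the Gaussian-likelihood convention above;
  published absolute AICs from other pipelines are not directly
  reproducible, only the comparison machinery is.
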