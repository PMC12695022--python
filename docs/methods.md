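# Methods

## The two-step binding model

The package models receptor–peptide recognition as

```
free + L  ⇌  dock  ⇌  lock
      (K_D^D, k_off^D)   (K_D^L = [dock]/[lock], k_ex^L = k_on^L + k_off^L)
```

The dock step is an ordinary bimolecular association into a partially formed
pocket; the lock step is a unimolecular folding of the receptor around the bound
ligand. K_D^L is defined as the dock/lock concentration ratio at equilibrium, so
small K_D^L means the locked complex dominates. When the lock exchange is fast on
the chemical-shift timescale the two bound states average, and titrations report
effective two-state constants K'_D = K_D^D·K_D^L/(K_D^L+1) and
k'_off = k_off^D·K_D^L/(K_D^L+1): the lock step depletes the sub-population from
which the ligand can dissociate, scaling both constants by the dock fraction of
the bound pool. Both relations share one scale factor, so k'_off/K'_D =
k_off^D/K_D^D exactly — the effective on-rate cannot exceed the dock on-rate
(k'_on ≤ k_on^D), which the package treats strictly as a *consistency check*,
never as a fitting constraint; an apparent violation is diagnostic of an
unreliable slow-exchange rate estimate.

Inversion: given K'_D from the full-length construct and K_D^D from a truncation
that cannot lock, K_D^L = r/(1−r) with r = K'_D/K_D^D (exact) or ≈ r when
K_D^L ≪ 1 (the small-K_L limit). Both the affinity route and the independent
off-rate route (k'_off/k_off^D) are computed and reported side by side rather
than averaged; their spread is the model's internal-consistency margin. The
dock-state population of the bound pool is r itself. A lower bound on the lock
exchange rate comes from the absence of exchange broadening at saturation:
k_ex^L must greatly exceed the largest free/bound shift difference (in s⁻¹ ≡ Hz).

Error propagation is Monte Carlo: independent Gaussian draws per input,
truncated to the physical domain by rejection resampling, with the median and
central-68% half-width reported. A first-order Taylor expansion was rejected
because r/(1−r) is strongly non-linear as r → 1 (weak lock contribution).

## Equilibria

The 1:1 bound fraction uses the exact depletion quadratic. The symmetric dimer
binds sequentially, D + L ⇌ DL ⇌ DL₂, with macroscopic constants K₁ = K/2 and
K₂ = 2αK built from a single microscopic site constant K and a cooperativity
factor α (α > 1 = negative cooperativity); the free-ligand root is bracketed and
solved by Brent's method, conserving both masses to <1e−8. Kinetically the
cooperativity is placed on the second-site *dissociation* (k_off,2 = α·k_off)
with a shared per-site on-rate, keeping on-rates diffusion-like. ΔG uses
R = 8.314 J mol⁻¹ K⁻¹ and T = 298.15 K; 298 vs 298.15 K changes ΔG by less than
the printed precision of any tabulated value, so the choice is not resolvable
from the data and is simply fixed.

## Lineshapes

1D absorption spectra are Re[1ᵀ(iω − L)⁻¹p] with L = i·2π·diag(ν) − diag(R₂) + K,
K the exchange generator satisfying detailed balance against the populations.
This is validated in the tests against an independent route — matrix-exponential
time propagation of the same generator followed by numerical Fourier quadrature —
to <1e−6. 2D HSQC peaks are treated as outer products of per-dimension 1D
lineshapes and all fitting operates on stacked 1D cross-sections; this discards
cross-correlated 2D information but retains the exchange content of a titration
at a fraction of the cost, and is stated as an approximation. ppm↔Hz conversion
uses the spectrometer ¹H frequency with the ¹⁵N frequency at 0.10136900 of it;
600 and 800 MHz presets.

The titration fitter runs three phases mirroring standard practice: endpoint
Lorentzian fits for free-state shifts and linewidths; per-residue exchange fits;
then a global fit sharing K_D and k_off (and α for the dimer model) across
residues, multi-started from a coarse log-grid. Scale and baseline are profiled
out analytically per cross-section (two nuisance parameters). Free-ligand pools
are recomputed exactly at every titration point — the pseudo-first-order
approximation is wrong by construction when ligand and protein are comparable.
Exchange-regime labels (slow if k_ex < Δω/5, fast if k_ex > 5Δω) are for
reporting only. Parameter uncertainties are Gauss–Newton covariances on
log-parameters.

The explicit three-state network is used to verify the effective-two-state
reduction numerically: with the lock exchange ≥100× faster than both Δω and
k_off^D, the three-state and reduced lineshapes agree to <2% pointwise across a
titration; at lock rates comparable to Δω they visibly diverge, which is the
regime where the reduction must not be used.

## CEST

Profiles propagate the full 6-dimensional magnetization (x, y, z per state)
under offset precession, B1 nutation, R1/R2 relaxation and exchange via a matrix
exponential (batched eigendecomposition, validated against fine-step ODE
integration to <1e−6). Both states start on +z with equilibrium weights and
profiles are normalized to a zero-irradiation reference, so the far-off-resonance
plateau is exp(−R1·t_ex). R1 is shared between states and R2 differs — the
standard identifiability compromise at a 2–3% minor population. The bound
population is *fitted* within [1e−4, 0.2] rather than fixed from the mixing
ratio, since the ratio alone does not pin it when K_D is not negligible.

The global fitter shares k_off and p_bound across residues and B1 fields;
per-residue Δω is initialised by a coarse 1D scan (dips from small shift
differences hide under the main dip, where a position heuristic fails). The
slow-exchange diagnostic fires when no secondary dip rises above 3× the noise,
or when the fitted rate's relative uncertainty exceeds 25% — at k_off ≈ 15 s⁻¹
too little saturation transfers during a 400 ms period for the rate to be
determined, and reporting a number there would be a silent bias.

## ITC

Injections follow the perfusion displacement convention: every total
concentration scales by V₀/(V₀+dV) per injection, injected ligand enters as
L_syr·dV/(V₀+dV), and differential heats carry the trapezoidal correction
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2 for heat displaced with the overflow.
Alternative dilution conventions differ by <1% at 1.5 µL into 200 µL. The cell
working volume is fixed at 200 µL (instrument-class constant). Stoichiometry N
is fitted per replicate, not fixed; replicates are fitted independently and
reported as mean ± SD. The first injection is discarded by default (standard
syringe-diffusion practice). Fits outside Wiseman c = N·[cell]/K_D ∈ [1, 1000]
are returned with a warning — the isotherm shape no longer determines K_D there.
ΔG and −TΔS are derived identities, never free parameters.

## CSP

Combined perturbations use Δδ = sqrt(Δδ_H² + (0.14·Δδ_N)²); the 0.14 ¹⁵N weight
is the common amide convention and is the principal dialect decision of the
module. Per-residue fits of Δδ_max·f_b(P, L, K_D) use the depletion-exact bound
fraction; the summary K_D is the mean ± SD over the top-10 residues by Δδ_max.
Residues whose 2D trajectory bends by >15% of its chord are excluded as not in
fast exchange. When the final point saturates <50% of the protein the estimate
is flagged as a lower bound — unavoidable for a ~10 mM binder at 100-fold ligand
excess.

## Synthetic data

The generators emulate the study conditions: 8-point titrations at 50 µM protein
(ligand schedules matched to each affinity regime), CEST at B1 = 12.5/25/50 Hz
with 400 ms irradiation and 2.5% bound population at 800 MHz, and ITC with
25 × 1.5 µL injections from 20–40 µM cell / 200–600 µM syringe at 25 °C in
triplicate. Residue panels draw free shifts from the amide envelope (¹H 7.0–9.5,
¹⁵N 105–130 ppm), bound-state changes capped at |Δω| ≤ 2000 Hz at the stated
field, R2 ∈ [10, 30] and R1 ∈ [1, 2] s⁻¹. The CEST offset sweep is widened (at
constant sampling density, 60 points per 12 ppm) when a panel's dips fall
outside the ±6 ppm default window. Noise is independent Gaussian — 1% of the
maximum signal for NMR observables, 2% of the largest |heat| for ITC — matching
the least-squares assumptions of every fitter; heteroscedastic and correlated
noise, peak overlap, baseline drift and phase errors of real spectra are *not*
emulated, so recovery tests demonstrate estimator correctness and identifiability
under the stated designs, not robustness to real-data artefacts. Generation is
bit-reproducible from (fixture, seed) and each dataset carries a manifest with
the fixture hash.

Default problem sizes (3–12 residues per panel, 140-point cross-sections,
8 titration points) were chosen so a full recovery battery runs in minutes on a
laptop while each fit remains comfortably over-determined.

## Known limitations

* The 2D→1D cross-section treatment ignores differential relaxation between
  dimensions within a peak.
* The dimer lineshape model fixes the asymmetric-environment shifts (F′/B′) to
  the symmetric ones unless supplied; fitting them freely is supported but
  poorly identified in noisy data.
* No raw-data processing (FID handling, peak picking, power-trace integration):
  inputs are peak lists, cross-sections, normalized CEST ratios and integrated
  heats.
* k_on^L and k_off^L are never fitted individually — only their sum is bounded
  from below and their ratio inferred; this mirrors what the data can support.
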