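# Methods

`cdbind` analyses the binding of a small guest molecule (here the polyphenolic
antioxidant DHTH) to β-cyclodextrin (β-CD) from two classical solution
experiments: a continuous-variation ¹H NMR series and an isothermal titration
calorimetry (ITC) experiment. This note records the models, the numerical
choices, and the limits of what the synthetic-data tests demonstrate.

## 1:1 equilibrium and fast-exchange shifts

For host H + guest G ⇌ HG with association constant K (L/mol) and totals
A (guest) and B (host), mass action gives the exact complex concentration

    [HG] = ½ [ (A + B + 1/K) − √((A + B + 1/K)² − 4AB) ].

We evaluate the root in the conjugate form 2AB / (S + √(S² − 4AB)),
S = A + B + 1/K, which is stable when 4AB ≪ S² (weak binding or dilution);
the naive subtraction loses up to ten digits there. K = 0 and A·B = 0 return
[HG] = 0 by continuity. A property test checks the closed form against
bisection root-finding of K(A−x)(B−x) = x to < 10⁻¹² M over random
(A, B, K) grids.

Under fast exchange a traced proton shows a single population-averaged peak.
Its perturbation relative to the free component is

    Δδ(i, j) = Δδc(j) · [HG]_i / X_i ,      Δδ = δ_free − δ_obs,

where X is the total concentration of the proton's own molecule (A for guest
protons, B for host protons) and Δδc(j) is the signed limiting shift of the
pure complex. No assumption is made about the sign of Δδc; upfield/downfield
interpretation is left to the caller.

## Continuous variation (Job plot)

The design holds C = A + B fixed (default 4 mM, the study condition) and
sweeps the interior mole ratios r_i = i/(n+1), i = 1..n (default n = 11);
the pure components at r = 0, 1 are the reference spectra, not mixtures. The
Job response Δδ·[X] equals Δδc·[HG], so for 1:1 binding it peaks at r = 0.5
for every K. The peak is located by a parabola through the discrete maximum
of |y| and its two neighbours (ties resolve to the smallest r); a peak within
0.05 of r = 0.5 (configurable) is classified 1:1.

K is fitted globally over all protons by variable projection: given K, the
model is linear in each Δδc(j), which is solved exactly per proton; the
profiled sum of squares is minimized over log₁₀K ∈ [−2, 8] by bounded Brent
search (absolute tolerance 10⁻¹⁰ on log₁₀K). This is derivative-free,
monotone in the best objective found, and reproduces any least-squares
-consistent result. The reported correlation factor R is the Pearson
correlation between observed and fitted Δδ pooled over all (i, j) — a single
scalar for the multi-proton fit. Uncertainty on K is available as a
nonparametric bootstrap over records (default 500 resamples, seeded).

**Identifiability caveat.** A constant-total design pins the stoichiometry
but carries little information about K when saturation is low: the
weak-binding expansion [HG] ≈ K·A·B·(1 − K·C + …) has its leading
K-dependence through the sample-independent factor (1 − K·C), which the
fitted Δδc absorb. At the study conditions (K ≈ 82 L/mol, C = 4 mM, so
K·C ≈ 0.33) the profile curvature implies a Cramér–Rao standard deviation of
about 1.4 decades in log₁₀K at 0.001 ppm shift noise: single-replicate K
estimates from such a series are essentially unconstrained, even though the
noiseless fit recovers K exactly and the replicate distribution brackets the
truth. The package reports this honestly rather than hiding it; precise K
determination needs a dilution or titration series that varies C.

## Independent-sites ITC

Injecting guest (syringe concentration X_syr) into host (cell concentration
M₀, active volume V₀, default 1.0 mL) with an overfilled perfusion cell, the
displacement-corrected totals after cumulative injected volume dV are

    M = M₀ (1 − dV/2V₀) / (1 + dV/2V₀),
    X = X_syr (dV/V₀) / (1 + dV/2V₀).

With an effective site concentration n·M the 1:1 solver yields the bound
concentration HG_k after injection k; the cell heat content is
Q_k = ΔH·V₀·HG_k and the measured heat of injection k includes the expelled
-heat term

    q_k = Q_k − Q_{k−1} + (dv_k/V₀)(Q_k + Q_{k−1})/2 .

A closed-cell variant (`displacement=False`) omits expulsion, making
Σq_k = ΔH·V₀·HG_final exact — used as a conservation oracle in the tests.
Heats are stored in calories (exothermic negative); CSV I/O accepts µcal and
µJ. A control titration (titrant into solvent) can be subtracted
injection-wise. An optional `discard_first` flag drops injection 1
(diffusion-artifact practice); off by default.

Fitting again uses variable projection — the model is linear in ΔH — with a
Nelder-Mead outer search over (log₁₀K, ln n) seeded from a coarse grid, or a
1-D bounded search when n is fixed. The Wiseman parameter c = n·K·M₀ is
always reported: outside [0.01, 10⁴] the isotherm carries essentially no
information on K; outside the classic reliable window [1, 1000] the fit
proceeds but a correlation warning is attached. The study design sits at
c ≈ 0.82, so noiseless round-trips recover (K, n, ΔH) to machine-level
accuracy while noisy replicates show a wide (but truth-bracketing) spread in
K; ΔH is median-unbiased when n is held at the NMR-determined stoichiometry
(relative error of the median ≈ 3% at 0.5 µcal noise over 100 replicates).

## Thermodynamic linkage

ΔG = −RT ln K (R = 1.98720425 cal mol⁻¹ K⁻¹) and ΔS = (ΔH − ΔG)/T, with a
consistency checker verifying both identities on any result to a default
tolerance of 0.01 kcal/mol — wide enough to absorb the 298 vs 298.15 K
rounding ambiguity in published values without guessing the authors'
convention.

## Synthetic data

The generators emulate the two study designs with known ground truth:
observed shifts δ_obs = δ_free − Δδ_model + ε (ε Gaussian, default
σ = 0.001 ppm, the order of digital resolution of a 500 MHz spectrometer)
over the 11-mixture series, and thermogram heats with Gaussian noise
(default σ = 0.5 µcal, typical for a modern nano-calorimeter baseline).
Ground-truth parameters default to the study's fitted values (K = 81.97
L/mol for NMR; K = 1096 L/mol, n = 1, ΔH = −1013 cal/mol for ITC). Free
shifts for the guest protons are the assigned free-state spectrum; the host
H3/H5 values (3.94/3.84 ppm) are typical β-CD shifts in D₂O. The limiting
shifts Δδc are not published; defaults (host +0.055/+0.075 ppm, guest
−0.024 to −0.041 ppm) are order-of-magnitude-plausible for β-CD inclusion
and are explicit configuration, never silent assumptions.

What the generators do **not** emulate: peak overlap and lineshape,
baseline/phase errors, heteroscedastic integration noise, dilution heats
beyond a flat control, and any slow-exchange behaviour. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every instrumental artifact.

## Problem sizes and determinism

All simulations are seconds-scale: 11 × 5 shift records, 25 injections,
200/100 noisy replicates in the robustness studies, 10⁴ random triples in
the equilibrium property test. Every stochastic path takes an explicit seed
(`numpy.random.default_rng`), making tables and thermograms byte-identical
across runs.

## Known limitations

- Only 1:1 (single-set-of-sites) models; no 1:2/2:1 stoichiometries,
  sequential sites, or kinetic deconvolution of raw power traces.
- The Job-plot K fit is ill-conditioned by design (above); the package
  quantifies but cannot remove this.
- Instrument file formats are out of scope; I/O is plain CSV/JSON.
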