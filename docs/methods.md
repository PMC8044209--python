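# Methods

This note documents the models implemented in `fuzzyfit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.  Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Chemical-shift perturbations and titrations

The combined amide CSP is Δδ_NH = √(Δδ_H² + (Δδ_N/5)²); components are
signed (free − bound) in ppm, and the 1/5 factor compensates the larger ¹⁵N
shift range.  All stored shifts are unscaled; scaling exists only inside the
CSP computation and inside the titration-tracking metric.  The Cα/Cβ CSP is
Δδ_CaCb = 0.25 × [(Cα−Cβ)_free − (Cα−Cβ)_bound]; the signed value is kept
and its magnitude reported as the CSP.

Fast-exchange titrations are tracked geometrically: assignments are taken
from the first (free) spectrum only and peaks at later points are linked by
nearest-neighbour matching in (¹H, X/5) ppm space with a per-step jump
ceiling (default 0.05 scaled ppm, configurable).  A step with no candidate
inside the ceiling marks the peak `unmatched`; two candidates inside the
ceiling mark it `ambiguous` — the tracker never guesses.  ¹³C trajectories
use the same /5 scaling, for matching only.

### Binding models

Fluorescence-polarization titrations are fitted to the one-site total model
Y = B_max·X/(K_d + X) + NS·X + Background by nonlinear least squares
(lmfit), with initial values K_d = median(X), B_max = max(Y) − min(Y),
NS = 0, Background = min(Y); a negative K_d optimum triggers a
log-parameterized refit.  Standard errors come from the fit covariance.

Fraction saturation of the labeled species uses the exact quadratic root

    C = A + B + K_d,   [AB] = (C − √(C² − 4AB)) / 2,   sat = [AB] / A.

This is the only root with 0 ≤ [AB] ≤ min(A, B); the alternative "+" root
exceeds the total concentrations.  In the dilute-label limit (A ≪ K_d) the
expression reduces to the hyperbola B/(B + K_d), which the suite checks to
0.1% at A = K_d/1000.

NMR-titration K_d estimation is a deliberate extension (the experimental
protocol behind "estimates from NMR titrations" is generally left unstated
in studies of this kind): per-residue CSP trajectories are fitted globally
to CSP_i(L) = CSPmax_i · sat(A, L, K_d) with a shared K_d.  Residues enter
the fit only if their endpoint CSP exceeds 3× a noise estimate taken as the
median second-difference roughness of the tracked trajectories (floored at
10⁻⁴ ppm); the threshold is overridable.

## Relaxation

T₁/T₂ intensities are fitted per residue to I(t) = I₀·e^(−t/T) with no
baseline offset (two parameters), standard errors from the covariance.
Residues with non-positive or absurdly long fitted T (no measurable decay)
or failed fits are flagged and excluded from the T₁/T₂ ratio profile, as are
residues with relative stderr above 50% (configurable plot hygiene).  Ratio
errors use first-order propagation σ_r = r·√((σ₁/T₁)² + (σ₂/T₂)²).  Under
fast exchange a lower bound k_ex ≥ k gives the bound-lifetime upper bound
1000/k ms; only this reciprocal conversion is implemented — no exchange-rate
estimation from lineshapes is attempted.

Default delay ladders (`T1_DELAYS_MS`, `T2_DELAYS_MS`) are the 8-point
interleaved sets commonly used for disordered activation domains
(10–1000 ms and 8.48–67.84 ms); T₂ delays are total CPMG evolution times,
with no loop-count arithmetic.

## Secondary-structure propensity

SSP is Δδ(Cα−Cβ) = (Cα−Cβ)_measured − (Cα−Cβ)_random-coil, unsmoothed
(an optional 3-residue running mean exists, off by default).  Positive
values indicate helix; ≈ +4 ppm corresponds to fully formed helix, and the
annotation `helical_fraction` = delta/4 (clipped to [−1, 1]) uses that
scale.  Random-coil Cα/Cβ references come from a packaged table of standard
consensus values plus an approximate nearest-neighbour correction table
(following-proline ≈ −2 ppm on Cα, small glycine/aromatic terms); terminal
residues use truncated context.  The packaged set is versioned in
`src/fuzzyfit/data/` and is *not* a reproduction of any particular
webserver's coefficients — for publication-grade SSP of real data, swap in
the laboratory's preferred coefficient set; the arithmetic is unchanged.

## PRE profiles

The per-residue observable is ratio = I_para/I_dia with error
σ_ratio = ratio·√((σ_para/I_para)² + (σ_dia/I_dia)²) from the two spectra's
noise levels.  The restraint form is the pseudo-rate
R₂\* = 1/I_para − 1/I_dia, computed on intensities normalized by the median
diamagnetic intensity so the rate is scale-free (`raw=True` gives the
literal formula).  Peaks with I_para below 3× the spectral noise are
*bleached*: the ratio is computed from the noise floor (I_para := 3σ) and
flagged — this avoids infinities while preserving the "strong PRE" rank,
and bleached residues later contribute one-sided restraint energy.
Saturation of the sample is carried as metadata and never used to correct
ratios.  Quartile classes rank residues by increasing ratio (most affected
first): the lowest n//4 are `top25`, the next n//4 `next25`, ties broken by
residue index.

## PRE forward model and ensemble fitting

The forward model is the transverse Solomon–Bloembergen rate of a nitroxide:

    Γ₂ = k · (4τ_c + 3τ_c/(1 + ω_H²τ_c²)) · ⟨r⁻⁶⟩
    I_para/I_dia = R₂dia · e^(−Γ₂·t) / (R₂dia + Γ₂)

with equal-weight ⟨r⁻⁶⟩ over ensemble members.  Defaults:
k = 1.23×10¹⁶ Å⁶·s⁻² (nitroxide–¹H dipolar constant), τ_c = 8 ns,
ω_H/2π = 500 MHz, t = 10 ms, R₂dia = 20 s⁻¹.  Synthetic data are generated
and fitted with the same constants, so the ensemble-size conclusions do not
depend on their absolute values.  The nitroxide is placed 6 Å beyond Cβ
along Cα→Cβ (rigid single-conformer approximation; for glycine, along the
backbone-midpoint→Cα axis).  Amide positions are approximated by the
backbone N coordinate.  Bound-state ratios are mixed with the free state by
linear population averaging, ratio_obs = sat·ratio_bound + (1 − sat),
appropriate for exchange fast on the PRE timescale.

**Simplification, stated prominently:** the original refinement protocol for
such systems is torsion-angle simulated annealing with NOE, dihedral and PRE
restraints on full atomic models.  `fuzzyfit` substitutes rigid-body
ensemble fitting of an idealized helical ligand against PRE restraints only,
plus a soft-sphere clash term.  This preserves the inferential logic — the
ensemble-size model comparison — at desk scale; it does not produce
publication-quality coordinates.

The restraint energy is Σ((R₂\*_pred − R₂\*_obs)/σ)² over matched residues,
with σ the observed ratio error propagated to the rate scale (floored at
10⁻¹²).  Bleached residues penalize under-prediction only.  The clash term
is Σ w·(d₀ − d)² over ligand–partner CA/CB pairs closer than d₀ = 2.5 Å
(w = 10).  Total energy is the unit-weighted sum.

Optimization is seeded Metropolis annealing over per-member rotations
(≤ 20° at the start) and translations (≤ 2.5 Å), decaying to 10% of the
initial amplitude over a geometric temperature ladder from
T₀ = 0.05 × E_init down to 10⁻³ T₀, with a 10% chance per step of
re-seeding one member at a fresh random surface placement (an escape move),
followed by a greedy quench.  Defaults of 1500 annealing + 400 quench steps
were set by checking that multi-state fits reach the energy of the true
generating poses on synthetic data (≈ 0.4 s per fit on one core).
Determinism: a fixed (seed, config) pair always returns the same ensemble.

### Size scan and model selection

For each size in 1–6 the scan runs `starting_models` independent seeded
initial placements × `replicates` re-annealed fits (13 × 10 = 130 fitted
structures per size at the full protocol; the scaled-down default used in
the tests is 4 × 10).  Summaries per size are box-plot statistics of total
and PRE energies and of the ten lowest-PRE-energy structures: quartile box
(linear-interpolation quantiles), median, whiskers at the most extreme
values within 1.5×IQR of the box, and outliers counted outside
median ± 1.5×IQR (the box-edge rule for whiskers and the median rule for
outliers are both implemented exactly as conventionally printed, although
they differ).

*Adequacy* — "the ensemble recapitulates the PRE data" — is operationalized
as median PRE energy of the ten lowest-PRE-energy structures ≤ 2 × the
number of restraints, i.e. reduced χ² ≤ 2; the ten-lowest population is used
because replicate annealing produces a tail of unconverged runs that says
nothing about the model class.  *Plateau* is the smallest size whose median
improves by < 10% upon adding one more member.  Both factors are
configurable; no numeric criterion is canonical, and the conclusions
(single state fails, two or more suffice, no gain past four) are robust to
the factor of 2.

## Synthetic data: what it emulates, and what it does not

`make_toy_complex` builds an idealized three-helix bundle partner
(default 60 residues) standing in for a compact activator-binding domain
with a surface groove, and a 12-residue ideal-helix ligand.  True bound
poses are placed on the partner surface (4–16 Å minimum-atom distance,
mutual centroid separation ≥ 8 Å), deterministically per seed.  The default
study design mirrors a three-site spin-label experiment: label sites at
ligand residues 2, 6 and 11 (flanking and central), per-site saturations
(0.9, 0.7, 0.5), 5% intensity noise, ~60 observable partner amides.
Diamagnetic intensities are drawn about a common scale with Gaussian
spectral noise; paramagnetic intensities are I_dia × the saturation-mixed
true ratio plus independent noise.

Titrations are population-weighted fast-exchange averages with quadratic
fraction bound and Gaussian ppm noise (¹⁵N noise ×5); decays and FP curves
are their models plus noise.  Every generator, fed back to its analysis
counterpart at zero noise, recovers the generating parameters — the suite
enforces this round-trip property.

Not emulated: lineshapes and peak overlap in frequency space, relaxation
interference, field/temperature dependence, flexible-linker label dynamics,
and — important for interpretation — the *extensive* orientational averaging
of a real fuzzy complex.  Two consequences, verified and documented here
because they bound what passing tests show about real data:

1. **Cross-label correlation.** In real fuzzy complexes, labels a dozen
   residues apart give nearly identical PRE profiles because the ligand
   samples many orientations.  A rigid 3-state toy cannot reproduce that
   near-identity: the closest label tips on the 12-mer sit ~9 Å apart and
   their r⁻⁶ fields partially decorrelate (observed Pearson r ≈ 0.3–0.8
   across seeds).  The suite therefore asserts near-identity (r > 0.9) for
   one truth measured twice with independent noise, and strong-but-partial
   correlation (r > 0.5) between flanking labels.
2. **Positional degeneracy.** Ensemble PRE fitting is underdetermined:
   distinct member configurations reach the ground-truth χ² at 5% noise
   while sitting 10–17 Å from the true label positions (one member's strong
   PRE dominates the ⟨r⁻⁶⟩ average and the other drifts).  Member
   coordinates are therefore *not* validated against truth; what is
   validated is that fits recapitulate the data (energy at the adequacy
   level) and reproduce the truth's PRE pattern (profile correlation
   r > 0.95).  This degeneracy is precisely why ensemble-*size* comparison,
   not structure determination, is the fuzziness test.

## Numerical conventions and degenerate inputs

Residue numbering is construct numbering, 1-based, preserved end to end;
prolines/unassigned residues are absent rows and all fits skip absent
residues.  Quantiles use linear interpolation.  Distances below 1 Å in the
forward model are clamped (and flagged sterically impossible); predicted
ratios underflowing to zero are floored at 10⁻¹⁶ before the R₂\* transform.
Peak lists reject duplicate (residue, atom-pair) entries and non-finite
shifts; glycine Cβ rows are rejected at parse time.  All random streams are
`numpy` Generators seeded from explicit integers; scan sub-seeds derive from
`SeedSequence(entropy=seed, spawn_key=(size, starting_model, replicate))`
and stay below 2³¹.

## Problem sizes used in the shipped tests

The scans exercised by the suite use the 60-residue toy partner, three label
sites (180 restraints), sizes 1–6 with 4 starting models × 10 replicates
(240 fits, ~2 minutes single-core); the structure-count bookkeeping check
runs 13 × 10 at a minimal annealing budget.  These sizes were chosen as the
smallest designs in which the single-state/multi-state separation is
unambiguous (the 1-state ten-lowest median sits ~20% above the adequacy
threshold, multi-state medians ~35–45% below it).

## Known limitations

* Rigid-body, equal-weight ensembles; no weight optimization (deliberate,
  to match the standard ensemble-refinement convention) and no internal
  ligand flexibility.
* The toy geometry is idealized (pseudo-backbone helices); clash handling is
  a soft-sphere CA/CB term, not a force field.
* The random-coil coefficient set is an approximate packaged table (see
  above).
* Exchange-rate estimation, NOE handling, CPMG dispersion and model-free
  dynamics are out of scope.
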