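# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `switchfret`, in the order the pipeline runs.

## The generative picture

A doubly labeled molecule diffusing through a confocal volume emits a
burst of photons while a hidden conformational process switches it
between K FRET states.  We model the conformational process as a
continuous-time Markov chain with rate matrix Q (s⁻¹; off-diagonals
non-negative, rows summing to zero) and per-state apparent FRET
efficiencies E_i.  For the ClpB M domain the default preset
(`wt_mdomain_model`) is the three-state sequential chain

- state 1 (active): E = 0.80, state 2 (inactive): E = 0.47, state 3
  (minor): E = 0.15;
- k₁₂ = 5300, k₂₁ = 5700, k₂₃ = 800, k₃₂ = 2300 s⁻¹ (no direct 1↔3
  exchange),

whose stationary occupancies are π = (0.444, 0.413, 0.143).  The 1↔2
relaxation time, 1/(k₁₂+k₂₁) ≈ 91 µs, is far shorter than a ~1 ms burst,
which is why burst histograms of such systems show one broad
time-averaged peak rather than separate state peaks.

## Synthetic photon streams

`synthetic_data.simulate_photon_stream` emulates a pulsed-interleaved
excitation (PIE) measurement at a 40 MHz laser repetition rate with a 3:1
donor:acceptor pulse ratio.  Design choices:

- **Burst envelope.**  Rectangular bursts with exponentially distributed
  durations (default mean 1 ms) separated by exponential gaps (default
  mean 5 ms), rather than explicit 3-D diffusion through a Gaussian
  focus.  This reproduces the burst-size and interphoton statistics every
  downstream stage depends on at a fraction of the cost; a diffusive
  envelope would add brightness variation within bursts but not change
  any quantity tested here.
- **Clock.**  64-bit integer timestamps in units of the laser repetition
  period (25 ns).  Each photon is snapped to a pulse slot consistent with
  its excitation label (slots 0–2 of each 4-pulse frame are donor
  pulses, slot 3 the acceptor pulse).
- **Emission model.**  In-burst photons arrive at `in_burst_photon_rate`
  (default 190,000 s⁻¹) split between FRET-pathway photons in donor slots
  (fraction 3/4) and acceptor-excitation photons (fraction 1/4 times
  `aa_brightness`).  A FRET-pathway photon is acceptor-detected with
  probability E of the current state; otherwise it is donor-detected and
  reclassified into the acceptor channel with probability `leakage`.
  Direct excitation adds acceptor photons in donor slots at
  `direct_excitation` times the acceptor-excitation rate, so the expected
  direct count is d·n_AA — matching the correction model below, which
  makes estimate→apply an exact round trip.
- **`aa_brightness` (default 4).**  At equal per-pulse brightness an
  acceptor-only molecule emits only ~47,500 photons/s (mean gap 21 µs),
  which never crosses the 10 µs burst-search cutoff: the population the
  direct-excitation estimator needs would be invisible.  Real PIE
  instruments balance the red laser so that acceptor-only molecules give
  strong bursts; `aa_brightness=4` reproduces that and puts doubly
  labeled molecules mid-range in stoichiometry (S̄ ≈ 0.43).  Setting it
  to 1 recovers the strict equal-brightness stream in which photon counts
  split between excitation slots exactly at the pulse ratio.
- **Background** (defaults 2000/1000 s⁻¹ donor/acceptor) is uniform over
  the whole record; contaminant species (donor-only, acceptor-only;
  defaults 20%/10%) are drawn per molecule.  One seeded generator drives
  every draw in a fixed order, so streams are bitwise reproducible.

What the generator does **not** emulate: diffusion-driven intensity
profiles within bursts, photophysics beyond leakage/direct excitation
(no blinking, bleaching, triplets), detector dead time or afterpulsing,
and multi-molecule coincidence events.  Passing tests therefore show
estimator correctness under the stated statistical model, not robustness
to those instrument artifacts.

## Burst search and corrections

Burst detection smooths the interphoton intervals with a centered
15-photon running average; intervals below the 10 µs cutoff seed a
burst, and edges expand outward while the raw adjacent interval is still
below the cutoff (a deterministic tie rule).  Bursts keep ≥ 30 photons
counted over both detectors and both excitation slots.  Intervals are
differenced in integer clock ticks, so detection is exactly invariant to
global time offsets.  No background subtraction or crosstalk correction
is applied at this stage.

Raw quantities per burst: E_raw = n_DA/(n_DD+n_DA) (donor-excitation
photons only) and S_raw = (n_DD+n_DA)/(n_DD+n_DA+n_AA).  Leakage is
estimated as the pooled apparent efficiency of the donor-only population
(S_raw > 0.9); direct excitation as the pooled n_DA/n_AA of the
acceptor-only population (S_raw < 0.2, including bursts with zero
donor-excitation photons, which are flagged E-invalid but are the purest
acceptor-only examples).  Corrected counts:

    n_DD' = n_DD/(1−l),   n_DA' = n_DA − n_DD·l/(1−l) − d·n_AA

which inverts the generative convention exactly.  Raw E/S are never
clipped; corrected values may leave [0, 1] and are flagged, not altered.
The doubly-labeled selection window on corrected S defaults to
[0.3, 0.8] and is configurable (the underlying criterion is categorical;
the numeric window is an analysis choice).

## Photon-by-photon hidden Markov inference

The likelihood of a burst's colored photon sequence is a forward
recursion with inter-photon propagators exp(QΔt) and emission matrices
B(c) = diag(E_i) or diag(1−E_i); bursts are independent and their
log-likelihoods add.  Numerical notes:

- Propagators come from the eigendecomposition of Q, computed once per
  iteration and evaluated per *unique* interphoton gap.  Gaps are
  quantized to the 25 ns clock before caching (exact for tick-based
  streams; for any realistic rates the quantization error is orders of
  magnitude below statistical resolution), which keeps the cache to a few
  thousand entries for hundreds of thousands of photons.  Rate matrices
  of interest here (birth–death chains) are always diagonalizable with
  real spectra; the implementation uses complex arithmetic throughout and
  takes real parts at the end, with a series fallback for near-degenerate
  eigenvalue pairs.  Propagator rows are clipped at zero and renormalized
  against roundoff.
- The forward pass is scaled per photon (no underflow for ≥10⁴-photon
  bursts); kernels are numba-compiled.

Fitting is **exact expectation-maximization**: the E-step computes, for
each interval conditioned on the data, the expected occupation time of
each state and the expected number of each transition, using the
closed-form integral ∫₀ᵗ e^{Qs} 1_k e^{Q(t−s)} ds evaluated in the
eigenbasis; the M-step sets k_kl = E[N_kl]/E[T_k] and E_k to the expected
acceptor fraction in state k.  The log-likelihood is monotone
non-decreasing at every iteration.  Connectivity masks (default:
sequential chain) are preserved exactly: masked rates start and stay at
zero.  The initial-state distribution p₀ is a free shared parameter
updated by EM — bursts begin mid-process, so p₀ converges near the
stationary distribution, but treating it as free keeps the M-step closed
form and the monotonicity exact.  Reported occupancies always come from
the stationary distribution of the fitted Q.

Defaults: convergence at relative log-likelihood change < 10⁻⁶ (or 1000
iterations), 5 restarts (one informed start — efficiencies from burst-E
quantiles in descending order, all allowed rates at 1/(10·mean Δt) —
plus seeded perturbations), states reported in canonical
descending-efficiency order (chains are reversed, not arbitrarily
permuted, to preserve their topology).  Fitted efficiencies are
raw-scale: emission uses uncorrected photon colors, as the crosstalk
corrections apply to burst populations, not to the per-photon process.
Uncertainties come from bootstrap over bursts (default 20 resamples),
run separately from the point fit.

K = 1 is handled in closed form (E equals the overall acceptor
fraction).  Model selection reports the Bayesian information criterion
and the recoloring discrepancy for each K; the recommendation is the
smallest K whose recoloring matches the data, since recoloring is the
operative goodness-of-fit notion for this kind of data.

### Validation analyses

- **Recoloring**: a fresh hidden path is simulated over each burst's real
  photon times from the fitted model and colors are redrawn; the
  per-burst efficiency histograms of data and recoloring are compared by
  a two-sample chi-square statistic, Σ(o₁−o₂)²/(o₁+o₂) over occupied
  bins, against the χ² quantile at level 0.99 with (occupied bins − 1)
  degrees of freedom.
- **Viterbi paths** use the same propagator/emission model in log space.
  Photon-level paths may show apparent next-nearest-neighbour steps even
  under chain connectivity — two hidden jumps can fall between
  consecutive photons — so no connectivity constraint is imposed on
  paths.
- **Dwell times**: segment boundaries are placed midway between the
  photons straddling a Viterbi transition; dwells touching a burst edge
  are censored.  The exponential MLE (1/mean) carries a 1/√n relative
  error.  This estimator needs several photons per dwell: at photon
  rates comparable to the exchange rate, missed short dwells bias rates
  low (~18% at 190 kHz for ~5500 s⁻¹ exchange), so dwell-based checks
  are run at 500 kHz with well-separated efficiencies (0.95/0.05), where
  the bias is a few percent.  This is a property of dwell analysis
  generally, and the reason the EM fit — which needs no path
  segmentation — is the primary estimator.
- **Cross-correlation**: donor and acceptor counts are binned (default
  2 µs) per burst, cross-correlated, normalized per burst by mean
  intensities, pooled, and fitted with c + A·e^(−τ/τ_R); for two-state
  exchange τ_R = 1/(k₁₂+k₂₁) and A < 0.
- **Segmentation histograms** pool per-dwell efficiencies of segments
  with at least m photons (default 10), resolving state efficiencies
  that time-averaging blurs in the burst histogram.

## Thermokinetic post-processing

State free energies follow from occupancy ratios, ΔG_i − ΔG_j =
ln(π_j/π_i), and barriers from the Arrhenius form ΔG‡_ij = ln(A/k_ij),
both in kBT with A = 10⁵ s⁻¹ by default (a conservative pre-exponential
for large-scale conformational motion; barriers shift by ln 10 ≈ 2.3 kBT
per decade of A, and rates exceeding A are flagged as negative
barriers).  The active/inactive ratio is π₁/π₂, which for a chain equals
k₂₁/k₁₂ exactly.  Labeling statistics are the binomial P(k) =
C(n,k)p^k(1−p)^(n−k) with p the labeled fraction; at a 1:100 mix and
n = 6, P(1) = 5.7% and P(2) = 0.14% (exact evaluation; 15p² alone, i.e.
dropping the (1−p)⁴ factor, would give 0.15%).  Hill and binding-isotherm
fits are constrained nonlinear least squares with analytic Jacobians and
data-driven starting values.

## Rigid-body triangulation

Conformers of the mobile domain are rotations about its anchor point on
a uniform grid of intrinsic Z-Y-Z Euler angles — azimuthal angles over
[0, 2π) excluding the endpoint, polar over [0, π] — 25 points per axis
(25³ = 15,625) including the identity.  The parameterization has the
usual gimbal degeneracy at polar angle 0 or π, where grid points
duplicate; ranking uses a stable (χ², index) tie-break so results are
deterministic.  Clash rejection uses Bondi van der Waals radii with a
0.3 Å overlap allowance (atoms clash when d < Rᵥᵢ + Rᵥⱼ − 0.3); a k-d
tree restricts candidate pairs but is exactly equivalent to the
all-pairs test.  The clash scope is all non-domain atoms, which subsumes
"same and adjacent protomers" for any structure supplied.

Dye accessible volumes keep cubic-grid positions within the linker
length of the attachment atom that clear every other atom by
max(dye radius, linker width/2) plus the atom's van der Waals radius
(AV defaults: linker 20 Å, width 4.5 Å, dye radius 3.5 Å, typical for
maleimide-linked Alexa-class dyes; all overridable).  Grid spacing
auto-tunes toward clouds of ~600–1200 positions.  Pair efficiencies are
exact means of 1/(1+(r/R₀)⁶) over all donor × acceptor position pairs —
averaging efficiencies, not distances — with seeded subsampling only
beyond 4×10⁶ pairs (error ~ spread/√n_pairs).  κ² = 2/3 (isotropic dye
averaging) is implicit in the AV treatment; R₀ is a per-pair input.
Conformers are ranked by χ² = Σ_pairs (E_measured − E_model)², computed
once per measured state vector (e.g. once with the active-state and once
with the inactive-state efficiencies).  RMSD to a reference uses the
shared fixed body frame with no refitting; the domain tilt is the angle
between first principal axes, folded to [0°, 90°], with near-spherical
domains rejected as axis-degenerate.

The bundled toy complex (slab body + jittered rod domain) carries four
labeled sites (two body, two domain) forming three informative
body↔domain pairs.  Three sites would be geometrically degenerate for
rigid-body recovery: all distances from a single body point are
preserved by the one-parameter family of rotations about the axis
through the anchor and that point.  Toy-scale runs use shorter linkers
(12 Å) and ~100-point clouds so the full-grid pipeline completes in
seconds; the 600–1200-point regime is exercised separately.

## Problem sizes and determinism

The acceptance script regenerates everything from its `--seed`: 4000
simulated bursts (~3400 pass the burst search, ≥3000 as required) at
190,000 photons/s for the three-state recovery, fitted with the informed
initialization (a single EM start; the informed start has not been
observed to need restarts on well-conditioned recovery problems, and
restarts remain available in the library).  The test suite uses smaller
replicates (e.g. ten 1200-burst fits for the recovery property) chosen
so that statistical error stays within the asserted bands.  All
randomness — simulation, restarts, bootstrap, recoloring, subsampling —
flows through seeded `numpy` generators.

## Known limitations

- The burst-duration and background-rate distributions are stand-ins
  (the modeled experiment does not report them); both are configurable.
- Recoloring calibration assumes approximately multinomial bin counts;
  with very few bursts the χ² threshold is conservative.
- EM convergence is assessed on the log-likelihood; for nearly
  unidentifiable models (duplicated states) parameters can drift along
  flat directions after the likelihood has converged.
- The triangulation reports grid-resolution conformers; no continuous
  refinement around the best grid point is attempted.
- Gamma-factor and background corrections of burst quantities are out of
  scope (the modeled analysis applies neither).
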