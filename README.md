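# switchfret

Photon-level analysis of ultrafast conformational switching measured by
single-molecule FRET, with FRET-restrained rigid-body structure
determination.  The package was built around the analysis of the ClpB
disaggregase's coiled-coil middle (M) domain — an allosteric switch that
jumps between an active and an inactive conformation on the microsecond
time scale — but every stage is generic for diffusion-based smFRET
measurements with pulsed interleaved excitation (PIE/ALEX).

## Who this is for

Single-molecule spectroscopists who need a tested, scriptable pipeline
going from raw photon streams (or realistic simulations of them) to
state-resolved kinetics and structural models:

1. **`synthetic_data`** — photon-level simulation of diffusing molecules:
   rectangular bursts with exponential durations, a hidden continuous-time
   Markov chain switching FRET states, 3:1 PIE at 40 MHz, leakage, direct
   excitation, donor-only/acceptor-only contaminants and background, all
   with per-photon ground truth.
2. **`burst_processing`** — burst search by the running-average
   interphoton-time criterion (15-photon window, 10 µs cutoff, ≥30
   photons), raw E/S, correction-factor estimation from the E/S plane,
   stoichiometry filtering, histograms and the shot-noise reference.
3. **`h2mm_inference`** — photon-by-photon maximum-likelihood inference of
   a K-state kinetic model from photon colors and arrival times
   (continuous-time hidden Markov model fitted by exact EM), plus four
   validation analyses: stochastic recoloring, Viterbi segmentation,
   dwell-time distributions and donor–acceptor cross-correlation.
4. **`thermokinetics`** — stationary populations, active/inactive ratios,
   Arrhenius free-energy profiles (ΔG‡ = ln(A/k) in units of kBT), binomial
   labeling statistics, Hill and binding-isotherm fits.
5. **`structure_model`** — rigid-body conformer grids (25³ = 15,625
   rotations), van der Waals clash filtering (d < Rᵥᵢ + Rᵥⱼ − 0.3 Å),
   accessible-volume dye clouds, AV-averaged pair efficiencies
   E = ⟨1/(1 + (r/R₀)⁶)⟩ and χ²_E ranking against measured efficiencies.
6. **`cli`** — `switchfret simulate|bursts|fit|recolor|thermo|triangulate|report`.

## The model at the core

Hidden states i = 1..K exchange with rate matrix **Q**; each
donor-excitation photon is acceptor-colored with probability E_i of the
state occupied at its arrival.  The likelihood of a colored photon
sequence is

L = p₀ᵀ B(c₁) ∏ₙ [exp(Q Δtₙ) B(cₙ)] 𝟙,  B(c) = diag(E_i if c = acceptor else 1 − E_i),

maximized over (E, Q) by expectation-maximization with closed-form
continuous-time sufficient statistics (expected state occupation times and
jump counts per inter-photon interval, via eigendecomposition integrals of
the propagator).  Because every photon contributes individually, exchange
much faster than the burst duration — invisible in the FRET histogram
except as broadening beyond shot noise — is resolved directly.

## Worked example

```python
import numpy as np
from switchfret import (SimConfig, simulate_photon_stream, detect_bursts,
                        donor_excitation_records, wt_mdomain_model)
from switchfret.h2mm_inference import fit_model
from switchfret.thermokinetics import active_inactive_ratio, free_energy_profile

model = wt_mdomain_model()          # 3 states: E = 0.8/0.47/0.15,
                                    # k12/k21/k23/k32 = 5300/5700/800/2300 1/s
cfg = SimConfig(n_bursts=3000, rng_seed=1, leakage=0.0, direct_excitation=0.0,
                donor_only_fraction=0.0, acceptor_only_fraction=0.0,
                aa_brightness=1.0)
stream, truth = simulate_photon_stream(cfg, model)
records = donor_excitation_records(stream, detect_bursts(stream))
res = fit_model(records, K=3)
print("E  =", np.round(res.model.E, 3))
print("k  =", [round(res.model.Q[i, j]) for i, j in [(0,1),(1,0),(1,2),(2,1)]])
print("pi =", np.round(res.model.pi, 3))
print("active/inactive =", round(active_inactive_ratio(res.model)[0], 2))
print("barrier 1->2 =", round(free_energy_profile(res.model).barriers[(1, 2)], 2), "kBT")
```

Output (seed 1):

```
E  = [0.792 0.465 0.152]
k  = [5172, 5655, 772, 2087]
pi = [0.444 0.406 0.15 ]
active/inactive = 1.09
barrier 1->2 = 2.96 kBT
```

The fitted efficiencies land within 0.01 of the generating values, the
four rates within ~10%, and the forward barrier at the conventional
pre-exponential factor of 10⁵ s⁻¹ is ~3 kBT — a switch whose barrier is
lower than a single hydrogen bond, which is what makes its equilibrium so
easy for ligands to tune.

The same pipeline runs from the shell:

```bash
switchfret simulate --config config.yaml --out run/
switchfret bursts   --photons run/photons.h5 --out run/
switchfret fit      --photons run/photons.h5 --k 3 --out run/
switchfret report   --model run/model.json --out run/
```

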