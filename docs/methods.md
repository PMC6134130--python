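# Model and methods

## The system being modelled

`betaclock` simulates the circadian clock of the rodent pancreatic β cell
together with a minimal glucose–insulin module, under two periodic
environmental inputs that can be put in conflict:

* the **feeding schedule** — food intake raises blood glucose, and glucose
  feeds back on the clock by activating *Per* transcription;
* an **SCN-driven neural cue** — a light-entrained signal from the central
  pacemaker that peaks during the light phase and increases *Rev-Erb*
  transcription, and that does *not* move when the feeding schedule is
  shifted.

Under normal (nighttime) feeding both cues point the local clock at the
same phase.  Restricting food to the light phase (daytime feeding, DF)
puts them 12 h apart: the model's core question is what a local clock does
when its two zeitgebers disagree, and what that does to insulin secretion.

## Equations

The state has 13 variables: 9 clock components (mRNA and protein for
*Bmal1*, *Per*, *Cry*, *Rev-Erb*, plus one PER–CRY complex), glucose,
insulin, and mRNA/protein of one generic clock-controlled exocytosis
factor (EXO).  Two further linear equations convert the feeding window
into a smooth food-intake signal, giving 15 equations in total.

Every regulation is a product of Hill activation/repression terms with
linear degradation; the PER–CRY complex forms by mass action:

* CLOCK–BMAL1 (represented by the BMAL1 protein) activates *Per*, *Cry*,
  *Rev-Erb* and *Exo* transcription through a shared activator gate
  `H⁺(BMAL1) · H⁻(PER–CRY)` — the PER–CRY complex inhibits the *action* of
  CLOCK–BMAL1, not its synthesis.  The *Exo* gene carries its own
  thresholds on the same two regulators (`K_bmal_exo`, `K_cplx_exo`), so
  its transcription phase can differ from that of the core genes, as
  clock-controlled output genes generally do.
* REV-ERB protein represses *Bmal1* transcription (the ROR activating arm
  is omitted).
* Glucose adds an activation term on *Per* transcription (strength
  `c_glu`); the SCN cue adds an activation term on *Rev-Erb* transcription
  (strength `cneur`).
* Insulin follows the coincidence rule
  `d[Ins]/dt = k_i · f_glu(G) · f_exo(EXO) − d_i · [Ins]`:
  secretion requires simultaneously high glucose and high exocytosis
  capacity.
* Glucose: basal production + food input − first-order clearance −
  insulin-dependent uptake (bilinear in insulin × glucose).

Units: time in hours, ZT convention (ZT0 = lights on, 12:12 LD);
concentrations are dimensionless relative units, as appropriate for
relative-expression data.

## Forcing signals

* **Feeding drive**: a smoothed square window (logistic edges, steepness
  4 h⁻¹), duration 12 h, onset ZT12 for NF; a shift Δ displaces the whole
  window (Δ = +12 gives DF).  Two linear relaxation stages
  (drive → activator → output) turn the window into the food-intake signal
  entering the glucose equation.
* **SCN cue**: a clipped-cosine pulse `cneur · max(0, cos)⁴` centred on
  `scn_peak` (constrained to the light phase).  The sharp pulse shape
  keeps the cue's temporal mean small (3/16 · cneur); a broad raised
  cosine with the same peak value would impose a constant Rev-Erb drive
  large enough to quench the autonomous oscillation at the reference
  coupling strength.  The cue never shifts with food.

## Parameters and calibration

All constants live in a flat `ModelParameters` record (YAML round-trip).
The shipped reference set was calibrated in two stages:

1. **Oscillator search** — steady states of the full system with both cues
   frozen at their temporal means were screened through their Jacobian
   eigenvalues for a Hopf instability with a circadian (20–28 h) imaginary
   period; candidates were verified by long integration to sustain a limit
   cycle.
2. **Phenotype calibration** — a seeded evolutionary refinement (log-normal
   multiplicative steps, uniform crossover) scored each candidate on the
   entrained NF/DF behaviour: the differential clock-gene phase shift
   (Per ≈ 11.6 h, Bmal1/Cry/Rev-Erb ≈ 8 h, in the delay direction),
   reduced DF insulin with raised DF glucose, a larger NF than DF
   coincidence index, and the food-anticipatory pre-meal insulin rise
   present under NF but not DF.

Two calibration outcomes deserve comment because the design space was
genuinely open:

* `scn_peak` ended in the early light phase.  The *direction* of the
  partial core-clock shift under feeding inversion (phase delay vs phase
  advance) depends on where the SCN cue sits relative to the feeding
  window; only the delay direction reproduces both the "exocytosis rise
  delayed relative to the meal" phenotype and hypoinsulinemia, because the
  partially-shifted exocytosis pulse must leave the feeding window under
  DF.
* The *Exo* gene's own regulatory thresholds put its transcription under
  near-saturated BMAL1 activation with mid-range PER–CRY repression, so
  its rise tracks the morning *fall* of the PER–CRY complex.  This places
  the EXO protein's rising flank before food onset — the substrate of the
  anticipatory insulin rise — while keeping its peak inside the feeding
  window.

## Simulation protocol

Integration uses LSODA at rtol 1e-8 / atol 1e-10 (a numba-compiled
right-hand side when numba is importable; the pure-Python definition is
the reference and their equivalence is tested).  Entrainment is found by
integrating day by day from a fixed documented initial state (all
variables 0.1) until consecutive cycles agree to an amplitude-normalized
sup distance < 1e-3 (flat variables are normalized by their mean); the
returned cycle is resampled at 0.05 h.  Non-convergence (e.g. free-running
dynamics under constant cues, or unlocked scan points) is reported in the
`converged` flag, never silently ignored.  Scans and calibration runs use
rtol 1e-6 with a 2e-3 cycle tolerance; this moves peak phases by well
under 0.01 h and keeps a full SCN-strength scan within minutes.

## Metrics

* **Peak phase**: grid argmax refined by a quadratic through the three
  bracketing samples; phases are reported mod 24.  Flat signals raise an
  explicit undefined-phase error.
* **Circular shift**: minimal circular distance in [0, 12] h with an
  advance/delay tag ("antiphase" at exactly 12 h).  The differential
  shift between conditions is the signed change of the Bmal1−Per circular
  difference, reduced to (−12, 12].
* **Coincidence index**: normalized overlap
  ∮f_glu f_exo / √(∮f_glu² · ∮f_exo²) over one cycle — 1 exactly for
  proportional gates (Cauchy–Schwarz), invariant to joint time shifts and
  to rescaling either signal.
* **Anticipation**: mean d[Ins]/dt over the 3 h before food onset
  (pre-slope) and the 3 h after (post-slope), each normalized by
  (cycle amplitude / window).  A slope rupture is detected when the
  pre-slope exceeds 0.05 and the post-slope is at least 1.5× the
  pre-slope.  The thresholds are package defaults chosen so that the three
  reference scenarios (NF, DF, clockless) classify as anticipating,
  non-anticipating and non-anticipating respectively; the clockless
  model's index is ~0 because a constant exocytosis gate cannot produce a
  pre-meal rise.
* **Architecture ablations** replace a signal by its temporal mean over
  the entrained physiological NF cycle: the SCN cue for
  "no central clock", the clock-driven *Exo* transcription for
  "no clock".  Adaptation after an NF→DF switch is counted in full cycles
  until the post-switch cycle matches the final re-entrained cycle under
  the same 1e-3 criterion.

## Synthetic data

The pseudo-experiment generator samples the entrained cycle at a sparse
daily grid (default every 4 h, 3 replicates) and applies multiplicative
lognormal noise with a fixed coefficient of variation (default 0.1),
matching the positive, roughly constant-CV character of expression and
hormone measurements.  It emulates sampling density and noise structure
only — no animal-to-animal random effects, no ultradian structure, no
assay-specific floor effects — so passing recovery tests demonstrate
pipeline correctness at realistic sparsity/noise, not robustness to every
failure mode of real data.

## Calibration machinery

Sparse tables are first smoothed with a least-squares Fourier series
(mean + 2 harmonics at the 24 h fundamental — 6–8 samples/day cannot
support more).  The fitting objective is the amplitude-normalized squared
mismatch between the entrained NF cycle and the target curves on an hourly
grid; parameter points that fail to entrain cost 1e6, which keeps the
derivative-free search inside the entrained regime.  The optimizer is a
from-scratch Hooke & Jeeves pattern search (exploratory coordinate moves
plus pattern extrapolation, step halving, deterministic); model fits run
it in log10-parameter space so steps are multiplicative and positivity is
automatic.  Practical identifiability of the full parameter set is *not*
claimed: recovery tests deliberately free only small subsets (e.g. three
transcription/coupling rates).

## Known limitations

* Rate laws and the parameter set are a refit of the network topology, not
  transcribed constants; quantities the network constrains only loosely
  (absolute concentrations, individual rate constants) are not meaningful,
  only the entrained phase relationships and relative metabolic changes
  are.
* Glucocorticoid/temperature cues, glucagon/α cells, β-cell mass,
  insulin's central feedback on appetite, and stochastic (molecular-noise)
  effects are all outside the model's scope.
* The two-harmonic Fourier interpolation carries a deterministic
  truncation bias for sharply peaked waveforms: on the reference model the
  fitted peak of *Per* mRNA sits about 1.5 h from the true model peak even
  for noiseless data, while the near-sinusoidal genes land within 1 h.
  Calibration fits model output to the *smoothed* curves, so the bias
  affects both sides equally; it matters only when the fitted phase is
  compared against the raw model curve.
* The NF anticipatory pre-rise is small relative to the post-meal rise
  (the model secretes little during fasting by construction), so the
  rupture classification, while robust for the three reference scenarios,
  depends on the documented threshold defaults.
* The entrained solution is obtained from one documented initial state;
  forced nonlinear oscillators can in principle have coexisting locked
  states, and no claim is made about other basins of attraction.
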