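# Methods

`cbf3select` asks which direct connections from the Arabidopsis circadian
clock to the *CBF3* promoter best explain the observed *CBF3* mRNA
waveform: a sharp daily peak 8 h after dawn whose phase is robust across
photoperiods and persists in constant light. It does so by fitting an
ensemble of candidate transcription models to multi-regime expression time
series, ranking them with the corrected Akaike Information Criterion
(AICc), and probing the fitted models with in-silico genetic and
cold-pulse experiments.

## The CBF3 submodel

*CBF3* mRNA is treated as a pure clock output:

    dC/dt = v_max · ∏_A  A^n/(A^n + K_A^n) · ∏_R  K_R^n/(K_R^n + R^n)  −  d·C

Each candidate regulator contributes an independent Hill term — activators
(A) saturating upward, repressors (R) downward — multiplied together, with
one half-saturation constant `K` per regulator (arbitrary units, matching
the clock abundances), a maximal transcription rate `v_max` (a.u. h⁻¹) and
a first-order decay rate `d` (h⁻¹). The Hill exponent `n` is fixed
(default 2, configurable) and shared by all terms, so a model with R
regulators has `2 + R` free parameters. Clock components act only on
transcription, never on decay, and there is no feedback from CBF3 to the
clock.

The ensemble has 13 members: combinations of LHY/CCA1 activation with
repression by TOC1, the Evening Complex (EC), or the day-phased PRRs
(PRR9, PRR7, and NI as the PRR5 proxy), including an EC-activation control
and two variants carrying all three PRR repressors at once.

## Clock driver

The default driver is phenomenological: each of the six regulator proteins
is a smooth, strictly positive, exactly 24-h periodic circular bump
(von-Mises-shaped, `amp · exp(κ(cos(2π(t−φ)/24) − 1))`) with peak phase φ,
a width set via the full width at half maximum, and unit amplitude.
Default phases (h after dawn): LHY/CCA1 1, PRR9 3, PRR7 6, NI 9, TOC1 13,
EC 23; widths: 8 h for LHY/CCA1 and the EC, 6 h for the PRR family. These
encode the canonical phase ordering — morning LHY, sequential day-phased
PRRs, dusk TOC1, EC activity high from late night across dawn and below
25 % of its maximum through the afternoon.

Two consequences of this choice matter for interpretation:

* **No photoperiod dependence.** The waveforms are functions of time after
  dawn only, identical in all four regimes including constant light (the
  free-running period drift of a mechanistic clock is out of scope).
  Model discrimination therefore rests entirely on waveform shape, not on
  regime-specific phase behaviour.
* **Width degeneracy.** Two antiphase circular bumps of *equal* width
  satisfy `x₁(t)·x₂(t) = const`, which makes activation by one exactly
  interchangeable with repression by the other inside a Hill term. With
  equal LHY/TOC1 widths the ensemble degenerates (architecture pairs fit
  to identical residuals); the unequal default widths (8 h vs 6 h) avoid
  the exact degeneracy, though a strong approximate symmetry remains.

Genotypes are configuration, not mechanism: a knockout zeroes a species,
and knock-on effects are amplitude multipliers (defaults: *ni prr7 prr9*
doubles LHY/CCA1, since the PRRs repress it; *lux* removes the EC and
scales LHY/CCA1 by 0.3, since EC loss lowers LHY expression). Applying a
genotype is idempotent because it always acts on the stored wild-type
baseline. An optional SBML driver (requires `python-libsbml`) can replace
the surrogate with a mechanistic clock model through a declared mapping of
SBML species ids onto the six regulator roles; it supports core SBML
constructs (reactions with kinetic laws, rate rules) and is integrated
with LSODA.

## Synthetic expression data

The data generator emulates diurnal microarray series of *CBF3*: a
raised-cosine bump centred at ZT8 with 4-h full width at half maximum on a
baseline of 5 % of the peak, identical in all four regimes, sampled every
4 h over 48 h (13 points × 4 regimes = 52 points), plus independent
Gaussian noise (SD 10 % of the peak) truncated at zero. Each regime draws
from an independent child stream of the seed. What it deliberately does
not model: replicate structure, probe-level effects, regime-dependent
waveform changes, and any phase drift in constant light — so passing the
selection tests shows that the machinery recovers the architecture best
able to explain *this* waveform family, not that it would reproduce every
regime-specific feature of the original microarray data.

## Fitting and model selection

Expression units are arbitrary, so model output and data are each
normalised to unit maximum within a regime before residuals are formed;
the cost is the residual sum of squares pooled over regimes. This makes
the fit scale-free, and `v_max` is held at 1 during optimisation (it only
sets the scale; the fitted `K` and `d` are unaffected). The first 24 h of
every simulation are discarded as an entrainment transient, with the
initial condition at the instantaneous steady state `p(0)/d` to shorten
the transient.

The optimiser is a seeded multi-start: a Latin hypercube of fixed size 64
is drawn once per seed over log-spaced bounds (each `K` in 10⁻³–10³ a.u.,
`d` in 0.05–5 h⁻¹, i.e. mRNA half-lives from ~8 min to ~14 h) and its
first `n_restarts` points (default 24) each start a bounded Nelder–Mead
refinement; the best restart (ties broken by lowest index) is polished
with tighter termination tolerances. Consuming a fixed pool from the
front makes the best cost non-increasing in the number of restarts, and
every stage is bit-reproducible for a fixed seed.

The linear production–decay equation is integrated with an exact
exponential-integrator recurrence for piecewise-linear forcing on a
sub-grid of ≤ 0.02 h (evaluated as a linear recursive filter), which
matches a 0.001-h fourth-order Runge–Kutta reference to better than 1e-4
relative error across all 13 architectures. Clock abundances are cubic-
spline interpolated between grid points and clipped at zero.

Scoring uses the standard RSS form of AICc with the profiled Gaussian
residual variance counted as one extra parameter (`k = k_free + 1`), one
pooled score per model across all four regimes (n = 52). Akaike weights
are computed from score differences to the minimum, which is
overflow-safe and shift-invariant.

## In-silico experiments

* **Peak phase**: argmax over the final full cycle with parabolic
  refinement, reported modulo 24; trajectories flat to within 1e-9
  relative amplitude raise an explicit arrhythmic error.
* **Mutant fold change**: mutant/wild-type ratio of cycle-peak mRNA in
  constant light with identical (wild-type-fitted) parameters; an
  arrhythmic mutant contributes its cycle mean and is flagged. Classes:
  < 0.05 abolished, < 0.5 reduced, 0.5–2 wild-type-like, > 2 elevated
  (configurable).
* **Cold gating**: five-fold perturbations applied every 4 h across the
  subjective day in constant light, either to the LHY/CCA1 protein for a
  4-h window (cold signalling routed through the clock, as with
  temperature-controlled CCA1 splicing) or to the CBF3 transcript at an
  instant (clock-independent induction). Induction at each pulse time is
  read over a 4-h observation window. The default statistic is the
  **response** — the maximum excess of the pulsed over the unperturbed
  trajectory — because the alternative absolute reading is bounded below
  by the ambient waveform's maximum in the window, so the pulse nearest
  the ambient peak dominates in *both* modes and the two cold-signalling
  hypotheses become indistinguishable by construction. The response
  reading also makes the direct-mode profile exactly proportional to the
  ambient waveform sampled at the pulse times, which is the defining
  structural property of a clock-independent signal. The absolute reading
  remains available (`statistic="absolute"`).

## Reproducibility

A single master seed drives everything: per-stage child seeds are derived
as `SeedSequence(master, spawn_key=(stage,))` truncated to 31 bits, and
per-architecture fitting seeds are spawned the same way from the fit-stage
seed. Re-running a configuration is bit-identical; the pipeline writes a
manifest with the config hash, derived seeds and a SHA-256 checksum of
every output file.

Default problem sizes — 52 data points, 24 restarts per architecture, a
0.25-h clock grid over 96 h with a ≤ 0.02-h integrator sub-grid — complete
a full 13-member selection in well under a minute on one CPU.

## Known limitations

* The surrogate clock's photoperiod independence means behaviours that
  hinge on regime-specific clock dynamics (e.g. a constant-light-specific
  phase delay in a model that fits light/dark cycles well) cannot arise;
  only models structurally unable to peak at ZT8 show delayed phase.
* The approximate LHY-activation/TOC1-repression symmetry of antiphase
  surrogate waveforms compresses the score separation between
  architectures that a mechanistic clock would distinguish more sharply,
  and leaves the partition of the fitted effect between the LHY and TOC1
  Hill terms — and hence the magnitude of simulated *toc1* knockout
  effects — only weakly identified.
* With the sharp, low-baseline default template, the fitted top model
  tends to a near-saturated LHY gate (small `K_LHY`), which damps the
  simulated response to LHY/CCA1 amplitude increases (the *ni prr7 prr9*
  knock-on and the via-LHY cold pulses at dawn, both of which act
  multiplicatively on an already-saturated term).
* Mutant knock-on effects are configured multipliers, not clock
  mechanism; predictions for mutants whose main effect is a waveform
  *reshaping* (rather than amplitude change) are outside the surrogate's
  vocabulary.
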