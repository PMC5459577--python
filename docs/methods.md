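# Methods

## The folding model

The simulator treats the nascent riboswitch transcript as a continuous-time
Markov chain whose states are `(chain length, conformation, ligand status)`
triples.  Chain length is the template position of the 3'-most synthesized
nucleotide (transcription start = 1); the simulation window starts at
position 75 (t = 0), the aptamer domain is complete at position 89, the
switching strand at 134, and the terminator poly-U at 164 (the decision
position).  Conformations are coarse-grained by which helices are formed —
the aptamer closing helix PA, the antiterminator AT, the terminator TH — with
PA and AT mutually exclusive.  All transitions are first order; the master
equation dp/dt = Q·p uses the column-convention generator (Q[j,i] is the
rate i → j, diagonal entries close the columns to zero).

### Topology

Without ligand the intermediates form a linear succession

```
P  →  PA  →  [PA]T  —k_AT_anneal→  P[AT]  →  P[AT]H  →  readthrough
                                               └─k_AT_dissoc_apo→ [PA][TH] → terminated
```

and with ligand the succession branches at the aptamer-complete length class:

```
PA —k_lig_bind→ ligPA —k_tert→ ligPA*          (binding locks strand A)
ligPA/ligPA* → lig[PA]T → lig[PA]TH —k_TH_anneal→ lig[PA][TH] → terminated
P[AT] —k_AT_dissoc_lig→ lig[PA]T               (ligand-accelerated AT dissociation)
P[AT]H —k_refold_holo→ ligP[AT]H —k_AT_dissoc_combined→ lig[PA][TH]
```

Synthesis proceeds in per-nucleotide steps at the elongation rate (default
20 nt/s, the apparent single-round assay rate corrected to cellular NTP
levels), so segment transit times are Erlang-distributed.  Steps whose source
position lies inside a pause interval are divided by the pause factor
(default: pause site 1, U107–U112, factor 70); a factor of 1 reproduces the
no-pausing model edge for edge.  A coarse `segment` granularity collapses
each uniform block into a single exponential step whose rate matches the
block's mean transit time; it reproduces the same switching logic but binds
slightly less ligand during the pause because a single exponential dwell has
a heavier short-time tail than the matched Erlang distribution (terminal
probabilities differ by up to ≈0.14 in the ligand + pause scenario).

### Rate constants

The eight folding/binding constants default to the centrally measured values
(all s⁻¹): ligand binding 0.24 (pseudo-first-order at the experimental
ligand excess, treated as irreversible on the simulation timescale; a
concentration-scaling hook exists but is off because binding was found
concentration-independent above equimolar ratios), intra-aptamer tertiary
rearrangement 0.018, terminator annealing 0.14, antiterminator annealing
9·10⁻³, apo antiterminator dissociation 5·10⁻⁴, ligand-accelerated
dissociation 8.9·10⁻⁴, and the combined pathway 2·10⁻² followed by
1.2·10⁻³.  Transitions with no measured reverse rate are irreversible — the
terminator fold is a kinetically trapped end state.

### Design choices on open points

* **Where ligand binds.** Binding edges are attached to the aptamer-complete
  length class only (positions 89–133).  Kinetically, binding to the
  completed aptamer is the structural decision point: once the switching
  strand emerges, antiterminator nucleation competes with pocket closure.
  Attaching the measured pseudo-first-order binding rate to the long-lived
  `[PA]T` state as well would make the no-pause scenario terminate almost
  fully, contradicting the observed escape of the polymerase without
  pausing — so the locked/unlocked decision is modelled as made by the time
  the switching strand is complete.
* **What locks the aptamer.** The fast binding step (0.24 s⁻¹) locks strand
  A; the slower 0.018 s⁻¹ step is a subsequent intra-aptamer rearrangement
  that does not gate the lock.
* **The decision rule.** On arrival at position 164, antiterminator-folded
  (and unstructured apo) transcripts commit to readthrough at the
  single-nucleotide synthesis rate; aptamer-locked transcripts are held at
  the terminator poly-U — a polymerase blocking point — until the terminator
  helix anneals (0.14 s⁻¹), then commit to termination.  This makes the
  terminated probability in the infinite-slowdown limit equal the
  probability that ligand binds before the pause is escaped, which tends
  to 1.
* **Slow side edges.** The apo dissociation (5·10⁻⁴ s⁻¹) and the combined
  pathway (2·10⁻², 1.2·10⁻³ s⁻¹) are present in the graph but carry
  negligible scenario flux because the commit step outcompetes them; they
  describe the post-decision refolding of released transcripts and are
  exercised by the trace-fitting recovery tests.
* **Pause placement.** The ≈70-fold slowdown is applied per synthesis step
  across the whole U107–U112 interval (six slowed steps), not once to the
  site.
* **Initial condition.** All probability starts in the apo state at position
  75; no pre-equilibrated ligand-bound fraction is assumed (configurable).
* **Regulation window.** The default output grid runs to t = 600 s, by which
  ≥ 99% of probability has been absorbed in every default scenario; the
  reported "ratio at the decision point" is evaluated at the end of this
  window.

### Numerics

`propagate` defaults to scaling-and-squaring matrix exponentials (exact for
this linear, time-homogeneous system; one `expm` per distinct grid spacing)
and offers a BDF integrator with analytic Jacobian at rtol 10⁻⁸ / atol 10⁻¹²;
the two agree to better than 10⁻⁶ and conserve probability to 10⁻⁸.  The
Gillespie sampler advances all trajectories in lock-step over jump rounds
with per-state vectorised categorical draws; identical seeds give bitwise
identical output.  All default rates are distinct, so no tie-breaking is
needed.

## Trace fitting

Mono- and bi-exponential models I(t) = c + Σ Aᵢ e^(−kᵢt) are fitted by
variable projection: for fixed rates the model is linear in plateau and
amplitudes, which are solved exactly, so only the log-rates are searched —
a 60-point logarithmic grid scan for the mono rate, and for the
bi-exponential a deterministic multi-start set (six brackets around the mono
solution plus the best three cells of an 18×18 triangular rate-pair grid),
each refined by Levenberg–Marquardt.  A final full-parameter polish with
lmfit supplies covariance-based standard errors.  Intensities are normalised
to their maximum magnitude before fitting, making results exactly
equivariant under intensity scaling; rising signals are handled by the sign
of the amplitude, not a separate model.  Fits are unweighted unless the
trace carries an explicit noise level (traces from one spectrum share a
single noise sigma); `estimate_noise` provides a robust estimate as
1.4826·MAD of the second differences divided by √6.

Model order is selected by the extra-sum-of-squares F-test (α = 0.05,
F(2, n−5)) **and** a guard requiring the two fitted rates to be more than
3-fold apart with both amplitudes non-negligible; near-degenerate
bi-exponential optima (k₁/k₂ < 1.05) are flagged and fall back to the
mono-exponential.  The distinguishability criterion is a package choice —
standard nested-model practice protected against unstable near-degenerate
fits; the guard only lowers the false bi-exponential acceptance rate below
the F-test's own.  Because the second rate is unidentifiable under the
mono-exponential null, the F reference distribution is approximate; the
empirically measured type-I rate at the study conditions (signal-to-noise
20, 60 points) is ≈3–5%, within the expected band around the nominal 5%.
Per-motif aggregation reports the unweighted mean and standard deviation
across signals (weighted means are an alternative the data do not
discriminate); mixed fit orders within a motif are matched by rank
(fast with fast) with a logged warning.

## Transcription-assay quantitation

The normalized pause fraction of a band divides its intensity by the summed
intensity of all species of equal or greater length in the same lane; lanes
with a zero denominator are masked, never zeroed.  Pause parameters come
from a single-exponential fit to the post-peak decay of that fraction
(k_p; τ = 1/k_p; t₁/₂ = ln2/k_p — the identities hold exactly by
construction); a fraction that only accumulates is reported as a polymerase
blocking point with no pause parameters.  The exact functional form behind
the published pause analysis is not restated in the source material, so the
post-peak exponential decay is this package's documented interpretation.
Apparent rates fit I(t) = I_max(1 − e^(−k_app·t)) and convert via
rate = L·k_app; the conversion is isolated in one function (`kapp_to_rate`)
so the convention can be swapped, and an externally known maximum can be
fixed when the series does not saturate within the observation window.
Termination efficiency is evaluated at the final lane; the ligand-induced
change is reported both as percentage points and as a relative increase,
since either reading of "increased by x%" is defensible.  A per-G label
correction (intensity divided by the species' G count, for body-labelled
transcripts) is available but off by default.  Two species presets ship as
data: the single-round assay numbering (FL 214 / T 164 / PS2 141 / PS1 110 /
RNA95 / RNA90 / RNA77) and the multi-round gel numbering (FL 228 / T 172 /
PS2 152 / PS1 124 / APT 96).

## Synthetic data

Kinetic traces are the exact model curve plus i.i.d. additive Gaussian noise
(spectroscopic noise is amplitude-independent); the default study condition
is signal-to-noise 20 with 60 points spanning five relaxation times.  Gel
time courses come from a per-nucleotide elongation chain (reusing the
master-equation propagator) starting at the 17-nt halted complex: a pause
site contributes an exponential dwell of mean τ, and at the terminated
species' length the flux splits by the commitment probability.  Band
intensities are expected abundances times lognormal noise with unit mean and
configurable coefficient of variation (multiplicative noise dominates band
quantitation); sub-second in-transit mass between landmarks is returned
separately as ground truth — on a real gel it is an unresolvable smear —
so bands plus in-transit mass conserve the initiated complexes exactly.
Defaults (τ = 25 s at the 110-nt pause, 70% commitment, 5% CV, twelve lanes
to 600 s) emulate a realistic single-round time course.  Both generators are
pure functions of (spec, seed).

What passing the round-trip tests shows — and does not.  The generators
share the package's own forward models, so closure demonstrates the
correctness and calibration of the analysis code, not the realism of the
models themselves: real traces have baseline drift and correlated noise,
real gels have background, smears, partial-length degradation products and
lane-to-lane loading variation, none of which are simulated.

## Problem sizes

The test suite uses 200 traces per rate constant for recovery, 500 null
replicates for the F-test calibration, 10⁵ Gillespie trajectories for the
solver cross-check, and 100 gel replicates for the round-trip closure; the
acceptance script uses 50 gel replicates of 10 lanes.  These sizes give
Monte-Carlo standard errors comfortably below the assertion tolerances.

## Known limitations

* Conformations are the coarse-grained helix classes only; there is no
  nucleotide-level secondary-structure prediction, no thermodynamic
  partition function, and no sequence-dependent pause-site prediction.
* Ligand binding is pseudo-first-order and irreversible; dose-response
  behaviour below the saturating regime is out of scope.
* The gel model quantifies band tables; image processing, lane/band
  detection and sequencing-ladder mapping are upstream of this package.
* Absolute termination-efficiency changes measured on real gels depend on
  the experimental intensity data and are not reproduced here; the package
  reproduces the quantitation rules and the switching logic.
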