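# switchsim

Kinetic analysis of co-transcriptional riboswitch folding: a chain-length-coupled
Markov simulator of terminator/antiterminator switching, exponential fitting of
real-time kinetic traces, and quantitation of time-resolved single-round
transcription assays — all exercisable on synthetic data with known ground truth.

## The problem

Transcriptional riboswitches such as the guanine-sensing switch of the
*Bacillus subtilis* *xpt-pbuX* operon decide between two mutually exclusive
folds of the nascent mRNA while it is being synthesized.  Four strand blocks
matter: the aptamer strand P, the aptamer-stabilising strand A, the switching
strand T and the terminator strand H.  In the off-state the aptamer closing
helix PA and the terminator helix TH are formed and transcription terminates;
in the on-state the antiterminator helix AT (pairing A with T) permits
readthrough.  The full-length RNA is kinetically trapped in the terminator
fold, so the regulatory decision has to be made by transcription
intermediates, on the clock set by RNA polymerase.  The question the simulator
answers quantitatively: under which combinations of elongation speed,
transcriptional pausing and ligand binding does the nascent chain commit to
termination?

The package is aimed at RNA biophysicists and quantitative biologists who
want to (a) explore this kinetic-competition model with measured rate
constants, (b) fit relaxation rates from kinetic traces the way the
corresponding wet-lab experiments are analysed, and (c) quantify single-round
transcription gels (pause dwell times, apparent nt/s rates, termination
efficiencies) with transparent, tested rules.

## The model

The nascent transcript is a continuous-time Markov chain over states
`(chain length, conformation, ligand status)`.  First-order transitions are of
four kinds: per-nucleotide **synthesis** steps at the elongation rate
v = 20 nt/s (steps inside pause site 1, U107–U112, are divided by a slowdown
factor of ≈70); **folding** steps carrying measured rate constants
(antiterminator annealing 9·10⁻³ s⁻¹, terminator annealing 1.4·10⁻¹ s⁻¹,
apo antiterminator dissociation 5·10⁻⁴ s⁻¹, ligand-accelerated dissociation
8.9·10⁻⁴ s⁻¹, combined-pathway refolding 2·10⁻² and 1.2·10⁻³ s⁻¹);
pseudo-first-order **ligand binding** at 2.4·10⁻¹ s⁻¹ to the completed
aptamer; and the **termination commit** at the terminator poly-U.  The master
equation dp/dt = Q·p is solved by scaling-and-squaring matrix exponentials or
a stiff BDF integrator, and an exact Gillespie sampler over the same
generator serves as an independent stochastic oracle.

Trace fitting uses variable projection (exact linear solve for plateau and
amplitudes, multi-start search over log-rates) for mono- and bi-exponential
relaxations, I(t) = c + Σᵢ Aᵢ e^(−kᵢt); the model order is chosen by an
extra-sum-of-squares F-test at α = 0.05 with a 3-fold minimum rate
separation.  Gel quantitation implements the normalized pause fraction
(a band divided by all equal-or-longer RNA in its lane), pause parameters
τ = 1/k_p and t₁/₂ = ln2/k_p from the post-peak exponential decay, apparent
rates in nt/s via rate = L·k_app, termination efficiency
%T = 100·I_T/(I_T + I_FL), and Miller units
1000·(A₄₂₀ − 1.75·A₅₅₀)/(t·V·A₆₀₀).

## Worked example

```bash
python examples/simulate_scenarios.py
```

```
scenario                P(terminated)  P(readthrough)  on/off ratio
no_ligand_no_pause             0.0000          0.9953         4e+04
no_ligand_pause                0.0000          0.9943         4e+04
ligand_no_pause                0.4164          0.5805          1.39
ligand_pause                   0.9838          0.0161        0.0163
```

Without ligand the nascent chain always reaches the metastable antiterminator
fold and the polymerase reads through (ratio ≫ 1), with or without pausing.
With ligand but no pausing, the aptamer is usually synthesized past before
binding occurs and the polymerase still escapes (ratio 1.39 > 1).  Only when
the 70-fold pause at U107–U112 holds the polymerase inside the ligand-binding
window does binding lock strand A into the aptamer, the antiterminator can no
longer form, and 98% of chains terminate (ratio 0.016 < 1).

Other entry points: `examples/fit_kinetic_traces.py` (rate recovery and
model-order selection), `examples/quantify_gel.py` (pause dwell, nt/s rate
and %T from a synthetic gel), `examples/reporter_assay.py` (Miller units),
and the `riboswitch` CLI (`simulate`, `fit-traces`, `analyze-gel`,
`make-synthetic`, `full`).

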