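"""Synthetic inputs with known ground truth.

Two generators cover everything the analysis consumes:

* :func:`generate_nmr_trace` draws noisy mono/bi-exponential kinetic traces —
  stand-ins for resolved imino-proton signal time courses — as the exact model
  curve plus i.i.d. additive Gaussian noise of configurable amplitude.
* :func:`generate_gel_timecourse` produces lane-by-band intensity tables from
  a per-nucleotide elongation chain with pausing (reusing the master-equation
  propagator), in which each pause site contributes an exponential dwell and
  the terminator splits flux between the terminated product and the run-off
  transcript with a configurable commitment probability.  Lane intensities
  carry multiplicative lognormal noise of configurable coefficient of
  variation (mean exactly 1), the dominant error source of band quantitation.

Both generators are pure functions of (spec, seed): identical inputs give
bitwise-identical outputs, and the ground truth travels with the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .assay import SPECIES_PRESETS, BandTable
from .errors import ConfigurationError
from .fitting import TimeTrace
from .model import KineticModel, StateSpec, TransitionSpec
from .simulate import propagate


@dataclass(frozen=True)
class TraceSpec:
    """Ground truth of one synthetic kinetic trace.

    ``snr`` of the generated trace is |amplitudes|_max / noise_sd.
    """

    order: int = 1
    plateau: float = 0.0
    amplitudes: tuple[float, ...] = (1.0,)
    rates: tuple[float, ...] = (0.24,)
    t_max: float = 30.0
    n_points: int = 60
    noise_sd: float = 0.05
    t_min: float = 0.0
    seed: int = 0
    signal_id: str = ""
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2) or len(self.rates) != self.order:
            raise ConfigurationError("order must be 1 or 2 and match the rate count")
        if len(self.amplitudes) != self.order:
            raise ConfigurationError("need one amplitude per rate")
        if any(k <= 0 for k in self.rates):
            raise ConfigurationError("rates must be positive")
        if self.n_points < 8:
            raise ConfigurationError("need at least 8 points")
        if self.noise_sd < 0 or self.t_max <= self.t_min:
            raise ConfigurationError("invalid noise or time window")

    def curve(self, times: np.ndarray) -> np.ndarray:
        out = np.full(times.shape, self.plateau, dtype=float)
        for a, k in zip(self.amplitudes, self.rates):
            out += a * np.exp(-k * times)
        return out


def generate_nmr_trace(spec: TraceSpec) -> TimeTrace:
    """Exact exponential curve plus seeded additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(spec.t_min, spec.t_max, spec.n_points)
    clean = spec.curve(times)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=times.shape) if spec.noise_sd else clean
    direction = "rise" if sum(spec.amplitudes) < 0 else "decay"
    return TimeTrace(
        times=times,
        intensities=noisy,
        sigma=spec.noise_sd or None,
        signal_id=spec.signal_id,
        motif=spec.motif,
        direction=direction,
        truth=spec,
    )


@dataclass(frozen=True)
class GelSpec:
    """Ground truth of one synthetic single-round transcription gel.

    The elongation chain starts from a halted complex at ``start_length`` and
    steps one nucleotide at a time at ``elongation_rate``; a transcript
    arriving at a pause-site length dwells there with mean ``tau`` before
    escaping.  At the terminated species' length, flux splits: a fraction
    ``commit_prob`` releases the terminated product, the rest elongates to the
    full-length end of the template.
    """

    species: tuple[tuple[str, int], ...] = SPECIES_PRESETS["single_round"]
    elongation_rate: float = 20.0
    pause_sites: tuple[tuple[int, float], ...] = ((110, 25.0),)  # (length nt, dwell tau s)
    commit_prob: float = 0.7
    stop_times: tuple[float, ...] = (5, 10, 20, 30, 45, 60, 90, 120, 180, 240, 360, 600)
    noise_cv: float = 0.05
    seed: int = 0
    start_length: int = 17
    terminated_species: str = "T"

    def __post_init__(self) -> None:
        lengths = [ln for _, ln in self.species]
        if any(b >= a for a, b in zip(lengths, lengths[1:])):
            raise ConfigurationError("species lengths must be strictly decreasing")
        if not 0.0 <= self.commit_prob <= 1.0:
            raise ConfigurationError("commit_prob must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(self.stop_times, self.stop_times[1:])):
            raise ConfigurationError("stop times must be strictly increasing")
        if self.elongation_rate <= 0:
            raise ConfigurationError("elongation rate must be positive")
        names = [n for n, _ in self.species]
        if len(self.species) > 1 and self.terminated_species not in names:
            raise ConfigurationError(
                f"terminated species {self.terminated_species!r} not in species list"
            )
        dwell_lengths = [ln for ln, _ in self.pause_sites]
        if any(ln <= self.start_length or ln > max(lengths) for ln in dwell_lengths):
            raise ConfigurationError("pause-site lengths must lie inside the transcript")
        if any(tau <= 0 for _, tau in self.pause_sites):
            raise ConfigurationError("pause dwell times must be positive")


def _elongation_model(spec: GelSpec) -> tuple[KineticModel, dict[str, list[str]]]:
    """Per-nucleotide elongation chain with pause dwells and terminator split.

    Returns the model plus the mapping from band name to the state ids whose
    population that band collects (pause dwell states and released products);
    mass in transit between landmarks belongs to no band (gel smear).
    """
    v = spec.elongation_rate
    lengths = {ln: name for name, ln in spec.species}
    full_length = max(ln for _, ln in spec.species)
    term_length = dict(spec.species).get(spec.terminated_species)
    dwell = dict(spec.pause_sites)

    states: list[StateSpec] = []
    transitions: list[TransitionSpec] = []
    bands: dict[str, list[str]] = {name: [] for name, _ in spec.species}

    def exit_rate(pos: int) -> float:
        return 1.0 / dwell[pos] if pos in dwell else v

    for pos in range(spec.start_length, full_length):
        sid = f"ec@{pos}"
        states.append(StateSpec(id=sid, position=pos, role="paused" if pos in dwell else "elongating"))
        if pos in dwell and pos in lengths:
            bands[lengths[pos]].append(sid)
        k_exit = exit_rate(pos)
        nxt = f"ec@{pos + 1}" if pos + 1 < full_length else "released_FL"
        if term_length is not None and pos == term_length and len(bands) > 1:
            if spec.commit_prob > 0:
                states.append(
                    StateSpec(id="released_T", position=pos, role="terminated")
                )
                transitions.append(
                    TransitionSpec(sid, "released_T", spec.commit_prob * k_exit, "termination_commit")
                )
                bands[spec.terminated_species].append("released_T")
            if spec.commit_prob < 1:
                transitions.append(
                    TransitionSpec(sid, nxt, (1 - spec.commit_prob) * k_exit, "synthesis")
                )
        else:
            transitions.append(TransitionSpec(sid, nxt, k_exit, "synthesis"))
    states.append(StateSpec(id="released_FL", position=full_length, role="readthrough"))
    bands[lengths[full_length]].append("released_FL")

    # drop states left unreachable (e.g. run-off chain when commit_prob = 1)
    targets = {t.target for t in transitions} | {t.source for t in transitions}
    states = [s for s in states if s.id in targets or s.id == f"ec@{spec.start_length}"]
    model = KineticModel(states, transitions)
    return model, bands


@lru_cache(maxsize=32)
def _expected_abundances_cached(spec_key: GelSpec) -> tuple[np.ndarray, np.ndarray]:
    spec = spec_key
    model, bands = _elongation_model(spec)
    p0 = model.initial_distribution(f"ec@{spec.start_length}")
    times = np.asarray(spec.stop_times, dtype=float)
    traj = propagate(model, p0, times, method="expm")
    expected = np.zeros((len(spec.species), times.size))
    for i, (name, _) in enumerate(spec.species):
        for sid in bands[name]:
            if sid in traj.state_ids:
                expected[i] += traj.population_of(sid)
    in_transit = 1.0 - expected.sum(axis=0)
    return expected, in_transit


def _expected_abundances(spec: GelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free band abundances and in-transit remainder per lane.

    Cached on the deterministic part of the spec: seed and noise level do not
    enter the expected abundances.
    """
    from dataclasses import replace

    return _expected_abundances_cached(replace(spec, seed=0, noise_cv=0.0))


@dataclass(frozen=True)
class GelTruth:
    """Ground-truth sidecar attached to a synthetic band table."""

    spec: GelSpec
    expected: tuple[tuple[float, ...], ...]  # noise-free band abundances
    in_transit: tuple[float, ...]  # mass between landmarks (gel smear), per lane

    def conservation(self) -> np.ndarray:
        """Band abundances plus in-transit mass, per lane (identically 1)."""
        return np.asarray(self.expected).sum(axis=0) + np.asarray(self.in_transit)


def generate_gel_timecourse(spec: GelSpec) -> BandTable:
    """Synthetic lane-by-band table from the elongation-with-pausing chain.

    Lane intensities are the expected band abundances times lognormal noise
    with unit mean and coefficient of variation ``noise_cv``.  A stop time
    earlier than the first possible product triggers an empty-lane warning.
    """
    expected, in_transit = _expected_abundances(spec)
    times = np.asarray(spec.stop_times, dtype=float)
    first_arrival = (min(ln for _, ln in spec.species) - spec.start_length) / spec.elongation_rate
    if times[0] < first_arrival and expected[:, 0].sum() < 1e-12:
        warnings.warn(
            f"lane at t={times[0]:g}s precedes the first possible product "
            f"(earliest arrival ~{first_arrival:.1f}s); lane will be empty",
            stacklevel=2,
        )
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sd_ln = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(-0.5 * sd_ln**2, sd_ln, size=expected.shape)
        intensities = expected * noise
    else:
        intensities = expected.copy()
    truth = GelTruth(
        spec=spec,
        expected=tuple(map(tuple, expected)),
        in_transit=tuple(in_transit),
    )
    return BandTable(times=times, species=spec.species, intensities=intensities, truth=truth)
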