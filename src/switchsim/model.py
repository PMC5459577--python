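"""State graph of co-transcriptional riboswitch folding.

The nascent transcript of a transcriptional guanine riboswitch is modelled as a
continuous-time Markov chain whose states are (chain length, conformation,
ligand status) triples.  Four strand blocks matter: the aptamer strand P, the
aptamer-stabilising strand A, the switching strand T and the terminator strand
H.  Conformations are coarse-grained by which of the mutually exclusive helices
are formed: the aptamer closing helix PA, the antiterminator AT (on-state) or
the terminator TH (off-state).  Synthesis transitions extend the chain one
nucleotide at a time at the elongation rate; a pause site divides the synthesis
rate inside its interval by a slowdown factor; folding and ligand-binding
transitions connect conformations at fixed length with first-order rate
constants measured in real-time kinetic experiments.

Two absorbing outcomes are attached where the terminator poly-U is completed
(the decision position): ``terminated`` (the off outcome, reached once the
terminator helix has annealed) and ``readthrough`` (the on outcome, reached by
antiterminator-folded or unstructured apo transcripts which do not stall the
polymerase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, ModelValidationError

HELICES = ("PA", "AT", "TH")
ROLES = ("elongating", "paused", "terminated", "readthrough")
TRANSITION_KINDS = ("synthesis", "folding", "ligand_binding", "termination_commit")

#: Absorbing outcome state ids.
TERMINATED = "terminated"
READTHROUGH = "readthrough"


@dataclass(frozen=True)
class StateSpec:
    """One node of the folding graph.

    ``position`` is the 1-based template position of the 3'-most synthesized
    nucleotide (transcription start = 1).  ``helices`` lists the helices formed
    in this conformation; PA and AT are mutually exclusive.
    """

    id: str
    position: int
    helices: frozenset[str] = frozenset()
    ligand_bound: bool = False
    role: str = "elongating"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("state id must be a non-empty string")
        if self.position < 1:
            raise ModelValidationError(f"state {self.id}: position must be >= 1")
        unknown = set(self.helices) - set(HELICES)
        if unknown:
            raise ModelValidationError(f"state {self.id}: unknown helices {sorted(unknown)}")
        if "PA" in self.helices and "AT" in self.helices:
            raise ModelValidationError(
                f"state {self.id}: PA and AT are mutually exclusive base pairings"
            )
        if self.role not in ROLES:
            raise ModelValidationError(f"state {self.id}: unknown role {self.role!r}")

    @property
    def absorbing(self) -> bool:
        return self.role in (TERMINATED, READTHROUGH)


@dataclass(frozen=True)
class TransitionSpec:
    """Directed first-order transition ``source -> target`` with rate in 1/s."""

    source: str
    target: str
    rate: float
    kind: str = "folding"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ModelValidationError(f"self-transition on {self.source}")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ModelValidationError(
                f"transition {self.source}->{self.target}: rate must be positive and "
                f"finite, got {self.rate!r}"
            )
        if self.kind not in TRANSITION_KINDS:
            raise ModelValidationError(
                f"transition {self.source}->{self.target}: unknown kind {self.kind!r}"
            )


@dataclass(frozen=True)
class RateTable:
    """Central values of the measured folding/binding rate constants (1/s).

    k_lig_bind
        pseudo-first-order ligand binding to the completed aptamer (apo -> holo).
    k_tert
        slow tertiary rearrangement inside the ligand-bound aptamer.
    k_TH_anneal
        terminator-helix annealing from single strands, [PA]TH -> [PA][TH].
    k_AT_anneal
        antiterminator annealing, [PA]T -> P[AT].
    k_AT_dissoc_apo
        rate-limiting AT dissociation on the apo pathway, P[AT]H -> [PA][TH].
    k_AT_dissoc_lig
        ligand-accelerated AT dissociation.
    k_refold_holo
        ligand-induced aptamer refolding on the combined pathway.
    k_AT_dissoc_combined
        rate-limiting AT dissociation on the combined pathway.
    """

    k_lig_bind: float = 0.24
    k_tert: float = 1.8e-2
    k_TH_anneal: float = 1.4e-1
    k_AT_anneal: float = 9e-3
    k_AT_dissoc_apo: float = 5e-4
    k_AT_dissoc_lig: float = 8.9e-4
    k_refold_holo: float = 2e-2
    k_AT_dissoc_combined: float = 1.2e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"rate {f.name} must be positive, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PauseSite:
    """Template interval (inclusive) over which synthesis is slowed."""

    start: int
    end: int
    factor: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigurationError(f"pause interval [{self.start}, {self.end}] is empty")
        if self.factor < 1:
            raise ConfigurationError(f"pause slowdown factor must be >= 1, got {self.factor}")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


#: Pause site 1, the U6 stretch between the aptamer and the switching strand.
DEFAULT_PS1 = PauseSite(start=107, end=112, factor=70.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one co-transcriptional folding simulation.

    Positions follow the single-round transcription-assay numbering: the time
    origin t = 0 sits at template position 75, the aptamer domain is complete
    at 89, the switching strand at 134, and the terminator poly-U at 164 (the
    decision position).  The elongation rate default of 20 nt/s is the apparent
    assay rate corrected to cellular NTP levels.
    """

    transcription_rate: float = 20.0
    pause_sites: tuple[PauseSite, ...] = (DEFAULT_PS1,)
    ligand_present: bool = False
    t_end: float = 600.0
    n_times: int = 601
    rtol: float = 1e-8
    atol: float = 1e-12
    start_position: int = 75
    aptamer_position: int = 89
    switch_position: int = 134
    decision_position: int = 164
    granularity: str = "nt"  # "nt" (per-nucleotide steps) or "segment"

    def __post_init__(self) -> None:
        if self.transcription_rate <= 0:
            raise ConfigurationError(
                f"transcription_rate must be positive, got {self.transcription_rate}"
            )
        if not (
            self.start_position
            < self.aptamer_position
            < self.switch_position
            < self.decision_position
        ):
            raise ConfigurationError("segment boundary positions must be strictly increasing")
        for ps in self.pause_sites:
            if ps.start < self.start_position or ps.end > self.decision_position:
                raise ModelValidationError(
                    f"pause interval [{ps.start}, {ps.end}] lies outside the transcript "
                    f"window [{self.start_position}, {self.decision_position}]"
                )
        if self.granularity not in ("nt", "segment"):
            raise ConfigurationError(f"unknown granularity {self.granularity!r}")
        if self.t_end <= 0 or self.n_times < 2:
            raise ConfigurationError("need t_end > 0 and at least two output times")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_times)

    def step_rate(self, position: int) -> float:
        """Per-nucleotide synthesis rate for the step leaving ``position``."""
        rate = self.transcription_rate
        for ps in self.pause_sites:
            if ps.covers(position):
                rate /= ps.factor
        return rate


class KineticModel:
    """Validated, indexed state graph ready for generator assembly."""

    def __init__(
        self,
        states: Iterable[StateSpec],
        transitions: Iterable[TransitionSpec],
        config: SimulationConfig | None = None,
        rates: RateTable | None = None,
    ) -> None:
        self.states: list[StateSpec] = list(states)
        self.transitions: list[TransitionSpec] = list(transitions)
        self.config = config
        self.rates = rates
        self.index: dict[str, int] = {s.id: i for i, s in enumerate(self.states)}
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if len(self.index) != len(self.states):
            dupes = [s.id for s in self.states if [t.id for t in self.states].count(s.id) > 1]
            raise ModelValidationError(f"duplicate state ids: {sorted(set(dupes))}")
        seen: set[tuple[str, str]] = set()
        for tr in self.transitions:
            for endpoint in (tr.source, tr.target):
                if endpoint not in self.index:
                    raise ModelValidationError(
                        f"transition references unknown state {endpoint!r}"
                    )
            key = (tr.source, tr.target)
            if key in seen:
                raise ModelValidationError(
                    f"duplicate transition {tr.source}->{tr.target}; rates are never "
                    "silently summed"
                )
            seen.add(key)
            src = self.states[self.index[tr.source]]
            dst = self.states[self.index[tr.target]]
            if src.absorbing:
                raise ModelValidationError(
                    f"absorbing state {src.id} must not have outgoing transitions"
                )
            if tr.kind == "synthesis" and dst.position <= src.position:
                raise ModelValidationError(
                    f"synthesis step {src.id}->{dst.id} must increase position"
                )
            if tr.kind != "synthesis" and dst.position < src.position:
                raise ModelValidationError(
                    f"transition {src.id}->{dst.id} decreases position"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def state(self, state_id: str) -> StateSpec:
        return self.states[self.index[state_id]]

    def initial_distribution(self, state_id: str | None = None) -> np.ndarray:
        """Point-mass start vector; defaults to the first state."""
        p0 = np.zeros(self.n_states)
        p0[self.index[state_id] if state_id else 0] = 1.0
        return p0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": [
                {
                    "id": s.id,
                    "position": s.position,
                    "helices": sorted(s.helices),
                    "ligand_bound": s.ligand_bound,
                    "role": s.role,
                }
                for s in self.states
            ],
            "transitions": [
                {"source": t.source, "target": t.target, "rate": float(t.rate), "kind": t.kind}
                for t in self.transitions
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "KineticModel":
        try:
            states = [
                StateSpec(
                    id=s["id"],
                    position=int(s["position"]),
                    helices=frozenset(s.get("helices", ())),
                    ligand_bound=bool(s.get("ligand_bound", False)),
                    role=s.get("role", "elongating"),
                )
                for s in payload["states"]
            ]
            transitions = [
                TransitionSpec(
                    source=t["source"],
                    target=t["target"],
                    rate=float(t["rate"]),
                    kind=t.get("kind", "folding"),
                )
                for t in payload["transitions"]
            ]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"model file missing key {exc}") from exc
        return cls(states, transitions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KineticModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default topology
# ---------------------------------------------------------------------------


def _conf_state(conf: str, pos: int, helices: Iterable[str], bound: bool, paused: bool = False) -> StateSpec:
    role = "paused" if paused else "elongating"
    return StateSpec(
        id=f"{conf}@{pos}", position=pos, helices=frozenset(helices), ligand_bound=bound, role=role
    )


def build_default_model(
    config: SimulationConfig | None = None, rates: RateTable | None = None
) -> KineticModel:
    """Assemble the default co-transcriptional folding topology.

    Without ligand the intermediates form a linear succession::

        P -> PA -> [PA]T -> P[AT] -> P[AT]H -> readthrough

    with the slow apo refolding P[AT]H -> [PA][TH] present as a side edge.
    With ligand the succession branches: the completed aptamer binds ligand
    (pseudo-first-order, k_lig_bind), locking strand A in the PA helix, and
    the bound branch runs lig[PA]T -> lig[PA]TH -> lig[PA][TH] -> terminated,
    the terminator annealing at k_TH_anneal while the polymerase is held at
    the terminator poly-U.  Ligand-accelerated AT dissociation and the
    combined refolding pathway connect the branches.

    Synthesis proceeds in per-nucleotide steps at ``transcription_rate``;
    steps whose source position lies inside a pause interval are divided by
    the pause factor.  ``granularity="segment"`` collapses each uniform block
    into a single exponential step of matching mean duration.
    """
    config = config or SimulationConfig()
    rates = rates or RateTable()
    if config.granularity == "segment":
        return _build_segment_model(config, rates)

    v = config.transcription_rate
    p_start, p_apt = config.start_position, config.aptamer_position
    p_switch, p_dec = config.switch_position, config.decision_position
    lig = config.ligand_present

    states: list[StateSpec] = []
    transitions: list[TransitionSpec] = []

    def add(tr: TransitionSpec) -> None:
        transitions.append(tr)

    def synth_chain(conf: str, helices: tuple[str, ...], bound: bool, lo: int, hi: int) -> None:
        """States conf@lo..hi and per-nt steps conf@p -> conf@p+1."""
        for p in range(lo, hi + 1):
            paused = any(ps.covers(p) for ps in config.pause_sites)
            states.append(_conf_state(conf, p, helices, bound, paused=paused))
        for p in range(lo, hi):
            add(TransitionSpec(f"{conf}@{p}", f"{conf}@{p + 1}", config.step_rate(p), "synthesis"))

    # unstructured leader, then aptamer-complete class
    synth_chain("P", (), False, p_start, p_apt - 1)
    synth_chain("PA", ("PA",), False, p_apt, p_switch - 1)
    add(TransitionSpec(f"P@{p_apt - 1}", f"PA@{p_apt}", config.step_rate(p_apt - 1), "synthesis"))

    # switching strand complete: apo antiterminator decision
    states.append(_conf_state("[PA]T", p_switch, ("PA",), False))
    add(
        TransitionSpec(
            f"PA@{p_switch - 1}", f"[PA]T@{p_switch}", config.step_rate(p_switch - 1), "synthesis"
        )
    )
    synth_chain("P[AT]", ("AT",), False, p_switch, p_dec)
    add(TransitionSpec(f"[PA]T@{p_switch}", f"P[AT]@{p_switch}", rates.k_AT_anneal, "folding"))

    # full-length apo off-state and outcomes
    states.append(_conf_state("[PA][TH]", p_dec, ("PA", "TH"), False))
    states.append(StateSpec(id=READTHROUGH, position=p_dec + 1, role="readthrough"))
    states.append(StateSpec(id=TERMINATED, position=p_dec, helices=frozenset(("PA", "TH")), role="terminated"))
    add(TransitionSpec(f"P[AT]@{p_dec}", f"[PA][TH]@{p_dec}", rates.k_AT_dissoc_apo, "folding"))
    add(TransitionSpec(f"P[AT]@{p_dec}", READTHROUGH, v, "synthesis"))
    add(TransitionSpec(f"[PA][TH]@{p_dec}", TERMINATED, v, "termination_commit"))

    if lig:
        # bound aptamer class (binding locks A; k_tert is a subsequent step)
        synth_chain("ligPA", ("PA",), True, p_apt, p_switch - 1)
        synth_chain("ligPA*", ("PA",), True, p_apt, p_switch - 1)
        for p in range(p_apt, p_switch):
            add(TransitionSpec(f"PA@{p}", f"ligPA@{p}", rates.k_lig_bind, "ligand_binding"))
            add(TransitionSpec(f"ligPA@{p}", f"ligPA*@{p}", rates.k_tert, "folding"))
        synth_chain("lig[PA]T", ("PA",), True, p_switch, p_dec)
        for conf in ("ligPA", "ligPA*"):
            add(
                TransitionSpec(
                    f"{conf}@{p_switch - 1}",
                    f"lig[PA]T@{p_switch}",
                    config.step_rate(p_switch - 1),
                    "synthesis",
                )
            )
        # ligand-accelerated AT dissociation rejoins the locked branch
        for p in range(p_switch, p_dec + 1):
            add(
                TransitionSpec(
                    f"P[AT]@{p}", f"lig[PA]T@{p}", rates.k_AT_dissoc_lig, "ligand_binding"
                )
            )
        # terminator annealing at the poly-U, then commitment
        states.append(_conf_state("lig[PA][TH]", p_dec, ("PA", "TH"), True))
        add(
            TransitionSpec(
                f"lig[PA]T@{p_dec}", f"lig[PA][TH]@{p_dec}", rates.k_TH_anneal, "folding"
            )
        )
        add(TransitionSpec(f"lig[PA][TH]@{p_dec}", TERMINATED, v, "termination_commit"))
        # combined pathway on the full-length antiterminator conformation
        states.append(_conf_state("ligP[AT]", p_dec, ("AT",), True))
        add(
            TransitionSpec(
                f"P[AT]@{p_dec}", f"ligP[AT]@{p_dec}", rates.k_refold_holo, "ligand_binding"
            )
        )
        add(
            TransitionSpec(
                f"ligP[AT]@{p_dec}",
                f"lig[PA][TH]@{p_dec}",
                rates.k_AT_dissoc_combined,
                "folding",
            )
        )

    return KineticModel(states, transitions, config=config, rates=rates)


def _build_segment_model(config: SimulationConfig, rates: RateTable) -> KineticModel:
    """Coarse variant: one exponential step per uniform synthesis block."""
    v = config.transcription_rate
    p_start, p_apt = config.start_position, config.aptamer_position
    p_switch, p_dec = config.switch_position, config.decision_position

    def block_rate(lo: int, hi: int) -> float:
        """Single-step rate matching the mean transit time of per-nt steps lo..hi-1."""
        mean_time = sum(1.0 / config.step_rate(p) for p in range(lo, hi))
        return 1.0 / mean_time

    states = [
        _conf_state("P", p_start, (), False),
        _conf_state("PA", p_apt, ("PA",), False),
        _conf_state("[PA]T", p_switch, ("PA",), False),
        _conf_state("P[AT]", p_switch, ("AT",), False),
        _conf_state("P[AT]", p_dec, ("AT",), False),
        _conf_state("[PA][TH]", p_dec, ("PA", "TH"), False),
        StateSpec(id=READTHROUGH, position=p_dec + 1, role="readthrough"),
        StateSpec(id=TERMINATED, position=p_dec, helices=frozenset(("PA", "TH")), role="terminated"),
    ]
    transitions = [
        TransitionSpec(f"P@{p_start}", f"PA@{p_apt}", block_rate(p_start, p_apt), "synthesis"),
        TransitionSpec(f"PA@{p_apt}", f"[PA]T@{p_switch}", block_rate(p_apt, p_switch), "synthesis"),
        TransitionSpec(f"[PA]T@{p_switch}", f"P[AT]@{p_switch}", rates.k_AT_anneal, "folding"),
        TransitionSpec(
            f"P[AT]@{p_switch}", f"P[AT]@{p_dec}", block_rate(p_switch, p_dec), "synthesis"
        ),
        TransitionSpec(f"P[AT]@{p_dec}", f"[PA][TH]@{p_dec}", rates.k_AT_dissoc_apo, "folding"),
        TransitionSpec(f"P[AT]@{p_dec}", READTHROUGH, v, "synthesis"),
        TransitionSpec(f"[PA][TH]@{p_dec}", TERMINATED, v, "termination_commit"),
    ]
    if config.ligand_present:
        states += [
            _conf_state("ligPA", p_apt, ("PA",), True),
            _conf_state("ligPA*", p_apt, ("PA",), True),
            _conf_state("lig[PA]T", p_switch, ("PA",), True),
            _conf_state("lig[PA]T", p_dec, ("PA",), True),
            _conf_state("lig[PA][TH]", p_dec, ("PA", "TH"), True),
            _conf_state("ligP[AT]", p_dec, ("AT",), True),
        ]
        transitions += [
            TransitionSpec(f"PA@{p_apt}", f"ligPA@{p_apt}", rates.k_lig_bind, "ligand_binding"),
            TransitionSpec(f"ligPA@{p_apt}", f"ligPA*@{p_apt}", rates.k_tert, "folding"),
            TransitionSpec(
                f"ligPA@{p_apt}", f"lig[PA]T@{p_switch}", block_rate(p_apt, p_switch), "synthesis"
            ),
            TransitionSpec(
                f"ligPA*@{p_apt}", f"lig[PA]T@{p_switch}", block_rate(p_apt, p_switch), "synthesis"
            ),
            TransitionSpec(
                f"lig[PA]T@{p_switch}",
                f"lig[PA]T@{p_dec}",
                block_rate(p_switch, p_dec),
                "synthesis",
            ),
            TransitionSpec(
                f"P[AT]@{p_switch}", f"lig[PA]T@{p_switch}", rates.k_AT_dissoc_lig, "ligand_binding"
            ),
            TransitionSpec(
                f"P[AT]@{p_dec}", f"lig[PA]T@{p_dec}", rates.k_AT_dissoc_lig, "ligand_binding"
            ),
            TransitionSpec(
                f"lig[PA]T@{p_dec}", f"lig[PA][TH]@{p_dec}", rates.k_TH_anneal, "folding"
            ),
            TransitionSpec(f"lig[PA][TH]@{p_dec}", TERMINATED, v, "termination_commit"),
            TransitionSpec(
                f"P[AT]@{p_dec}", f"ligP[AT]@{p_dec}", rates.k_refold_holo, "ligand_binding"
            ),
            TransitionSpec(
                f"ligP[AT]@{p_dec}",
                f"lig[PA][TH]@{p_dec}",
                rates.k_AT_dissoc_combined,
                "folding",
            ),
        ]
    return KineticModel(states, transitions, config=config, rates=rates)


def default_config_with(**overrides) -> SimulationConfig:
    """Convenience: the default configuration with selected fields replaced."""
    return replace(SimulationConfig(), **overrides)


def load_packaged_model() -> KineticModel:
    """The segment-granularity default model shipped with the package."""
    from importlib.resources import files

    path = files("switchsim").joinpath("data/default_model.yaml")
    return KineticModel.from_dict(yaml.safe_load(path.read_text()))
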