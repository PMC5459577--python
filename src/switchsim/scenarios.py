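"""Regulatory readout of folding trajectories and the four study scenarios.

The switching outcome is summarised by the ratio of on-state to off-state
probability over time: antiterminator-folded conformations and readthrough
count as *on* (the downstream gene is expressed), terminator-folded
conformations and terminated count as *off*.  The four scenarios cross ligand
presence with pausing at pause site 1, the comparison at the heart of the
kinetic-control argument: only the combination of ligand and pausing flips
the outcome to termination.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ClassificationError
from .model import (
    RateTable,
    SimulationConfig,
    StateSpec,
    KineticModel,
    build_default_model,
    READTHROUGH,
    TERMINATED,
)
from .simulate import Trajectory, propagate

Classification = Mapping[str, str] | Callable[[StateSpec], str]

#: Scenario keys: (ligand present, pausing active).
SCENARIO_NAMES: dict[tuple[bool, bool], str] = {
    (False, False): "no_ligand_no_pause",
    (False, True): "no_ligand_pause",
    (True, False): "ligand_no_pause",
    (True, True): "ligand_pause",
}


def classify_state(state: StateSpec) -> str:
    """Default on/off/neither mapping of a state."""
    if "AT" in state.helices or state.role == READTHROUGH:
        return "on"
    if "TH" in state.helices or state.role == TERMINATED:
        return "off"
    return "neither"


def _class_of(traj: Trajectory, model: KineticModel | None, classification: Classification | None):
    if classification is None:
        if model is None:
            raise ClassificationError("need a model or an explicit classification")
        return [classify_state(s) for s in model.states]
    out = []
    for sid in traj.state_ids:
        if callable(classification):
            if model is None:
                raise ClassificationError("callable classification requires the model")
            label = classification(model.state(sid))
        else:
            try:
                label = classification[sid]
            except KeyError as exc:
                raise ClassificationError(f"state {sid!r} is not classified") from exc
        if label not in ("on", "off", "neither"):
            raise ClassificationError(f"state {sid!r}: unknown class {label!r}")
        out.append(label)
    return out


def on_off_ratio(
    traj: Trajectory,
    model: KineticModel | None = None,
    classification: Classification | None = None,
    off_floor: float = 1e-12,
) -> np.ndarray:
    """P_on(t) / P_off(t); +inf wherever P_off falls below ``off_floor``."""
    labels = np.array(_class_of(traj, model, classification))
    p_on = traj.populations[labels == "on"].sum(axis=0)
    p_off = traj.populations[labels == "off"].sum(axis=0)
    ratio = np.full_like(p_on, np.inf)
    ok = p_off >= off_floor
    ratio[ok] = p_on[ok] / p_off[ok]
    return ratio


def class_populations(traj: Trajectory, model: KineticModel) -> dict[str, np.ndarray]:
    """Summed population of each regulatory class over time."""
    labels = np.array(_class_of(traj, model, None))
    return {c: traj.populations[labels == c].sum(axis=0) for c in ("on", "off", "neither")}


@dataclass
class ScenarioResult:
    """One panel of the four-scenario comparison."""

    name: str
    ligand: bool
    pausing: bool
    model: KineticModel
    trajectory: Trajectory
    ratio: np.ndarray
    ratio_at_decision: float
    terminal_probabilities: dict[str, float]

    def summary(self) -> dict:
        return {
            "scenario": self.name,
            "ligand": self.ligand,
            "pausing": self.pausing,
            "ratio_at_decision": self.ratio_at_decision,
            "terminal_probabilities": self.terminal_probabilities,
        }


def run_scenario(
    config: SimulationConfig,
    rates: RateTable | None = None,
    method: str = "expm",
) -> ScenarioResult:
    """Build and propagate one model; summarise its regulatory outcome.

    The on/off ratio "at the decision point" is evaluated at the end of the
    simulated regulation window, by which time essentially all probability
    has committed to an absorbing outcome under the default parameters.
    """
    model = build_default_model(config, rates)
    traj = propagate(model, method=method)
    ratio = on_off_ratio(traj, model)
    terminal = {
        TERMINATED: float(traj.population_of(TERMINATED)[-1]),
        READTHROUGH: float(traj.population_of(READTHROUGH)[-1]),
    }
    if terminal[TERMINATED] + terminal[READTHROUGH] > 1 + 1e-9:
        raise ClassificationError("absorbed mass exceeds 1")
    pausing = any(ps.factor > 1 for ps in config.pause_sites)
    name = SCENARIO_NAMES[(config.ligand_present, pausing)]
    return ScenarioResult(
        name=name,
        ligand=config.ligand_present,
        pausing=pausing,
        model=model,
        trajectory=traj,
        ratio=ratio,
        ratio_at_decision=float(ratio[-1]),
        terminal_probabilities=terminal,
    )


def run_scenarios(
    config: SimulationConfig | None = None,
    rates: RateTable | None = None,
    method: str = "expm",
) -> dict[tuple[bool, bool], ScenarioResult]:
    """The four (ligand x pausing) scenarios on a shared configuration.

    The -pause variants set every pause factor to 1, which reproduces the
    no-pausing model edge for edge.
    """
    base = config or SimulationConfig()
    results: dict[tuple[bool, bool], ScenarioResult] = {}
    for ligand in (False, True):
        for pausing in (False, True):
            sites = tuple(
                ps if pausing else replace(ps, factor=1.0) for ps in base.pause_sites
            )
            cfg = replace(base, ligand_present=ligand, pause_sites=sites)
            results[(ligand, pausing)] = run_scenario(cfg, rates, method=method)
    return results


def tidy_populations(
    results: Mapping[tuple[bool, bool], ScenarioResult], stride: int = 5
) -> pd.DataFrame:
    """Long-format table (scenario, time_s, state_id, probability)."""
    frames = []
    for res in results.values():
        traj = res.trajectory
        t = traj.times[::stride]
        pops = traj.populations[:, ::stride]
        frames.append(
            pd.DataFrame(
                {
                    "scenario": res.name,
                    "time_s": np.repeat(t, len(traj.state_ids)),
                    "state_id": np.tile(traj.state_ids, t.size),
                    "probability": pops.T.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
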