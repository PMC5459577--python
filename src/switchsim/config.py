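"""Run configuration: YAML loading with strict validation.

An empty file (or no file) yields the full default configuration — 20 nt/s
elongation, pause site 1 at U107–U112 slowed 70-fold, and the central values
of all measured rate constants.  Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .model import DEFAULT_PS1, PauseSite, RateTable, SimulationConfig

_SCENARIO_CHOICES = ("all", "no_ligand_no_pause", "no_ligand_pause", "ligand_no_pause", "ligand_pause")


@dataclass
class RunConfig:
    """Fully-resolved analysis configuration.

    The global ``seed`` deterministically derives every stage seed; the
    resolved configuration is echoed into every output directory.
    """

    seed: int = 17
    scenario: str = "all"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rates: RateTable = field(default_factory=RateTable)
    n_traces_per_rate: int = 25
    trace_snr: float = 20.0
    trace_points: int = 60
    gel_commit_minus_ligand: float = 0.45
    gel_commit_plus_ligand: float = 0.70
    gel_noise_cv: float = 0.05
    verbosity: int = 1

    def as_dict(self) -> dict:
        sim = {
            f.name: getattr(self.simulation, f.name)
            for f in fields(SimulationConfig)
            if f.name != "pause_sites"
        }
        sim["pause_sites"] = [
            {"start": ps.start, "end": ps.end, "factor": ps.factor}
            for ps in self.simulation.pause_sites
        ]
        return {
            "seed": self.seed,
            "scenario": self.scenario,
            "simulation": sim,
            "rates": self.rates.as_dict(),
            "n_traces_per_rate": self.n_traces_per_rate,
            "trace_snr": self.trace_snr,
            "trace_points": self.trace_points,
            "gel_commit_minus_ligand": self.gel_commit_minus_ligand,
            "gel_commit_plus_ligand": self.gel_commit_plus_ligand,
            "gel_noise_cv": self.gel_noise_cv,
            "verbosity": self.verbosity,
        }


def _check_keys(section: str, payload: dict, allowed: set[str]) -> None:
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}"
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML run configuration; absent values fall back to defaults."""
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        payload = loaded
    return config_from_dict(payload)


def config_from_dict(payload: dict) -> RunConfig:
    top_allowed = {
        "seed",
        "scenario",
        "simulation",
        "rates",
        "n_traces_per_rate",
        "trace_snr",
        "trace_points",
        "gel_commit_minus_ligand",
        "gel_commit_plus_ligand",
        "gel_noise_cv",
        "verbosity",
    }
    _check_keys("config", payload, top_allowed)

    sim_payload = dict(payload.get("simulation") or {})
    sim_allowed = {f.name for f in fields(SimulationConfig)}
    _check_keys("simulation", sim_payload, sim_allowed)
    if "pause_sites" in sim_payload:
        sites = []
        for entry in sim_payload["pause_sites"]:
            _check_keys("pause_sites entry", dict(entry), {"start", "end", "factor"})
            sites.append(PauseSite(**entry))
        sim_payload["pause_sites"] = tuple(sites)
    simulation = replace(SimulationConfig(), **sim_payload)

    rate_payload = dict(payload.get("rates") or {})
    _check_keys("rates", rate_payload, {f.name for f in fields(RateTable)})
    rates = replace(RateTable(), **rate_payload)

    scenario = payload.get("scenario", "all")
    if scenario not in _SCENARIO_CHOICES:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; choose one of {_SCENARIO_CHOICES}"
        )

    cfg = RunConfig(
        seed=int(payload.get("seed", 17)),
        scenario=scenario,
        simulation=simulation,
        rates=rates,
        n_traces_per_rate=int(payload.get("n_traces_per_rate", 25)),
        trace_snr=float(payload.get("trace_snr", 20.0)),
        trace_points=int(payload.get("trace_points", 60)),
        gel_commit_minus_ligand=float(payload.get("gel_commit_minus_ligand", 0.45)),
        gel_commit_plus_ligand=float(payload.get("gel_commit_plus_ligand", 0.70)),
        gel_noise_cv=float(payload.get("gel_noise_cv", 0.05)),
        verbosity=int(payload.get("verbosity", 1)),
    )
    for name, lo in (("n_traces_per_rate", 1), ("trace_points", 8)):
        if getattr(cfg, name) < lo:
            raise ConfigurationError(f"{name} must be >= {lo}")
    if cfg.trace_snr <= 0:
        raise ConfigurationError("trace_snr must be positive")
    for name in ("gel_commit_minus_ligand", "gel_commit_plus_ligand"):
        if not 0.0 <= getattr(cfg, name) <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    return cfg


def echo_config(cfg: RunConfig, outdir: str | Path) -> Path:
    """Write the fully-resolved configuration into an output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "resolved_config.yaml"
    target.write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
    return target
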