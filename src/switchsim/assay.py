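"""Quantitation of time-resolved single-round transcription assays.

A single-round transcription time course is quantified from a gel as a
lane-by-band intensity table: each lane is a stop time, each band an RNA
species of known length (paused intermediates, the terminated product, the
full-length run-off transcript).  From such a table this module computes

* normalized pause fractions — a band's intensity divided by the summed
  intensity of all species of the same length or longer in that lane,
* pause parameters t1/2, tau and kp from the post-peak decay of the fraction,
* apparent transcription rates in nt/s from saturating-exponential product
  appearance, using rate = length x k_app,
* termination efficiency %T = 100 I_T / (I_T + I_FL) and its change upon
  ligand addition, and
* Miller units for the beta-galactosidase reporter assay.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError
from .fitting import TimeTrace, fit_monoexp

#: Species presets (name, length in nt).  ``single_round`` is the
#: time-resolved single-round assay numbering; ``multi_round`` the overnight
#: multiple-round gel numbering of the same template.
SPECIES_PRESETS: dict[str, tuple[tuple[str, int], ...]] = {
    "single_round": (
        ("FL", 214),
        ("T", 164),
        ("PS2", 141),
        ("PS1", 110),
        ("RNA95", 95),
        ("RNA90", 90),
        ("RNA77", 77),
    ),
    "multi_round": (
        ("FL", 228),
        ("T", 172),
        ("PS2", 152),
        ("PS1", 124),
        ("APT", 96),
    ),
}


@dataclass
class BandTable:
    """Lanes (stop times) x bands (species) intensity matrix, a.u. >= 0."""

    times: np.ndarray
    species: tuple[tuple[str, int], ...]
    intensities: np.ndarray  # (n_species, n_times)
    truth: object | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.species), self.times.size):
            raise ConfigurationError("intensities must be (n_species, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("lane stop times must be strictly increasing")
        if self.intensities.min() < 0:
            raise ConfigurationError("band intensities must be non-negative")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.species]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([ln for _, ln in self.species])

    def row(self, name: str) -> np.ndarray:
        return self.intensities[self.names.index(name)]

    # -- TSV round trip: first column species, second length_nt, remaining
    #    columns intensities headed by the stop time in seconds --------------
    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        df = pd.DataFrame(
            self.intensities,
            index=pd.Index(self.names, name="species"),
            columns=[f"{t:g}" for t in self.times],
        )
        df.insert(0, "length_nt", self.lengths)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "BandTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = df.pop("length_nt").astype(int)
        times = np.array([float(c) for c in df.columns])
        species = tuple(zip(df.index.tolist(), lengths.tolist()))
        return cls(times=times, species=species, intensities=df.to_numpy(float))


def pause_fraction_series(table: BandTable, species_name: str) -> np.ma.MaskedArray:
    """Normalized pause fraction of one species over the lanes.

    fraction(t) = I_species(t) / sum of I over species of equal or greater
    length.  Lanes whose denominator is zero are masked, not zeroed.
    """
    if species_name not in table.names:
        raise ConfigurationError(f"species {species_name!r} not in table")
    length = dict(table.species)[species_name]
    include = table.lengths >= length
    denom = table.intensities[include].sum(axis=0)
    masked = denom <= 0
    frac = np.ma.masked_array(np.zeros_like(denom), mask=masked)
    frac[~masked] = table.row(species_name)[~masked] / denom[~masked]
    return frac


@dataclass
class PauseParams:
    """Pause-escape parameters; tau = 1/kp and t1/2 = ln2/kp by definition."""

    t_half: float
    tau: float
    kp: float
    stderr_kp: float | None = None

    @classmethod
    def from_kp(cls, kp: float, stderr_kp: float | None = None) -> "PauseParams":
        return cls(t_half=np.log(2.0) / kp, tau=1.0 / kp, kp=kp, stderr_kp=stderr_kp)


def pause_parameters(
    times: np.ndarray, fractions: np.ndarray | np.ma.MaskedArray
) -> PauseParams | None:
    """Pause parameters from the post-peak decay of a normalized pause fraction.

    A single exponential A exp(-kp t) is fitted to the lanes at and after the
    fraction's peak; kp is the pause-escape rate.  A series that never decays
    (the band only accumulates — a polymerase blocking point rather than a
    pause) returns ``None``.
    """
    times = np.asarray(times, dtype=float)
    fr = np.ma.masked_invalid(np.ma.asarray(fractions))
    ok = ~np.ma.getmaskarray(fr)
    t, f = times[ok], np.asarray(fr[ok], dtype=float)
    if t.size < 4:
        raise FitError("need at least 4 defined lanes to determine pause parameters")
    peak = int(np.argmax(f))
    post_t, post_f = t[peak:], f[peak:]
    if post_t.size < 3 or post_f[-1] >= 0.95 * post_f[0] or post_f[0] <= 0:
        return None  # monotone accumulation: blocking point, no escape decay
    # log-linear initialisation, then least squares on A exp(-kp t)
    pos = post_f > 0
    slope, intercept = np.polyfit(post_t[pos], np.log(post_f[pos]), 1)
    kp0 = max(-slope, 1e-9)
    from scipy.optimize import curve_fit

    def model(tt, a, kp):
        return a * np.exp(-kp * tt)

    popt, pcov = curve_fit(
        model, post_t, post_f, p0=(np.exp(intercept), kp0), maxfev=20000
    )
    kp = float(popt[1])
    if kp <= 0:
        return None
    se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else None
    return PauseParams.from_kp(kp, se)


@dataclass
class RateEstimate:
    """Apparent product-appearance rate converted to nt/s via the length."""

    k_app: float
    length: int
    rate: float  # nt/s, = length * k_app
    uncertainty: float | None  # nt/s
    i_max: float
    non_saturating: bool = False


def apparent_rate(
    times: np.ndarray,
    intensities: np.ndarray,
    length: int,
    i_max: float | None = None,
) -> RateEstimate:
    """Fit saturating product appearance I(t) = I_max (1 - exp(-k_app t)).

    ``rate = length * k_app`` converts the apparent first-order constant to a
    transcription rate in nt/s (the conversion convention is isolated in
    :func:`kapp_to_rate` so it can be swapped).  When the series has not
    saturated within the observation window, an externally known maximum can
    be supplied via ``i_max`` (it enters the fit as a fixed plateau);
    otherwise the result is flagged ``non_saturating`` and carries a wide
    uncertainty.
    """
    if length <= 0:
        raise ConfigurationError("length must be positive")
    times = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    # rewrite as plateau + A exp(-k t) with A = -I_max and reuse the trace fitter
    if i_max is not None:
        trace = TimeTrace(times=times, intensities=y - i_max, direction="rise")
        fit = fit_monoexp(trace, fit_plateau=False)
        imax = float(i_max)
    else:
        trace = TimeTrace(times=times, intensities=y, direction="rise")
        fit = fit_monoexp(trace, fit_plateau=True)
        imax = float(fit.plateau)
    k_app = float(fit.rates[0])
    se_k = fit.stderr_rates[0]
    non_sat = bool(y[-1] < 0.9 * imax) if imax > 0 else True
    if non_sat:
        warnings.warn(
            "product appearance did not saturate within the observation window; "
            "k_app is poorly constrained (consider supplying i_max)",
            stacklevel=2,
        )
    unc = kapp_to_rate(float(se_k), length) if np.isfinite(se_k or np.nan) else None
    return RateEstimate(
        k_app=k_app,
        length=length,
        rate=kapp_to_rate(k_app, length),
        uncertainty=unc,
        i_max=imax,
        non_saturating=non_sat,
    )


def kapp_to_rate(k_app: float, length: int) -> float:
    """nt/s from an apparent first-order appearance constant: length * k_app."""
    return length * k_app


def termination_efficiency(
    table: BandTable,
    terminated: str = "T",
    full_length: str = "FL",
    g_counts: dict[str, int] | None = None,
) -> float:
    """Termination efficiency in percent at the final lane.

    %T = 100 I_T / (I_T + I_FL).  With body labelling the raw intensity of a
    species is proportional to its G count times its molarity; supplying
    ``g_counts`` divides each intensity by the species' G count first (off by
    default — raw band signals are quantified as printed).
    """
    for name in (terminated, full_length):
        if name not in table.names:
            raise ConfigurationError(f"species {name!r} not in table")
    i_t = float(table.row(terminated)[-1])
    i_fl = float(table.row(full_length)[-1])
    if g_counts is not None:
        i_t /= g_counts[terminated]
        i_fl /= g_counts[full_length]
    if i_t + i_fl == 0:
        raise ConfigurationError(
            "termination efficiency undefined: terminated and full-length bands "
            "are both zero in the final lane"
        )
    return 100.0 * i_t / (i_t + i_fl)


def termination_difference(
    minus_ligand: BandTable, plus_ligand: BandTable, **kwargs
) -> dict[str, float]:
    """Ligand-induced change of termination efficiency.

    Returns both readings of "increased by x%": the absolute percentage-point
    difference and the relative increase in percent.
    """
    t_minus = termination_efficiency(minus_ligand, **kwargs)
    t_plus = termination_efficiency(plus_ligand, **kwargs)
    return {
        "percent_minus_ligand": t_minus,
        "percent_plus_ligand": t_plus,
        "absolute_points": t_plus - t_minus,
        "relative_percent": 100.0 * (t_plus - t_minus) / t_minus if t_minus else np.inf,
    }


@dataclass(frozen=True)
class MillerInput:
    """Plate-reader absorbances with reaction time t (min) and volume V (mL)."""

    A420: float
    A550: float
    A600: float
    t: float
    V: float

    def __post_init__(self) -> None:
        if self.t <= 0 or self.V <= 0 or self.A600 <= 0:
            raise ConfigurationError("t, V and A600 must all be positive")


def miller_units(x: MillerInput) -> float:
    """Beta-galactosidase activity: 1000 (A420 - 1.75 A550) / (t V A600).

    The chromophore reading is debris-corrected by 1.75 x A550; a negative
    result (over-corrected blank) is returned as-is with a warning.
    """
    mu = 1000.0 * (x.A420 - 1.75 * x.A550) / (x.t * x.V * x.A600)
    if mu < 0:
        warnings.warn("negative Miller units: A420 < 1.75 * A550", stacklevel=2)
    return mu
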