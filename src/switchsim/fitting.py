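"""Mono- and bi-exponential relaxation fitting for kinetic time traces.

Real-time kinetic experiments on individual base-pair reporter signals yield
(time, intensity) traces that relax mono-exponentially (a single underlying
process) or bi-exponentially (two distinguishable processes, e.g. fast
ligand-induced aptamer refolding followed by rate-limiting antiterminator
dissociation).  This module fits both model orders by least squares, selects
the order with an extra-sum-of-squares F-test guarded by a minimum rate
separation, and aggregates fitted rates per structural motif.

The optimisation uses variable projection: for fixed rate constants the model
is linear in plateau and amplitudes, so those are solved exactly and only the
(log-)rates are searched, from a deterministic multi-start grid.  A final
full-parameter polish with lmfit supplies the covariance-based standard
errors.  Intensities are normalised to their maximum magnitude before fitting
and the amplitudes rescaled afterwards, so results are exactly equivariant
under intensity scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError

logger = logging.getLogger(__name__)

MOTIFS = ("ligand_binding", "PA", "AT", "TH")

MIN_POINTS_MONO = 8
MIN_POINTS_BI = 12
#: rate separation below which a bi-exponential optimum is flagged degenerate
COLLAPSE_RATIO = 1.05


@dataclass
class TimeTrace:
    """A kinetic time trace for one resolved signal.

    ``sigma`` is the (single) noise standard deviation of the trace in the
    same units as the intensities; when absent, :func:`estimate_noise` can
    supply a robust estimate.
    """

    times: np.ndarray
    intensities: np.ndarray
    sigma: float | None = None
    signal_id: str = ""
    motif: str | None = None
    direction: str = "decay"
    truth: object | None = None  # generator ground truth, attached by synthetic data

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise FitError("times and intensities must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise FitError("times must be strictly increasing and non-negative")
        if self.motif is not None and self.motif not in MOTIFS:
            raise FitError(f"unknown motif {self.motif!r}")

    @property
    def n_points(self) -> int:
        return self.times.size


@dataclass
class FitResult:
    """Parameters of a mono- (order 1) or bi-exponential (order 2) fit.

    Rates are sorted fast-to-slow (k[0] > k[1] for order 2) with amplitudes
    matched; standard errors come from the covariance of the polished
    least-squares fit.  ``flags`` may contain ``"indistinguishable"`` when a
    bi-exponential optimum collapsed (k1/k2 < 1.05).
    """

    order: int
    plateau: float
    amplitudes: np.ndarray
    rates: np.ndarray
    stderr_plateau: float | None
    stderr_amplitudes: np.ndarray
    stderr_rates: np.ndarray
    rss: float
    n_points: int
    n_varied: int
    signal_id: str = ""
    motif: str | None = None
    flags: tuple[str, ...] = ()
    selection: dict = field(default_factory=dict)

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.full_like(t, self.plateau)
        for a, k in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-k * t)
        return out


def estimate_noise(trace: TimeTrace) -> float:
    """Robust noise standard deviation of a trace.

    If the trace carries an explicit ``sigma`` it is returned unchanged.
    Otherwise the estimate is 1.4826 * MAD of the second differences divided
    by sqrt(6): second-differencing annihilates the smooth relaxation up to
    curvature and inflates white noise by sqrt(6).
    """
    if trace.sigma is not None:
        return float(trace.sigma)
    if trace.n_points < 4:
        raise FitError("need at least 4 points to estimate noise")
    d2 = np.diff(trace.intensities, n=2)
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


# ---------------------------------------------------------------------------
# variable projection machinery
# ---------------------------------------------------------------------------


def _design(t: np.ndarray, ks: np.ndarray, plateau: bool) -> np.ndarray:
    ks = np.clip(ks, 1e-14, 1e10)
    cols = [np.exp(np.clip(-k * t, -700.0, 0.0)) for k in ks]
    if plateau:
        cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _varpro_solve(t: np.ndarray, y: np.ndarray, ks: np.ndarray, plateau: bool):
    """Exact linear coefficients and RSS for fixed rate constants."""
    a = _design(t, ks, plateau)
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    r = y - a @ coef
    return float(r @ r), coef


def _rate_bounds(t: np.ndarray) -> tuple[float, float]:
    span = t[-1] - t[0]
    dt = np.min(np.diff(t))
    return 0.05 / span, 50.0 / dt


def _scan_mono_rate(t: np.ndarray, y: np.ndarray, plateau: bool, n_grid: int = 60) -> float:
    k_lo, k_hi = _rate_bounds(t)
    grid = np.geomspace(k_lo, k_hi, n_grid)
    rss = [_varpro_solve(t, y, np.array([k]), plateau)[0] for k in grid]
    return float(grid[int(np.argmin(rss))])


def _refine_rates(t: np.ndarray, y: np.ndarray, ks0: np.ndarray, plateau: bool) -> np.ndarray:
    """Gauss-Newton refinement of log-rates with projected linear part."""

    def resid(log_k):
        a = _design(t, np.exp(np.clip(log_k, -40.0, 25.0)), plateau)
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        return y - a @ coef

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            resid, np.log(ks0), method="lm", xtol=1e-13, ftol=1e-13, max_nfev=2000
        )
    return np.exp(np.clip(sol.x, -40.0, 25.0))


# ---------------------------------------------------------------------------
# lmfit polish (standard errors) and packaging
# ---------------------------------------------------------------------------


def _exp_model(params: Parameters, t: np.ndarray, order: int) -> np.ndarray:
    out = np.full_like(t, params["plateau"].value)
    for i in range(1, order + 1):
        out = out + params[f"a{i}"].value * np.exp(-params[f"k{i}"].value * t)
    return out


def _polish(t, y, plateau0, amps0, ks0, order, fit_plateau):
    params = Parameters()
    params.add("plateau", value=plateau0, vary=fit_plateau)
    for i, (a, k) in enumerate(zip(amps0, ks0), start=1):
        params.add(f"a{i}", value=a)
        params.add(f"k{i}", value=max(k, 1e-12), min=1e-14, max=1e8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = minimize(
            lambda p: _exp_model(p, t, order) - y,
            params,
            method="leastsq",
            ftol=1e-13,
            xtol=1e-13,
            maxfev=5000,
        )
    return out


def _package(out, order, scale, n, fit_plateau, signal_id, motif, flags=()) -> FitResult:
    p = out.params
    rates = np.array([p[f"k{i}"].value for i in range(1, order + 1)])
    amps = np.array([p[f"a{i}"].value for i in range(1, order + 1)]) * scale
    se_k = np.array([p[f"k{i}"].stderr or np.nan for i in range(1, order + 1)])
    se_a = np.array([(p[f"a{i}"].stderr or np.nan) * scale for i in range(1, order + 1)])
    idx = np.argsort(rates)[::-1]  # fast first
    se_plat = p["plateau"].stderr
    return FitResult(
        order=order,
        plateau=float(p["plateau"].value) * scale,
        amplitudes=amps[idx],
        rates=rates[idx],
        stderr_plateau=None if se_plat is None else float(se_plat) * scale,
        stderr_amplitudes=se_a[idx],
        stderr_rates=se_k[idx],
        rss=float(np.sum(out.residual**2)) * scale**2,
        n_points=n,
        n_varied=2 * order + int(fit_plateau),
        signal_id=signal_id,
        motif=motif,
        flags=tuple(flags),
    )


def fit_monoexp(trace: TimeTrace, fit_plateau: bool = True) -> FitResult:
    """Least-squares fit of I(t) = plateau + A exp(-k t).

    The rate is located on a logarithmic grid with exactly-solved linear
    parameters, refined by Gauss-Newton, and polished with lmfit for the
    covariance-based standard errors.
    """
    if trace.n_points < MIN_POINTS_MONO:
        raise FitError(f"mono-exponential fit needs >= {MIN_POINTS_MONO} points")
    t, y = trace.times, trace.intensities
    scale = float(np.max(np.abs(y))) or 1.0
    yn = y / scale
    try:
        k0 = _scan_mono_rate(t, yn, fit_plateau)
        ks = _refine_rates(t, yn, np.array([k0]), fit_plateau)
        rss, coef = _varpro_solve(t, yn, ks, fit_plateau)
        plateau0 = float(coef[-1]) if fit_plateau else 0.0
        out = _polish(t, yn, plateau0, coef[:1], ks, 1, fit_plateau)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitError(
            f"mono-exponential fit failed for {trace.signal_id!r}: {exc}; "
            f"grid bounds k in [{_rate_bounds(t)[0]:.3g}, {_rate_bounds(t)[1]:.3g}] 1/s"
        ) from exc
    if not out.success or not np.isfinite(out.params["k1"].value):
        raise FitError(
            f"mono-exponential fit failed for {trace.signal_id!r}: {out.message}; "
            f"init k={k0:.3g} 1/s, bounds k in (1e-14, 1e8)"
        )
    return _package(out, 1, scale, trace.n_points, fit_plateau, trace.signal_id, trace.motif)


def _biexp_starts(t: np.ndarray, yn: np.ndarray, fit_plateau: bool):
    """Deterministic multi-start rate pairs bracketing the mono solution."""
    km = _scan_mono_rate(t, yn, fit_plateau)
    pairs = [
        (km * 3, km / 3),
        (km * 10, km / 10),
        (km * 30, km / 30),
        (km * 1.2, km / 1.2),
        (km * 20, km),
        (km, km / 50),
    ]
    # exhaustive coarse pair grid catches components far from the mono rate;
    # the best few distinct cells are all refined
    k_lo, k_hi = _rate_bounds(t)
    grid = np.geomspace(k_lo, k_hi, 18)
    cand = [(a, b) for i, a in enumerate(grid) for b in grid[: i + 1]]
    rss = np.array([_varpro_solve(t, yn, np.array(p), fit_plateau)[0] for p in cand])
    pairs.extend(cand[j] for j in np.argsort(rss)[:3])
    return pairs


def fit_biexp(trace: TimeTrace, fit_plateau: bool = True) -> FitResult:
    """Fit I(t) = plateau + A1 exp(-k1 t) + A2 exp(-k2 t), with k1 > k2.

    Deterministic multi-starts (including a coarse exhaustive rate-pair grid)
    guard against local minima.  If the optimum has k1/k2 < 1.05 the result
    is flagged ``indistinguishable`` and callers should fall back to the
    mono-exponential fit.
    """
    if trace.n_points < MIN_POINTS_BI:
        raise FitError(f"bi-exponential fit needs >= {MIN_POINTS_BI} points")
    t, y = trace.times, trace.intensities
    scale = float(np.max(np.abs(y))) or 1.0
    yn = y / scale

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for pair in _biexp_starts(t, yn, fit_plateau):
        try:
            ks = _refine_rates(t, yn, np.array(pair), fit_plateau)
            rss, coef = _varpro_solve(t, yn, ks, fit_plateau)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or rss < best[0]:
            best = (rss, ks, coef)
    if best is None:
        raise FitError(f"bi-exponential fit failed for {trace.signal_id!r} from all starts")
    rss, ks, coef = best
    plateau0 = float(coef[-1]) if fit_plateau else 0.0
    out = _polish(t, yn, plateau0, coef[:2], ks, 2, fit_plateau)
    if not out.success:
        raise FitError(f"bi-exponential polish failed for {trace.signal_id!r}: {out.message}")
    flags = []
    k_sorted = sorted((out.params["k1"].value, out.params["k2"].value), reverse=True)
    if k_sorted[1] > 0 and k_sorted[0] / k_sorted[1] < COLLAPSE_RATIO:
        flags.append("indistinguishable")
    return _package(
        out, 2, scale, trace.n_points, fit_plateau, trace.signal_id, trace.motif, flags
    )


def f_test(mono: FitResult, bi: FitResult) -> tuple[float, float]:
    """Extra-sum-of-squares F statistic and p-value for order 2 vs order 1."""
    extra = bi.n_varied - mono.n_varied
    df2 = bi.n_points - bi.n_varied
    if df2 <= 0 or extra <= 0:
        raise FitError("too few points for the F-test")
    num = max(mono.rss - bi.rss, 0.0) / extra
    den = bi.rss / df2
    if den == 0:
        return np.inf, 0.0
    f = num / den
    return float(f), float(stats.f.sf(f, extra, df2))


def select_model(
    trace: TimeTrace,
    alpha: float = 0.05,
    min_rate_ratio: float = 3.0,
    fit_plateau: bool = True,
) -> FitResult:
    """Fit both orders and choose between them.

    The bi-exponential model is accepted only when the extra-sum-of-squares
    F-test rejects the mono-exponential at ``alpha`` *and* the fitted rates
    are separated by more than ``min_rate_ratio`` (two rates closer than that
    are not distinguishable in practice).  The decision statistics and
    thresholds are recorded on the returned result.
    """
    mono = fit_monoexp(trace, fit_plateau=fit_plateau)
    scale = float(np.max(np.abs(trace.intensities))) or 1.0
    # a mono fit at round-off level cannot be improved meaningfully
    if mono.rss <= (1e-10 * scale) ** 2 * trace.n_points:
        mono.selection = {
            "f_statistic": np.nan,
            "p_value": np.nan,
            "rate_ratio": np.nan,
            "alpha": alpha,
            "min_rate_ratio": min_rate_ratio,
            "order_chosen": 1,
            "bi_fit_error": None,
        }
        return mono
    bi_error: str | None = None
    try:
        bi = fit_biexp(trace, fit_plateau=fit_plateau)
        f, p = f_test(mono, bi)
        ratio = float(bi.rates[0] / bi.rates[1]) if bi.rates[1] > 0 else np.inf
        amp = np.abs(bi.amplitudes)
        meaningful = amp.min() > 1e-6 * amp.max()
        accept = (
            p < alpha
            and ratio > min_rate_ratio
            and meaningful
            and "indistinguishable" not in bi.flags
        )
    except FitError as exc:
        bi, f, p, ratio, accept = None, np.nan, np.nan, np.nan, False
        bi_error = str(exc)
    chosen = bi if accept else mono
    chosen.selection = {
        "f_statistic": f,
        "p_value": p,
        "rate_ratio": ratio,
        "alpha": alpha,
        "min_rate_ratio": min_rate_ratio,
        "order_chosen": chosen.order,
        "bi_fit_error": bi_error,
    }
    return chosen


@dataclass
class MotifRateSummary:
    """Per-motif aggregation of fitted rates across signals.

    ``mean_rates``/``sd_rates`` are indexed by rank (fast first).  With mixed
    fit orders within a motif, rates are matched by rank and a warning is
    logged; a single-signal motif reports sd 0 with a ``single_signal`` flag.
    """

    motif: str
    mean_rates: np.ndarray
    sd_rates: np.ndarray
    per_signal_rates: list[np.ndarray]
    n_signals: int
    flags: tuple[str, ...] = ()


def aggregate_motif_rates(results: list[FitResult]) -> dict[str, MotifRateSummary]:
    """Unweighted per-motif mean and standard deviation of fitted rates."""
    by_motif: dict[str, list[FitResult]] = {}
    for r in results:
        if r.motif is None:
            raise FitError(f"fit result {r.signal_id!r} carries no motif label")
        by_motif.setdefault(r.motif, []).append(r)

    summaries: dict[str, MotifRateSummary] = {}
    for motif, group in by_motif.items():
        flags = []
        orders = {r.order for r in group}
        if len(orders) > 1:
            logger.warning(
                "motif %s mixes fit orders %s; matching rates by rank (fast with fast)",
                motif,
                sorted(orders),
            )
            flags.append("mixed_orders")
        n_ranks = max(orders)
        means, sds = [], []
        for rank in range(n_ranks):
            vals = np.array([r.rates[rank] for r in group if r.order > rank])
            means.append(vals.mean())
            sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
            if vals.size == 1:
                flags.append("single_signal")
        summaries[motif] = MotifRateSummary(
            motif=motif,
            mean_rates=np.array(means),
            sd_rates=np.array(sds),
            per_signal_rates=[r.rates.copy() for r in group],
            n_signals=len(group),
            flags=tuple(dict.fromkeys(flags)),
        )
    return summaries
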