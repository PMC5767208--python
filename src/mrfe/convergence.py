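"""PMF convergence diagnostics and outlier flagging.

Umbrella sampling is treated as a quasi-static process that gradually fixes
the errors introduced by the preceding non-equilibrium pull.  If the error
fixing rate is proportional to the amount of error left, the pooled work
estimate follows a saturating exponential

    ΔW(t) = C₀ − C₁·(1 − exp(−k·t)),      lim_{t→∞} ΔW(t) = C₀ − C₁,

whose asymptote extrapolates the estimate to infinite sampling time.  A
healthy estimation shows a small-but-nonzero route spread σ_ΔW and a small
positive decay coefficient k; across a compound set, robust z-scores of
σ_ΔW and k single out the estimations that deserve re-simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .pmf import PMFProfile, UmbrellaWindow, combine_routes, pmf_work, wham

__all__ = [
    "ConvergenceTrace",
    "ConvergenceFit",
    "ConvergenceFitError",
    "pmf_timeseries",
    "fit_convergence",
    "flag_outliers",
    "decay_model",
    "read_trace",
    "write_trace",
]

FLAG_OK = "ok"
FLAG_SIGMA = "suspicious-sigma"
FLAG_K = "suspicious-k"
FLAG_NON_DECAYING = "non-decaying"


class ConvergenceFitError(RuntimeError):
    """Exponential-decay fit failed; carries the initialization and residuals."""

    def __init__(self, message: str, init: tuple, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


@dataclass
class ConvergenceTrace:
    """ΔW as a function of accumulated simulation time for one compound."""

    t: np.ndarray  # ns, strictly increasing
    dw: np.ndarray  # kJ/mol
    compound_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.dw = np.asarray(self.dw, dtype=float)
        if self.t.size < 4:
            raise ValueError("trace needs at least 4 checkpoints")
        if self.t.shape != self.dw.shape:
            raise ValueError("t and dw length mismatch")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("checkpoints must be strictly increasing")


@dataclass(frozen=True)
class ConvergenceFit:
    """(C₀, C₁, k) of the decay model, the implied asymptote C₀ − C₁, and
    the fit RMSE.  ``k_identifiable`` is False for flat traces where k
    carries no information."""

    c0: float  # kJ/mol
    c1: float  # kJ/mol
    k: float  # ns⁻¹
    rmse: float  # kJ/mol
    k_identifiable: bool = True

    @property
    def asymptote(self) -> float:
        return self.c0 - self.c1


def decay_model(t, c0: float, c1: float, k: float):
    """ΔW(t) = C₀ − C₁·(1 − exp(−k·t))."""
    t = np.asarray(t, dtype=float)
    return c0 - c1 * (1.0 - np.exp(-k * t))


def fit_convergence(trace: ConvergenceTrace) -> ConvergenceFit:
    """Nonlinear least-squares fit of the decay model to a ΔW(t) trace.

    Initialization: C₀ = ΔW(t₀), C₁ = ΔW(t₀) − ΔW(t_end), k = 1/t_end.
    k is unconstrained in sign — a negative k (divergence) is itself a
    diagnostic.  A constant trace short-circuits to C₁ = 0 with k marked
    unidentifiable.
    """
    t, dw = trace.t, trace.dw
    k0 = 1.0 / float(t[-1])
    init = (float(dw[0]), float(dw[0] - dw[-1]), k0)
    if np.ptp(dw) == 0.0:
        return ConvergenceFit(c0=float(dw[0]), c1=0.0, k=k0, rmse=0.0, k_identifiable=False)

    def residual(p):
        return decay_model(t, *p) - dw

    # Variable projection: for fixed k the model is linear in (C₀, C₁), so
    # scan k over a signed log grid, solve the 2-parameter linear problem
    # exactly, and polish the best candidate with Levenberg–Marquardt.  A
    # plain 3-parameter descent from one start routinely slides into the
    # degenerate k→0 ridge (|C₁|→∞ with C₁·k finite), which fits a noisy
    # plateau equally well but extrapolates to a nonsense asymptote.
    k_grid = np.concatenate([[0.0], k0 * np.logspace(-2, 3, 40),
                             -k0 * np.logspace(-2, 2, 20)])
    starts = [init]
    best_lin = None
    for k_try in k_grid:
        basis = 1.0 - np.exp(-k_try * t)
        a = np.stack([np.ones_like(t), -basis], axis=1)
        coef, *_ = np.linalg.lstsq(a, dw, rcond=None)
        rmse_lin = float(np.sqrt(np.mean((a @ coef - dw) ** 2)))
        if np.isfinite(rmse_lin) and (best_lin is None or rmse_lin < best_lin[0]):
            best_lin = (rmse_lin, (float(coef[0]), float(coef[1]), float(k_try)))
    if best_lin is not None and best_lin[1][2] != 0.0:
        starts.append(best_lin[1])

    best = None
    failure = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0=x0, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception as exc:  # pragma: no cover - scipy failure path
            failure = exc
            continue
        if not np.isfinite(res.x).all():
            continue
        rmse = float(np.sqrt(np.mean(residual(res.x) ** 2)))
        if best is None or rmse < best[0] - 1e-12:
            best = (rmse, res.x)
    if best is None:
        raise ConvergenceFitError(f"optimizer failure: {failure}", init) from failure
    rmse, x = best
    c0, c1, k = (float(v) for v in x)
    return ConvergenceFit(c0=c0, c1=c1, k=k, rmse=rmse)


def pmf_timeseries(
    routes: Sequence[Sequence[UmbrellaWindow]] | Sequence[UmbrellaWindow],
    checkpoints: Sequence[float],
    duration_ns: float,
    bound_region: tuple[float, float] = (0.0, 0.1),
    burn_in: float = 0.1,
    method: str = "arithmetic",
    compound_id: str = "",
    grid: Optional[np.ndarray] = None,
) -> ConvergenceTrace:
    """Prefix-wise ΔW(t): re-run WHAM + work extraction on each window's
    sample prefix up to checkpoint t, then pool the routes.

    ``routes`` is a list of window sets (one per parallel route) or a single
    window set.  Samples are assumed uniform in time across ``duration_ns``;
    the first ``burn_in`` fraction of each prefix is discarded as
    equilibration.  Checkpoints that leave some window empty are skipped
    with a warning.
    """
    if routes and isinstance(routes[0], UmbrellaWindow):
        routes = [list(routes)]  # type: ignore[list-item]
    if duration_ns <= 0:
        raise ValueError("duration_ns must be positive")
    ts, dws = [], []
    for t_chk in checkpoints:
        if t_chk > duration_ns + 1e-9:
            raise ValueError(f"checkpoint {t_chk} ns exceeds window duration {duration_ns} ns")
        frac = t_chk / duration_ns
        route_dws = []
        ok = True
        for windows in routes:
            prefix_windows = []
            for w in windows:
                n = int(round(frac * w.samples.size))
                n0 = int(np.floor(burn_in * n))
                if n - n0 < 1:
                    ok = False
                    break
                prefix_windows.append(
                    UmbrellaWindow(w.center, w.spring_k, w.samples[n0:n], w.temperature)
                )
            if not ok:
                break
            profile = wham(prefix_windows, grid=grid)
            route_dws.append(pmf_work(profile, bound_region=bound_region).value)
        if not ok:
            warnings.warn(f"checkpoint {t_chk} ns leaves an empty window; skipped", stacklevel=2)
            continue
        dw, _ = combine_routes(route_dws, method=method)
        ts.append(t_chk)
        dws.append(dw)
    return ConvergenceTrace(np.asarray(ts), np.asarray(dws), compound_id=compound_id)


def _robust_z(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median/MAD z-scores; second return is False when MAD = 0 (fallback)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        return np.zeros_like(values), False
    return (values - med) / (1.4826 * mad), True


def flag_outliers(
    fits: Sequence[ConvergenceFit],
    sigmas: Sequence[float],
    z_threshold: float = 2.0,
) -> list[set[str]]:
    """Per-compound diagnostic flags from population statistics.

    Robust (median/MAD) z-scores of σ_ΔW and of k across the set; values
    with |z| above ``z_threshold`` receive the corresponding suspicious
    flag, and any k ≤ 0 is flagged non-decaying.  Flags are unioned; an
    empty union reports {'ok'}.  When the MAD vanishes the z-score falls
    back to rank extremes (any value differing from the median), with a
    warning.
    """
    if len(fits) < 3 or len(fits) != len(sigmas):
        raise ValueError("need >= 3 compounds with one sigma per fit")
    sig = np.asarray([float(s) for s in sigmas])
    ks = np.asarray([f.k for f in fits])
    flags: list[set[str]] = [set() for _ in fits]
    for values, flag in ((sig, FLAG_SIGMA), (ks, FLAG_K)):
        z, ok = _robust_z(values)
        if ok:
            for i in np.flatnonzero(np.abs(z) > z_threshold):
                flags[i].add(flag)
        else:
            warnings.warn(
                f"zero MAD for {flag}; falling back to rank-based extremes", stacklevel=2
            )
            med = np.median(values)
            for i in np.flatnonzero(values != med):
                flags[i].add(flag)
    for i, f in enumerate(fits):
        if f.k <= 0:
            flags[i].add(FLAG_NON_DECAYING)
    return [f if f else {FLAG_OK} for f in flags]


def write_trace(trace: ConvergenceTrace) -> str:
    lines = ["# t_ns  dW_kJ_per_mol"]
    for t, dw in zip(trace.t, trace.dw):
        lines.append(f"{t:.6f} {dw:.6f}")
    return "\n".join(lines) + "\n"


def read_trace(text: str, compound_id: str = "") -> ConvergenceTrace:
    t, dw = [], []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        a, b = s.split()[:2]
        t.append(float(a))
        dw.append(float(b))
    return ConvergenceTrace(np.asarray(t), np.asarray(dw), compound_id=compound_id)
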