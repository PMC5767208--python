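"""Umbrella-sampling PMF estimation and standard-state binding free energy.

The reaction coordinate z (nm) is the ligand–site separation.  Biased
window samples are combined into one unbiased profile W(z) with the WHAM
self-consistent equations; parallel dissociation routes give independent
work estimates ΔW_i that are pooled either arithmetically (preferred for a
handful of routes, where large spread is interpreted as error) or by
exponential work averaging, which bounds the free energy from above via
Jensen's inequality.  The pooled ΔW is converted to ΔG° at 1 M standard
concentration (V° ≈ 1661 ų per molecule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "R_GAS_KJ",
    "UmbrellaWindow",
    "PMFProfile",
    "PMFEnsemble",
    "StandardStateCal",
    "PMFWork",
    "ConnectivityError",
    "WHAMConvergenceError",
    "standard_volume_A3",
    "STANDARD_VOLUME_A3",
    "default_wham_grid",
    "wham",
    "pmf_work",
    "combine_routes",
    "build_ensemble",
    "standard_dg",
    "standard_dg_integral",
    "fit_kw_cv",
    "read_window_series",
    "write_profile",
    "read_profile",
]

#: Gas constant, kJ mol⁻¹ K⁻¹.
R_GAS_KJ = 8.314462618e-3

#: Avogadro constant, mol⁻¹ (2019 SI exact value).
AVOGADRO = 6.02214076e23


def standard_volume_A3() -> float:
    """Volume per molecule at the 1 M standard concentration, in ų.

    V° = 1 / (N_A · 1 mol/L) expressed in ų (1 L = 10²⁷ ų) ≈ 1661 ų.
    """
    litres_per_molecule = 1.0 / AVOGADRO
    return litres_per_molecule * 1e27


STANDARD_VOLUME_A3 = standard_volume_A3()


class ConnectivityError(ValueError):
    """Adjacent umbrella windows share no sampled bins."""


class WHAMConvergenceError(RuntimeError):
    """WHAM self-consistency iteration did not reach tolerance."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3g} kJ/mol)"
        )
        self.residual = residual


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint ½·spring_k·(z−center)² plus
    the sampled reaction-coordinate values (nm)."""

    center: float  # nm
    spring_k: float  # kJ mol⁻¹ nm⁻²
    samples: np.ndarray  # nm
    temperature: float = 310.0  # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(z, dtype=float) - self.center) ** 2


@dataclass
class PMFProfile:
    """W(z) on a strictly increasing grid, minimum-shifted to 0; unsampled
    grid points carry NaN."""

    z: np.ndarray  # nm
    w: np.ndarray  # kJ/mol

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.w.shape:
            raise ValueError("z and w must be 1-D arrays of equal length")
        if not (np.diff(self.z) > 0).all():
            raise ValueError("z grid must be strictly increasing")

    def sampled(self) -> tuple[np.ndarray, np.ndarray]:
        mask = np.isfinite(self.w)
        return self.z[mask], self.w[mask]


@dataclass
class PMFEnsemble:
    """Parallel route estimates with their pooled ΔW and spread σ_ΔW."""

    profiles: list[PMFProfile]
    dw_values: np.ndarray
    dw_mean: float
    dw_sigma: float
    route_probs: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dw_values = np.asarray(self.dw_values, dtype=float)
        if self.route_probs is not None:
            p = np.asarray(self.route_probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("route_probs must be non-negative and sum to 1")
            self.route_probs = p
        if self.dw_sigma < 0:
            raise ValueError("dw_sigma must be >= 0")


@dataclass(frozen=True)
class StandardStateCal:
    """Empirical bound-state factor k_w and volume-normalization offset C_V
    relating pooled work to standard binding free energy."""

    k_w: float = 1.0
    c_v: float = 0.0  # kJ/mol
    v_std: float = STANDARD_VOLUME_A3  # ų

    def __post_init__(self):
        if self.k_w <= 0:
            raise ValueError("k_w must be positive")


@dataclass(frozen=True)
class PMFWork:
    """Route work estimate ΔW with a plateau diagnostic."""

    value: float  # kJ/mol
    plateaued: bool = True

    def __float__(self) -> float:
        return self.value


def default_wham_grid(windows: Sequence[UmbrellaWindow], bin_width: float = 0.02) -> np.ndarray:
    """Bin centres: ``bin_width`` (default 0.02 nm) over
    [min center − 0.2, max center + 0.2] nm."""
    lo = min(w.center for w in windows) - 0.2
    hi = max(w.center for w in windows) + 0.2
    n = int(np.ceil((hi - lo) / bin_width))
    return lo + (np.arange(n) + 0.5) * bin_width


def wham(
    windows: Sequence[UmbrellaWindow],
    grid: Optional[np.ndarray] = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    min_count: int = 10,
) -> PMFProfile:
    """Weighted-histogram analysis of biased windows into one PMF.

    Iterates the standard self-consistent equations

        P(z) = Σ_j h_j(z) / Σ_j N_j exp((f_j − u_j(z))/RT),
        f_j  = −RT ln Σ_z P(z) exp(−u_j(z)/RT),

    until the largest change in any window free energy f_j is below ``tol``
    (kJ/mol).  W(z) = −RT ln P(z), minimum-shifted to 0.  Requires every
    pair of center-adjacent windows to share at least one sampled bin.

    Bins holding fewer than ``min_count`` total samples are histogram
    noise (their −RT·ln of a tiny count swings by several RT) and are
    reported as unsampled (NaN) rather than letting a stray tail count
    anchor the minimum shift.
    """
    if len(windows) == 0:
        raise ValueError("no windows")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        warnings.warn("multiple window temperatures; WHAM assumes a single T (using mean)")
    rt = R_GAS_KJ * float(np.mean([w.temperature for w in windows]))

    centers = default_wham_grid(windows) if grid is None else np.asarray(grid, dtype=float)
    width = np.diff(centers)
    if not (width > 0).all():
        raise ValueError("grid must be strictly increasing")
    edges = np.concatenate(
        [[centers[0] - width[0] / 2], (centers[:-1] + centers[1:]) / 2, [centers[-1] + width[-1] / 2]]
    )

    hist = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows]).astype(float)
    _check_overlap(windows, hist)

    n_j = hist.sum(axis=1)  # samples per window
    h_total = hist.sum(axis=0)  # counts per bin
    bias = np.stack([w.bias(centers) for w in windows])  # (J, Z)
    c = np.exp(-bias / rt)

    f = np.zeros(len(windows))
    residual = np.inf
    for _ in range(max_iter):
        denom = (n_j[:, None] * np.exp(f / rt)[:, None] * c).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, h_total / denom, 0.0)
        norm = (c * p[None, :]).sum(axis=1)
        f_new = -rt * np.log(norm)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise WHAMConvergenceError(residual, max_iter)

    supported = h_total >= max(min_count, 1)
    with np.errstate(divide="ignore"):
        w_vals = np.where(supported, -rt * np.log(np.where(supported, p, 1.0)), np.nan)
    w_vals = w_vals - np.nanmin(w_vals)
    return PMFProfile(centers, w_vals)


def _check_overlap(windows: Sequence[UmbrellaWindow], hist: np.ndarray) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise ConnectivityError(
                "no histogram overlap between adjacent windows centred at "
                f"{windows[a].center:.3f} and {windows[b].center:.3f} nm"
            )


def pmf_work(
    profile: PMFProfile,
    bound_region: tuple[float, float] = (0.0, 0.1),
    plateau_frac: float = 0.2,
    slope_threshold: float = 5.0,
) -> PMFWork:
    """Dissociation work ΔW of one route (kJ/mol).

    ΔW = max W over the plateau region (final ``plateau_frac`` of the
    sampled z range) − mean W over ``bound_region``.  If the final segment
    still has |slope| above ``slope_threshold`` kJ/mol/nm the profile has
    not plateaued and the result is flagged.
    """
    z, w = profile.sampled()
    if z.size < 2:
        raise ValueError("profile has fewer than 2 sampled points")
    lo, hi = bound_region
    bound_mask = (z >= lo) & (z <= hi)
    if not bound_mask.any():
        raise ValueError("bound_region lies outside the sampled support")
    z_start = z[-1] - plateau_frac * (z[-1] - z[0])
    tail = z >= z_start
    value = float(w[tail].max() - w[bound_mask].mean())
    plateaued = True
    if tail.sum() >= 2:
        slope = np.polyfit(z[tail], w[tail], 1)[0]
        plateaued = bool(abs(slope) <= slope_threshold)
    return PMFWork(value, plateaued)


def combine_routes(
    dws: Sequence[float],
    T: float = 310.0,
    method: str = "arithmetic",
) -> tuple[float, float]:
    """Pool parallel route estimates ΔW_i into (ΔW, σ_ΔW).

    ``arithmetic``: plain mean — preferred for a handful of routes, where
    spread is read as error.  ``jarzynski``: −RT·ln(mean exp(−ΔW_i/RT)),
    the exponential work average; by Jensen's inequality it never exceeds
    the arithmetic mean, with equality iff all ΔW_i are equal.
    """
    dws = np.asarray([float(d) for d in dws], dtype=float)
    if dws.size < 1:
        raise ValueError("need at least one route estimate")
    if T <= 0:
        raise ValueError("temperature must be positive")
    sigma = float(np.std(dws, ddof=1)) if dws.size > 1 else 0.0
    if method == "arithmetic":
        return float(dws.mean()), sigma
    if method == "jarzynski":
        rt = R_GAS_KJ * T
        # log-sum-exp for numerical safety
        m = (-dws / rt).max()
        val = -rt * (m + np.log(np.mean(np.exp(-dws / rt - m))))
        return float(val), sigma
    raise ValueError(f"unknown method {method!r}")


def build_ensemble(
    profiles: Sequence[PMFProfile],
    bound_region: tuple[float, float] = (0.0, 0.1),
    T: float = 310.0,
    method: str = "arithmetic",
    route_probs: Optional[Sequence[float]] = None,
) -> PMFEnsemble:
    """Bundle parallel route profiles into a :class:`PMFEnsemble`.

    Extracts each route's ΔW, pools with :func:`combine_routes` (uniform
    route probabilities by default — the arithmetic mean) and records the
    spread σ_ΔW.
    """
    dws = [pmf_work(p, bound_region=bound_region).value for p in profiles]
    dw_mean, dw_sigma = combine_routes(dws, T=T, method=method)
    probs = None if route_probs is None else np.asarray(route_probs, dtype=float)
    return PMFEnsemble(
        profiles=list(profiles), dw_values=np.asarray(dws),
        dw_mean=dw_mean, dw_sigma=dw_sigma, route_probs=probs,
    )


def standard_dg(dw: float, cal: StandardStateCal, T: float = 310.0) -> float:
    """Standard binding free energy from pooled work:
    ΔG° = −RT·ln(k_w·exp(−ΔW/RT)) − C_V  (≡ ΔW − RT·ln k_w − C_V)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS_KJ * T
    return float(-rt * (np.log(cal.k_w) + (-float(dw) / rt)) - cal.c_v)


def standard_dg_integral(
    profile: PMFProfile,
    bound_region: tuple[float, float],
    v_unbound: float,
    T: float = 310.0,
    include_minus_one: bool = True,
    v_std: float = STANDARD_VOLUME_A3,
) -> float:
    """Standard binding free energy from the profile itself:

        ΔG° = −RT·ln[ ∫(exp(−W(z)/RT) − 1)dz / ∫_bound dz ]
              − RT·ln(V_unbound / V°).

    Trapezoidal integration on the sampled grid; the −1 term (negligible
    where W ≫ 0) is switchable.  ``v_unbound`` and ``v_std`` in ų.
    """
    if T <= 0 or v_unbound <= 0:
        raise ValueError("temperature and v_unbound must be positive")
    z, w = profile.sampled()
    rt = R_GAS_KJ * T
    integrand = np.exp(-w / rt) - (1.0 if include_minus_one else 0.0)
    numerator = float(np.trapezoid(integrand, z))
    if numerator <= 0:
        raise ValueError("bound-state integral is non-positive over the sampled range")
    lo, hi = bound_region
    if hi <= lo:
        raise ValueError("empty bound_region")
    dg_pmf = -rt * np.log(numerator / (hi - lo))
    dg_v = -rt * np.log(v_unbound / v_std)
    return float(dg_pmf + dg_v)


def fit_kw_cv(
    references: Sequence[tuple[object, float]],
    T: float = 310.0,
    bound_region: tuple[float, float] = (0.0, 0.1),
    k_w: Optional[float] = None,
) -> tuple[StandardStateCal, np.ndarray]:
    """Calibrate the standard-state constants against known affinities.

    Each reference is (profile-or-ΔW, ΔG_exp kJ/mol).  In the relation
    ΔG° = ΔW − RT·ln k_w − C_V only the combined offset RT·ln k_w + C_V is
    identifiable (the two constants enter as one additive term), so the
    fit is gauge-fixed: ``k_w`` is held at the supplied value (default 1)
    and C_V absorbs the offset by least squares.  Returns the calibration
    and the per-reference residuals.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 references")
    if T <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS_KJ * T
    dws, dgs = [], []
    for ref, dg_exp in references:
        if isinstance(ref, PMFProfile):
            dws.append(pmf_work(ref, bound_region=bound_region).value)
        else:
            dws.append(float(ref))
        dgs.append(float(dg_exp))
    dws = np.asarray(dws)
    dgs = np.asarray(dgs)
    kw = 1.0 if k_w is None else float(k_w)
    if kw <= 0:
        raise ValueError("k_w gauge must be positive")
    # ΔG_exp = ΔW − RT ln k_w − C_V  ⇒  C_V = mean(ΔW − RT ln k_w − ΔG_exp)
    c_v = float(np.mean(dws - rt * np.log(kw) - dgs))
    cal = StandardStateCal(k_w=kw, c_v=c_v)
    residuals = np.array([standard_dg(dw, cal, T) - dg for dw, dg in zip(dws, dgs)])
    return cal, residuals


# ---------------------------------------------------------------------------
# Text I/O (GROMACS pullx-compatible dialect: '#'/'@' headers skipped)

def read_window_series(text: str) -> np.ndarray:
    """Read a two-column (time ps, ξ nm) series; returns the ξ values."""
    vals = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.split()
        vals.append(float(parts[1] if len(parts) > 1 else parts[0]))
    if not vals:
        raise ValueError("empty window series")
    return np.asarray(vals)


def write_profile(profile: PMFProfile) -> str:
    lines = ["# z_nm  W_kJ_per_mol"]
    for z, w in zip(profile.z, profile.w):
        lines.append(f"{z:.6f} {w:.6f}")
    return "\n".join(lines) + "\n"


def read_profile(text: str) -> PMFProfile:
    z, w = [], []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        a, b = s.split()[:2]
        z.append(float(a))
        w.append(float(b))
    return PMFProfile(np.asarray(z), np.asarray(w))
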