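"""Replica-weighted linear interaction energy (LIE) scoring.

A single replica's binding free energy estimate is a linear form over its
time-averaged interaction energies and an entropy term,

    ΔG_i = α⟨U_lig^Coul⟩_i + β⟨U_lig^LJ⟩_i + γ⟨U_site^Coul⟩_i + δ⟨U_site^LJ⟩_i + ε·S_i,

replicas are combined through self-referential weights

    w_i = ΔG_i / (k·ΣΔG),     Σw_i = 1/k,

and the pooled estimate applies the same coefficients to the
weight-averaged observables.  With k = 0.2 (the protocol default) equal
replicas pool to ΔG_single/k.  Coefficients are fitted to experimental
affinities by iterated reweighted linear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ReplicaObservables",
    "LIEParams",
    "LIETrainingRecord",
    "DEFAULT_LIE_PARAMS",
    "DegenerateWeightsError",
    "SingularFitError",
    "replica_dg",
    "replica_weights",
    "weighted_lie",
    "fit_lie_params",
    "quasi_harmonic_entropy",
    "read_energy_table",
]

#: Gas constant, J mol⁻¹ K⁻¹ (entropy terms are carried in J/mol/K).
R_GAS_J = 8.314462618


class DegenerateWeightsError(ZeroDivisionError):
    """ΣΔG = 0: replica weights are undefined."""


class SingularFitError(np.linalg.LinAlgError):
    """Design matrix of the LIE fit is rank-deficient."""


@dataclass(frozen=True)
class ReplicaObservables:
    """Time-averaged observables of one MD replica (kJ/mol; S in J/mol/K)."""

    u_lig_coul: float
    u_lig_lj: float
    u_site_coul: float
    u_site_lj: float
    entropy_s: float

    def __post_init__(self):
        vec = self.as_vector()
        if not np.isfinite(vec).all():
            raise ValueError("observables must be finite")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.u_lig_coul, self.u_lig_lj, self.u_site_coul, self.u_site_lj, self.entropy_s],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, v) -> "ReplicaObservables":
        v = np.asarray(v, dtype=float)
        return cls(*v.tolist())


@dataclass(frozen=True)
class LIEParams:
    """Regression coefficients α..ε, weighting constant k and the optional
    reference offsets U₀ for the binding-site energy terms.

    ``u0_mode`` controls where the offsets enter: ``"none"`` (default) uses
    the raw site averages; ``"site"`` subtracts (u0_coul, u0_lj) from the
    site Coulomb/LJ terms before weighting.  The published parameter set
    lists the offsets alongside the coefficients without fixing their
    application point, so it stays configurable.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float
    k: float = 0.2
    u0_coul: float = 0.0
    u0_lj: float = 0.0
    u0_mode: str = "none"

    def __post_init__(self):
        if self.k == 0:
            raise ValueError("k must be nonzero")
        if self.u0_mode not in ("none", "site"):
            raise ValueError("u0_mode must be 'none' or 'site'")

    def coefficients(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta, self.epsilon])


#: Reference coefficient set, fitted on a 12-complex nuclear-receptor
#: training set (benzimidazole-dominated), with its reference offsets;
#: the protocol default.
DEFAULT_LIE_PARAMS = LIEParams(
    alpha=-0.059274,
    beta=0.343518,
    gamma=0.012304,
    delta=0.110224,
    epsilon=-0.00003,
    k=0.2,
    u0_coul=6418.28,
    u0_lj=-1458.75,
)


@dataclass
class LIETrainingRecord:
    """Replica observables of one compound plus its experimental ΔG (kJ/mol)."""

    replicas: list[ReplicaObservables]
    dg_exp: float
    label: str = ""

    def __post_init__(self):
        if len(self.replicas) < 1:
            raise ValueError("record needs at least one replica")


def _observable_matrix(replicas: Sequence[ReplicaObservables], params: LIEParams) -> np.ndarray:
    """(n_replicas, 5) matrix of observables with U₀ offsets applied."""
    x = np.stack([r.as_vector() for r in replicas])
    if params.u0_mode == "site":
        x = x.copy()
        x[:, 2] -= params.u0_coul
        x[:, 3] -= params.u0_lj
    return x


def replica_dg(obs: ReplicaObservables, params: LIEParams) -> float:
    """Single-replica estimate ΔG_i (kJ/mol): the linear form α..ε over the
    replica's observables."""
    x = _observable_matrix([obs], params)[0]
    return float(x @ params.coefficients())


def replica_weights(dgs: Sequence[float], k: float) -> np.ndarray:
    """Self-referential weights w_i = ΔG_i/(k·ΣΔG); Σw_i = 1/k exactly.

    Weights are not confined to [0, 1] — sign-mixed ΔG_i legitimately push
    them outside; a warning is emitted when any |w_i| > 10.
    """
    dgs = np.asarray(dgs, dtype=float)
    total = dgs.sum()
    if total == 0.0:
        raise DegenerateWeightsError("sum of replica ΔG values is zero")
    w = dgs / (k * total)
    if np.abs(w).max() > 10.0:
        warnings.warn("extreme replica weight |w| > 10 (sign-mixed ΔG set?)", stacklevel=2)
    return w


def weighted_lie(replicas: Sequence[ReplicaObservables], params: LIEParams) -> float:
    """Pooled multi-replica estimate ΔG_LIE (kJ/mol).

    Two-pass evaluation: per-replica ΔG_i fix the weights, then the
    coefficients are applied to the weight-averaged observables.  With one
    replica the result is ΔG_single/k (since Σw = 1/k).
    """
    if len(replicas) < 1:
        raise ValueError("need at least one replica")
    x = _observable_matrix(replicas, params)
    theta = params.coefficients()
    dgs = x @ theta
    w = replica_weights(dgs, params.k)
    return float((w @ x) @ theta)


def fit_lie_params(
    records: Sequence[LIETrainingRecord],
    k: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 100,
    u0_coul: float = 0.0,
    u0_lj: float = 0.0,
    u0_mode: str = "none",
    free: Optional[Sequence[bool]] = None,
) -> tuple[LIEParams, np.ndarray]:
    """Fit α..ε against experimental affinities.

    The replica weights depend on the coefficients, so the fit iterates:
    freeze the weights, solve the linear least-squares problem for α..ε,
    recompute the weights, repeat until the coefficient change falls below
    ``tol`` (or ``max_iter``).  Returns the fitted parameters and the
    per-record residuals ΔG_LIE − ΔG_exp.

    ``free`` is a 5-element mask selecting which coefficients to fit;
    masked-out coefficients are pinned to 0 (useful for reduced models,
    e.g. a dispersion-only fit of β).
    """
    mask = np.ones(5, dtype=bool) if free is None else np.asarray(free, dtype=bool)
    if mask.shape != (5,) or not mask.any():
        raise ValueError("free must be a 5-element mask with at least one True")
    if len(records) < int(mask.sum()) + 1:
        raise ValueError("need more records than free coefficients")
    probe = LIEParams(0, 0, 0, 0, 0.5, k=k, u0_coul=u0_coul, u0_lj=u0_lj, u0_mode=u0_mode)
    xs = [_observable_matrix(r.replicas, probe) for r in records]
    y = np.array([r.dg_exp for r in records])

    def solve(design):
        theta_full = np.zeros(5)
        theta_full[mask] = _solve_lstsq(design[:, mask], y)
        return theta_full

    # Start from uniform weights (w_i = 1/(k n), consistent with Σw = 1/k).
    theta = solve(np.stack([x.mean(axis=0) / k for x in xs]))
    for _ in range(max_iter):
        rows = []
        for x in xs:
            dgs = x @ theta
            w = replica_weights(dgs, k)
            rows.append(w @ x)
        design = np.stack(rows)
        theta_new = solve(design)
        # per-coefficient relative change: ε is orders of magnitude smaller
        # than β, so an absolute criterion would abandon it early
        change = np.abs(theta_new - theta) / np.maximum(np.abs(theta_new), 1e-300)
        theta = theta_new
        if np.max(change) < tol:
            break
    params = LIEParams(*theta.tolist(), k=k, u0_coul=u0_coul, u0_lj=u0_lj, u0_mode=u0_mode)
    residuals = np.array([weighted_lie(r.replicas, params) - r.dg_exp for r in records])
    return params, residuals


def _solve_lstsq(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularFitError("rank-deficient LIE design matrix")
    theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return theta


def quasi_harmonic_entropy(
    ligand_frames: np.ndarray,
    variance_floor: float = 1e-10,
) -> float:
    """Quasi-harmonic rigid-body entropy of a ligand pose time series.

    ``ligand_frames`` is (n_frames, 6): 3 translational coordinates (Å) and
    3 orientation angles (rad) per frame (mass/inertia weighting, if
    desired, is applied by the caller).  Under the multivariate-Gaussian
    assumption

        S = (R/2)·ln det(2πe·Σ̂)   [J mol⁻¹ K⁻¹],

    with Σ̂ the 6×6 sample covariance.  Degenerate directions are floored
    at ``variance_floor`` (with a warning) instead of failing.
    """
    frames = np.asarray(ligand_frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != 6:
        raise ValueError("ligand_frames must be (n_frames, 6)")
    if frames.shape[0] < 10:
        raise ValueError("need at least 10 frames")
    cov = np.cov(frames.T)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < variance_floor:
        warnings.warn("singular pose covariance; flooring eigenvalues", stacklevel=2)
        eig = np.maximum(eig, variance_floor)
    return float(0.5 * R_GAS_J * np.sum(np.log(2.0 * np.pi * np.e * eig)))


def read_energy_table(text: str) -> ReplicaObservables:
    """Average a whitespace-delimited replica energy table into observables.

    Columns: time (ps), ligand Coulomb, ligand LJ, site Coulomb, site LJ
    (kJ/mol).  Lines starting with ``#`` or ``@`` are skipped.  The entropy
    term is not part of the table and is returned as 0; callers supply it
    from :func:`quasi_harmonic_entropy`.
    """
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.split()
        if len(parts) < 5:
            raise ValueError(f"line {ln}: expected 5 columns (time + 4 energies)")
        rows.append([float(p) for p in parts[:5]])
    if not rows:
        raise ValueError("empty energy table")
    arr = np.asarray(rows)
    means = arr[:, 1:5].mean(axis=0)
    return ReplicaObservables(*means.tolist(), entropy_s=0.0)
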