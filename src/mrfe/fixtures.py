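"""Seeded synthetic generators standing in for the MD and docking engines.

Every input the toolkit consumes can be generated here with bit-reproducible
seeding: toy protein–ligand complexes, umbrella-window samples Boltzmann-
drawn from analytic PMFs, exponential-decay convergence traces, LIE training
sets with known generating coefficients, and a stub MD backend that biases
its "simulations" toward a planted true pose.  None of this is physically
realistic dynamics — it exists so that every estimator in the package can be
exercised against a known ground truth, offline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .convergence import ConvergenceTrace, decay_model
from .lie import LIEParams, LIETrainingRecord, ReplicaObservables, weighted_lie
from .pmf import R_GAS_KJ, UmbrellaWindow
from .structures import (
    DEFAULT_RADII,
    LIGAND,
    RECEPTOR,
    Atom,
    MolecularComplex,
    RadiiTable,
    ligand_rmsd,
)

__all__ = [
    "AnalyticPMF",
    "DEFAULT_WINDOW_CENTERS",
    "make_toy_complex",
    "make_umbrella_dataset",
    "make_convergence_trace",
    "make_lie_dataset",
    "StubMDBackend",
    "stub_md_backend",
    "make_pose_complexes",
    "make_pose_problem",
]


#: Protocol window schedule for the ligand–site separation coordinate (nm):
#: dense 0.1 nm steps through the bound region, 0.2 nm steps further out.
DEFAULT_WINDOW_CENTERS: tuple[float, ...] = (
    0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
    1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0, 3.2,
)


@dataclass(frozen=True)
class AnalyticPMF:
    """Closed-form PMF used as sampling oracle; minimum value is 0.

    Forms: ``flat`` (0 everywhere); ``step`` (0 below z0, ``barrier``
    above); ``harmonic`` (½·curvature·(z−z0)²); ``double-well`` (quartic
    with zeros at the two well positions, ``barrier`` at the midpoint,
    flat 0 beyond the outer well).
    """

    form: str = "flat"
    barrier: float = 20.0  # kJ/mol
    z0: float = 0.4  # nm (step edge / harmonic centre / inner well)
    z1: float = 2.0  # nm (outer well, double-well only)
    curvature: float = 100.0  # kJ mol⁻¹ nm⁻² (harmonic only)

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            w = np.zeros_like(z)
        elif self.form == "step":
            w = np.where(z < self.z0, 0.0, self.barrier)
        elif self.form == "harmonic":
            w = 0.5 * self.curvature * (z - self.z0) ** 2
        elif self.form == "double-well":
            a, b = self.z0, self.z1
            scale = ((b - a) / 2.0) ** 4
            quartic = self.barrier * ((z - a) ** 2 * (z - b) ** 2) / scale
            w = np.where(z >= b, 0.0, quartic)
        else:
            raise ValueError(f"unknown PMF form {self.form!r}")
        return w


def _receptor_atoms(rng, n, palette, pocket, table) -> list[Atom]:
    """Jittered cubic lattice (3 Å pitch, 0.3 Å jitter) with a 3.5 Å pocket
    carved out around ``pocket``; closest-to-pocket atoms kept first."""
    side = int(np.ceil((2 * max(n, 1)) ** (1 / 3))) + 1
    grid = np.array(
        [[i, j, k] for i in range(side) for j in range(side) for k in range(side)], dtype=float
    )
    grid = (grid - grid.mean(axis=0)) * 3.0 + pocket
    grid = grid + rng.normal(0.0, 0.3, grid.shape)
    keep = np.linalg.norm(grid - pocket, axis=1) > 3.5
    grid = grid[keep]
    order = np.argsort(np.linalg.norm(grid - pocket, axis=1))
    atoms = []
    for xyz in grid[order[:n]]:
        el = palette[int(rng.integers(len(palette)))]
        r_ion, r_vdw = table.lookup(el)
        atoms.append(Atom(el, xyz, RECEPTOR, False, r_ion, r_vdw))
    return atoms


def _ligand_atoms(rng, n, palette, pocket, table) -> list[Atom]:
    """Gaussian cluster (1.2 Å sd) of ligand atoms in the pocket."""
    atoms = []
    for xyz in pocket + rng.normal(0.0, 1.2, (n, 3)):
        el = palette[int(rng.integers(len(palette)))]
        r_ion, r_vdw = table.lookup(el)
        atoms.append(Atom(el, xyz, LIGAND, False, r_ion, r_vdw))
    return atoms


def _mark_polar_hydrogens(atoms: list[Atom]) -> None:
    het = np.array([a.coords for a in atoms if a.element in ("N", "O", "S")])
    for a in atoms:
        if a.element == "H" and het.size:
            a.is_polar_hydrogen = bool((np.linalg.norm(het - a.coords, axis=1) < 1.2).any())


def make_toy_complex(
    seed: int,
    n_receptor_atoms: int = 60,
    n_ligand_atoms: int = 8,
    element_palette: Sequence[str] = ("C", "N", "O"),
    radii: Optional[RadiiTable] = None,
    pocket_center: Sequence[float] = (0.0, 0.0, 0.0),
    label: str = "",
) -> MolecularComplex:
    """A jittered-lattice receptor with a pocket and a clustered ligand.

    Receptor atoms sit on a cubic lattice (3 Å pitch, 0.3 Å jitter) with
    atoms within 3.5 Å of ``pocket_center`` carved out; ligand atoms are
    Gaussian-clustered (1.2 Å sd) in the pocket.  Deterministic per seed.
    """
    if n_receptor_atoms < 0 or n_ligand_atoms < 1:
        raise ValueError("need >= 0 receptor and >= 1 ligand atoms")
    table = radii or RadiiTable()
    rng = np.random.default_rng(seed)
    pocket = np.asarray(pocket_center, dtype=float)
    atoms = _receptor_atoms(rng, n_receptor_atoms, element_palette, pocket, table)
    atoms += _ligand_atoms(rng, n_ligand_atoms, element_palette, pocket, table)
    _mark_polar_hydrogens(atoms)
    return MolecularComplex(atoms, label=label or f"toy-{seed}")


def make_umbrella_dataset(
    pmf: AnalyticPMF,
    centers: Sequence[float],
    spring_k: float = 1000.0,
    n_per_window: int = 5000,
    T: float = 310.0,
    seed: int = 0,
    grid_points: int = 4096,
) -> list[UmbrellaWindow]:
    """Boltzmann-sample umbrella windows from an analytic PMF.

    Per window, samples are drawn from the biased density
    ∝ exp(−(W(z) + ½·spring_k·(z−c)²)/RT) by inverse-CDF interpolation on a
    ``grid_points``-point grid spanning all window supports.  Seeded.
    """
    if n_per_window < 100:
        raise ValueError("need at least 100 samples per window")
    rng = np.random.default_rng(seed)
    rt = R_GAS_KJ * T
    lo = min(centers) - 1.0
    hi = max(centers) + 1.0
    z = np.linspace(lo, hi, grid_points)
    w_z = pmf(z)
    windows = []
    for c in centers:
        u = w_z + 0.5 * spring_k * (z - c) ** 2
        log_p = -(u - u.min()) / rt
        p = np.exp(log_p)
        total = np.trapezoid(p, z)
        if not np.isfinite(total) or total <= 0:
            raise ValueError(f"biased density vanishes for window at {c} nm")
        cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(z))])
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_per_window), cdf, z)
        windows.append(UmbrellaWindow(center=c, spring_k=spring_k, samples=samples, temperature=T))
    return windows


def make_convergence_trace(
    c0: float,
    c1: float,
    k: float,
    noise_frac: float = 0.0,
    checkpoints: Sequence[float] = tuple(np.linspace(4.0, 32.0, 8)),
    seed: int = 0,
    compound_id: str = "",
) -> ConvergenceTrace:
    """Exponential-decay ΔW(t) trace with multiplicative Gaussian noise."""
    t = np.asarray(list(checkpoints), dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 checkpoints")
    dw = decay_model(t, c0, c1, k)
    if noise_frac:
        rng = np.random.default_rng(seed)
        dw = dw * (1.0 + noise_frac * rng.standard_normal(dw.shape))
    return ConvergenceTrace(t, dw, compound_id=compound_id)


#: Observable sampling ranges (kJ/mol; entropy J/mol/K) bracketing the
#: magnitude scale of bound-state interaction energies in solvated
#: protein–ligand MD: tens to a couple hundred kJ/mol per term.
LIE_RANGES = {
    "u_lig_coul": (-200.0, -20.0),
    "u_lig_lj": (-250.0, -50.0),
    "u_site_coul": (-120.0, -10.0),
    "u_site_lj": (-150.0, -20.0),
    "entropy_s": (100.0, 500.0),
}


def make_lie_dataset(
    true_params: LIEParams,
    n_compounds: int = 12,
    replicas_per_compound: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[LIETrainingRecord]:
    """LIE training records with a known generating coefficient set.

    Observables are uniform in :data:`LIE_RANGES`; the experimental value
    is the pooled replica-weighted estimate under ``true_params`` plus
    Gaussian noise of sd ``noise_sd`` (kJ/mol).
    """
    if n_compounds < 6:
        raise ValueError("need at least 6 compounds for a 5-coefficient fit")
    rng = np.random.default_rng(seed)
    keys = ["u_lig_coul", "u_lig_lj", "u_site_coul", "u_site_lj", "entropy_s"]
    records = []
    for i in range(n_compounds):
        replicas = []
        for _ in range(replicas_per_compound):
            vals = {k: rng.uniform(*LIE_RANGES[k]) for k in keys}
            replicas.append(ReplicaObservables(**vals))
        dg = weighted_lie(replicas, true_params)
        if noise_sd:
            dg += rng.normal(0.0, noise_sd)
        records.append(LIETrainingRecord(replicas, dg_exp=dg, label=f"cmpd{i}"))
    return records


# ---------------------------------------------------------------------------
# Stub MD backend


def _pose_seed(seed: int, compound_id: str, pose_id: str) -> np.random.Generator:
    h1 = zlib.crc32(compound_id.encode()) & 0x7FFFFFFF
    h2 = zlib.crc32(pose_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, h1, h2]))


@dataclass
class StubMDBackend:
    """Deterministic stand-in for an MD engine in the iterative loop.

    ``evaluate(pose)`` returns replica end-state complexes plus replica
    observables.  Near-truth poses (ligand RMSD to the planted pose below
    ``near_threshold``) are pulled toward the planted coordinates with
    strength ``attraction`` and receive more favourable (lower) interaction
    energies; far poses are pushed away.  The favourability gap scales
    linearly with ``attraction`` so attraction = 0 yields pure jitter and a
    zero gap.  Deterministic per (seed, compound, pose).
    """

    planted_truth: dict[str, str]
    truth_coords: dict[str, np.ndarray]  # compound_id → planted ligand coords
    attraction: float = 1.0
    seed: int = 0
    n_replicas: int = 8
    near_threshold: float = 2.0  # Å
    far_scale: float = 8.0  # Å over which favourability decays
    jitter_sd: float = 0.3  # Å
    energy_gap: float = 120.0  # kJ/mol between perfect and far poses
    noise_sd: float = 3.0  # kJ/mol observable noise
    base_obs: tuple[float, float, float, float, float] = (-60.0, -90.0, -40.0, -60.0, 300.0)

    def __post_init__(self):
        if not (0.0 <= self.attraction <= 1.0):
            raise ValueError("attraction must lie in [0, 1]")

    def evaluate(self, pose) -> tuple[list[MolecularComplex], list[ReplicaObservables]]:
        cid, pid = pose.compound_id, pose.pose_id
        if cid not in self.planted_truth:
            raise KeyError(f"compound {cid!r} absent from planted_truth")
        truth = self.truth_coords[cid]
        rng = _pose_seed(self.seed, cid, pid)
        comp = pose.complex
        lig = comp.ligand_coords
        rmsd = float(np.sqrt(np.mean(np.sum((lig - truth) ** 2, axis=1))))
        proximity = max(0.0, 1.0 - rmsd / self.far_scale)

        lig_idx = [i for i, a in enumerate(comp.atoms) if a.owner == LIGAND]
        replicas, observables = [], []
        for _ in range(self.n_replicas):
            coords = comp.coords.copy()
            if rmsd < self.near_threshold:
                drift = self.attraction * (truth - lig)
            else:
                delta = lig - truth
                norm = np.linalg.norm(delta, axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                drift = self.attraction * delta / norm  # 1 Å outward
            coords[lig_idx] = lig + drift + rng.normal(0.0, self.jitter_sd, lig.shape)
            replicas.append(comp.with_coords(coords, label=f"{cid}:{pid}:md"))
            favour = self.attraction * self.energy_gap * proximity
            noise = rng.normal(0.0, self.noise_sd, 5)
            base = self.base_obs
            observables.append(
                ReplicaObservables(
                    u_lig_coul=base[0] - 0.3 * favour + noise[0],
                    u_lig_lj=base[1] - favour + noise[1],
                    u_site_coul=base[2] - 0.2 * favour + noise[2],
                    u_site_lj=base[3] - 0.5 * favour + noise[3],
                    entropy_s=base[4] + 0.2 * favour + noise[4],
                )
            )
        return replicas, observables


def stub_md_backend(
    planted_truth: dict[str, str],
    attraction: float,
    seed: int,
    pose_pool: Optional[Sequence] = None,
    truth_coords: Optional[dict[str, np.ndarray]] = None,
    **kwargs,
) -> StubMDBackend:
    """Build a :class:`StubMDBackend`.

    The backend needs the planted poses' ligand coordinates; supply either
    ``pose_pool`` (records with ``compound_id``/``pose_id``/``complex``,
    from which the planted coordinates are resolved) or ``truth_coords``
    directly.
    """
    if truth_coords is None:
        if pose_pool is None:
            raise ValueError("supply pose_pool or truth_coords")
        truth_coords = {}
        for rec in pose_pool:
            if planted_truth.get(rec.compound_id) == rec.pose_id:
                truth_coords[rec.compound_id] = rec.complex.ligand_coords
        missing = set(planted_truth) - set(truth_coords)
        if missing:
            raise ValueError(f"planted poses not found in pool: {sorted(missing)}")
    return StubMDBackend(
        planted_truth=dict(planted_truth),
        truth_coords=truth_coords,
        attraction=attraction,
        seed=seed,
        **kwargs,
    )


def make_pose_problem(
    seed: int,
    n_compounds: int = 20,
    n_poses: int = 10,
    n_seed_compounds: int = 4,
    attraction: float = 1.0,
    n_replicas: int = 2,
    grid=None,
):
    """Full synthetic pose-prediction problem for the iterative loop.

    All compounds bind one shared receptor (as in a single-target study);
    each contributes a distinct in-pocket ligand as its planted pose plus
    ``n_poses − 1`` displaced decoys.  A stub MD backend is planted on the
    true poses, and an initial training set emulating the resolved
    reference complexes is created by pre-evaluating the planted pose plus
    one contrast decoy for the first ``n_seed_compounds`` compounds.
    Returns (pose_pool, truth map, backend, grid).
    """
    from .pipeline import PoseRecord, evaluate_pose
    from .structures import RadiiTable
    from .voxel import GridSpec

    if grid is None:
        grid = GridSpec(origin=(-8.0, -8.0, -8.0), spacing=2.0, shape=(8, 8, 8))
    table = RadiiTable()
    rng = np.random.default_rng(seed)
    pocket = np.zeros(3)
    palette = ("C", "N", "O")
    receptor = _receptor_atoms(rng, 40, palette, pocket, table)

    pool, truth = [], {}
    for c in range(n_compounds):
        cid = f"c{c:02d}"
        n_lig = int(rng.integers(5, 9))
        ligand = _ligand_atoms(rng, n_lig, palette, pocket, table)
        base = MolecularComplex(list(receptor) + ligand, label=cid)
        poses, planted = _displaced_poses(base, rng, n_poses, cid)
        truth[cid] = planted
        for pid, comp in poses:
            pool.append(PoseRecord(cid, pid, comp))
    backend = stub_md_backend(
        truth, attraction=attraction, seed=seed, pose_pool=pool, n_replicas=n_replicas
    )
    for c in range(min(n_seed_compounds, n_compounds)):
        cid = f"c{c:02d}"
        for pid in (truth[cid], "p1"):
            rec = next(p for p in pool if p.compound_id == cid and p.pose_id == pid)
            if not rec.evaluated:
                evaluate_pose(rec, backend, grid)
    return pool, truth, backend, grid


def _displaced_poses(
    base: MolecularComplex,
    rng,
    n_poses: int,
    compound_id: str,
    displacement_range: tuple[float, float] = (2.5, 7.0),
) -> tuple[list[tuple[str, MolecularComplex]], str]:
    """Pose 'p0' is the planted in-pocket pose; the rest are the same
    ligand rigidly displaced by 2.5–7 Å in random directions."""
    poses = [("p0", base)]
    lig_idx = [i for i, a in enumerate(base.atoms) if a.owner == LIGAND]
    for j in range(1, n_poses):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(*displacement_range)
        coords = base.coords.copy()
        coords[lig_idx] += direction * dist
        poses.append((f"p{j}", base.with_coords(coords, label=f"{compound_id}:p{j}")))
    return poses, "p0"


def make_pose_complexes(
    seed: int,
    n_poses: int = 10,
    n_receptor_atoms: int = 40,
    n_ligand_atoms: int = 6,
    displacement_range: tuple[float, float] = (2.5, 7.0),
    compound_id: str = "c0",
) -> tuple[list[tuple[str, MolecularComplex]], str]:
    """Docked-pose pool for one synthetic compound.

    The planted in-pocket pose plus ``n_poses − 1`` decoys of the same
    ligand rigidly displaced out of the pocket.  Returns the
    (pose_id, complex) list and the planted pose id.
    """
    rng = np.random.default_rng(seed)
    base = make_toy_complex(
        int(rng.integers(2**31)), n_receptor_atoms, n_ligand_atoms, label=compound_id
    )
    return _displaced_poses(base, rng, n_poses, compound_id, displacement_range)
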