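"""Self-contained validation scenarios exercising every stage end to end.

Each function builds its own synthetic inputs (with explicit seeds),
runs one estimator of the toolkit against a known ground truth and returns
the headline numbers.  The test suite asserts on them; the acceptance
script reports them.  Problem sizes are chosen to finish on one CPU in
minutes — see the methods note for what they do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from . import ann, fixtures, pipeline, pmf
from .convergence import fit_convergence
from .fixtures import AnalyticPMF, DEFAULT_WINDOW_CENTERS
from .lie import DEFAULT_LIE_PARAMS, fit_lie_params
from .voxel import GridSpec

__all__ = [
    "wham_doublewell_rms",
    "jensen_check",
    "convergence_recovery",
    "lie_recovery",
    "ann_overfit",
    "pipeline_planted_truth",
]


def wham_doublewell_rms(
    seed: int = 1,
    barrier: float = 20.0,
    n_per_window: int = 5000,
    spring_k: float = 1000.0,
) -> dict:
    """Recover an analytic double-well PMF from Boltzmann-sampled windows.

    22 windows on the protocol ξ schedule; the returned RMS error is taken
    after removing the mean offset (a PMF is defined up to an additive
    constant) over the sampled support.
    """
    analytic = AnalyticPMF(form="double-well", barrier=barrier)
    windows = fixtures.make_umbrella_dataset(
        analytic, DEFAULT_WINDOW_CENTERS, spring_k=spring_k,
        n_per_window=n_per_window, seed=seed,
    )
    profile = pmf.wham(windows)
    z, w = profile.sampled()
    diff = w - analytic(z)
    diff -= diff.mean()
    rms = float(np.sqrt(np.mean(diff**2)))
    rt = pmf.R_GAS_KJ * 310.0
    return {"rms_kj_mol": rms, "rms_over_rt": rms / rt, "n_windows": len(windows)}


def jensen_check(seed: int = 0, n_sets: int = 100) -> dict:
    """Exponential work averaging never exceeds the arithmetic mean."""
    rng = np.random.default_rng(seed)
    violations = 0
    max_gap = 0.0
    for _ in range(n_sets):
        dws = rng.uniform(5.0, 80.0, int(rng.integers(2, 9)))
        arith, _ = pmf.combine_routes(dws, method="arithmetic")
        jarz, _ = pmf.combine_routes(dws, method="jarzynski")
        if jarz > arith + 1e-9:
            violations += 1
        max_gap = max(max_gap, arith - jarz)
    equal, _ = pmf.combine_routes([30.0] * 4, method="jarzynski")
    equality_holds = abs(equal - 30.0) < 1e-9
    return {"violations": violations, "n_sets": n_sets, "equality_case_ok": equality_holds}


def convergence_recovery(seed: int = 0, n_checkpoints: int = 16, n_replicates: int = 5) -> dict:
    """Recover (C₀, C₁, k) of the decay model, noiseless and at 5% noise.

    At 5% i.i.d. multiplicative noise the asymptote's standard error on one
    16-checkpoint trace is about 2% of its value, so the noisy check is
    made on the median over ``n_replicates`` independent traces — mirroring
    the protocol's own reliance on replication rather than a single run.
    """
    c0, c1, k = 60.0, 10.0, 0.5
    checkpoints = np.linspace(2.0, 32.0, n_checkpoints)
    clean = fixtures.make_convergence_trace(c0, c1, k, 0.0, checkpoints)
    fit = fit_convergence(clean)
    rel = max(
        abs(fit.c0 - c0) / c0, abs(fit.c1 - c1) / c1, abs(fit.k - k) / k
    )
    rng = np.random.default_rng(seed)
    errs = []
    for sub in rng.integers(0, 2**31, n_replicates):
        noisy = fixtures.make_convergence_trace(c0, c1, k, 0.05, checkpoints, seed=int(sub))
        fit_n = fit_convergence(noisy)
        errs.append(abs(fit_n.asymptote - (c0 - c1)) / (c0 - c1))
    return {
        "noiseless_max_rel_err": float(rel),
        "noisy_asymptote_rel_err": float(np.median(errs)),
        "noisy_asymptote_worst_err": float(np.max(errs)),
    }


def lie_recovery(seed: int = 3, n_compounds: int = 12, replicas: int = 8) -> dict:
    """Recover the generating LIE coefficients from noiseless synthetic data."""
    records = fixtures.make_lie_dataset(
        DEFAULT_LIE_PARAMS, n_compounds, replicas, noise_sd=0.0, seed=seed
    )
    fitted, residuals = fit_lie_params(records, k=0.2)
    rel = np.abs(
        (fitted.coefficients() - DEFAULT_LIE_PARAMS.coefficients())
        / DEFAULT_LIE_PARAMS.coefficients()
    )
    return {
        "max_rel_err": float(rel.max()),
        "residual_rms": float(np.sqrt(np.mean(residuals**2))),
        "n_records": n_compounds,
    }


def ann_overfit(seed: int = 0, generations: int = 30) -> dict:
    """Overfit-capacity check: one 8³ example, GA + CG, 30 generations."""
    spec = ann.NetworkSpec(input_shape=(5, 8, 8, 8))
    comp = fixtures.make_toy_complex(seed, n_receptor_atoms=30, n_ligand_atoms=6)
    grid = GridSpec(
        origin=tuple(comp.ligand_centroid() - 8.0), spacing=2.0, shape=(8, 8, 8)
    )
    from .voxel import voxelize

    rng = np.random.default_rng(seed)
    vin = voxelize(comp, grid)
    relaxed = comp.with_coords(comp.coords + rng.normal(0, 0.3, (len(comp), 3)))
    vtarget = voxelize(relaxed, grid)
    example = ann.TrainingExample(
        vin, vtarget, np.array([-60.0, -120.0, -40.0, -70.0, 300.0])
    )
    _, history = ann.train(
        [example], spec, seed=seed,
        ga_config={"population": 4, "generations": generations},
        cg_config={"max_iters": 20},
    )
    return {
        "initial_loss": history[0],
        "final_loss": history[-1],
        "loss_ratio": history[-1] / history[0],
    }


def pipeline_planted_truth(seed: int = 7, n_compounds: int = 20, n_poses: int = 10) -> dict:
    """Planted-truth recovery of the iterative dock→predict→simulate loop.

    20 compounds sharing one receptor, 10 poses each, stub backend with
    attraction 1.0; the initial training set holds the resolved complexes
    of 6 compounds.  Reports the fraction of compounds whose planted pose
    ranks first after convergence and the iteration count.
    """
    pool, truth, backend, grid = fixtures.make_pose_problem(
        seed=seed, n_compounds=n_compounds, n_poses=n_poses, n_seed_compounds=6,
        attraction=1.0, n_replicas=2,
    )
    spec = ann.NetworkSpec(
        input_shape=(5, 8, 8, 8), encoder_channels=(4, 6, 6),
        encoder_strides=(2, 2, 1), nested_channels=6,
        mid_sizes=(32,), perceptron_sizes=(16,),
    )
    cfg = {
        "spec": spec, "grid": grid,
        "ga": {"population": 3, "generations": 2},
        "cg": {"max_iters": 60},
    }
    poses, log = pipeline.iterate(
        pool, backend, cfg, DEFAULT_LIE_PARAMS, select_n=1, max_iters=5,
        seed=seed, combine="weighted", margin=5.0,
    )
    ranked = pipeline.rank_poses(poses, combine="weighted")
    top1 = sum(1 for cid, group in ranked.items() if group[0].pose_id == truth[cid])
    return {
        "top1_fraction": top1 / n_compounds,
        "top1_percent": 100.0 * top1 / n_compounds,
        "n_compounds": n_compounds,
        "iterations": log.n_iterations,
        "productive_iterations": log.productive_iterations,
        "converged": log.converged,
    }
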