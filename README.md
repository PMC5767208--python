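# mrfe — multi-route free-energy estimation toolkit

Binding free energies of ligands to flexible receptors are dominated by
entropy and by the multiplicity of dissociation pathways, which is why
docking scores alone rank them poorly.  One practical remedy combines
several layers of molecular-dynamics machinery: replicated linear
interaction energy (LIE) runs for fast scoring, multiple non-equilibrium
pulls smoothed by umbrella sampling for rigorous estimates, convergence
diagnostics to catch unlucky route selections, and a learned surrogate
that predicts what MD would do to a docked pose so that the expensive
simulations are spent only on promising candidates.

`mrfe` implements that computational layer as a reusable Python library
(plus a thin `mrfe` CLI), with the MD and docking engines abstracted
behind a backend interface and a fully seeded synthetic layer standing in
for them, so every stage runs and validates offline.

## What is inside

| module | contents |
| --- | --- |
| `mrfe.structures` | PDB I/O, the five chemical feature channels, radii tables, Kabsch superposition |
| `mrfe.voxel` | signed 5-channel voxelization ρ(r) (1 inside r_ion, Gaussian flank to r_vdw), cosine map similarity |
| `mrfe.lie` | ΔG_i = αΔ⟨U_lig^Coul⟩ + β⟨U_lig^LJ⟩ + γ⟨U_site^Coul⟩ + δ⟨U_site^LJ⟩ + εS; weights w_i = ΔG_i/(kΣΔG); iterated reweighted fitting; quasi-harmonic entropy |
| `mrfe.pmf` | WHAM over umbrella windows, ΔW = Σp_iΔW_i route pooling (arithmetic or Jarzynski exp-average), ΔG° = −RT ln(k_W e^(−ΔW/RT)) − C_V with V° ≈ 1661 ų |
| `mrfe.convergence` | ΔW(t) = C₀ − C₁(1 − e^(−kt)) fitting, asymptote extrapolation, σ_ΔW/k outlier flags |
| `mrfe.ann` | 3D conv encoder–decoder + perceptron head (tanh, no pooling, no ReLU), GA + Polak–Ribière CG training, dual energetic/geometric pose score |
| `mrfe.pipeline` | the iterative dock → predict → simulate → retrain loop over pluggable MD backends |
| `mrfe.fixtures` | seeded synthetic inputs: toy complexes, Boltzmann-sampled umbrella windows from analytic PMFs, decay traces, LIE datasets, a planted-truth stub MD backend |

## Worked example: a binding free energy from umbrella windows

Four parallel dissociation routes are emulated by sampling umbrella
windows (22 windows, ξ = 0 … 3.2 nm, κ = 1000 kJ mol⁻¹ nm⁻²) from an
analytic step PMF with a 30 kJ/mol dissociation plateau; each route is
analyzed with WHAM, pooled arithmetically, converted to a standard-state
free energy, and checked for convergence:

```python
import numpy as np
from mrfe import fixtures, pmf
from mrfe.convergence import fit_convergence, pmf_timeseries

analytic = fixtures.AnalyticPMF(form="step", barrier=30.0, z0=0.5)
routes = [
    fixtures.make_umbrella_dataset(analytic, fixtures.DEFAULT_WINDOW_CENTERS,
                                   spring_k=1000.0, n_per_window=5000, seed=s)
    for s in (1, 2, 3, 4)
]
dws = [pmf.pmf_work(pmf.wham(w), bound_region=(0.0, 0.1)).value for w in routes]
dw, sigma = pmf.combine_routes(dws, T=310.0)
print(f"route works (kJ/mol): {[round(x, 2) for x in dws]}")
print(f"pooled dW = {dw:.2f} kJ/mol, sigma = {sigma:.2f} kJ/mol")

cal = pmf.StandardStateCal(k_w=1.0, c_v=8.0)   # from fit_kw_cv on references
print(f"dG0 = {pmf.standard_dg(dw, cal, T=310.0):.2f} kJ/mol")

trace = pmf_timeseries(routes, checkpoints=np.linspace(4, 32, 8), duration_ns=32.0)
fit = fit_convergence(trace)
print(f"decay fit: k = {fit.k:.3f} /ns, asymptote = {fit.asymptote:.2f} kJ/mol, rmse = {fit.rmse:.2f}")
```

Output:

```
route works (kJ/mol): [30.32, 30.32, 30.46, 32.02]
pooled dW = 30.78 kJ/mol, sigma = 0.83 kJ/mol
dG0 = 22.78 kJ/mol
decay fit: k = 0.078 /ns, asymptote = 30.85 kJ/mol, rmse = 0.20
```

Reading it: each route's WHAM profile recovers the 30 kJ/mol dissociation
work to within sampling noise (one route drifts to 32 — exactly the kind
of spread σ_ΔW is meant to expose); the pooled estimate is 30.8 ± 0.8
kJ/mol; subtracting the calibrated standard-state offset gives the
standard free energy; and the convergence fit's small positive k with an
asymptote near the pooled value marks the estimation as healthy rather
than an outlier needing re-simulation.

The same operations are scriptable from the shell: `mrfe fixtures
make-umbrella`, `mrfe pmf wham`, `mrfe pmf combine`, `mrfe pmf stdfe`,
`mrfe converge fit` — see `mrfe --help`.

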