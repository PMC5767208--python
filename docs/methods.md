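# Methods

`mrfe` implements the computational machinery that surrounds MD-based
binding studies of flexible receptors: pooling replicated linear
interaction energy (LIE) estimates, combining umbrella-sampling free-energy
profiles from parallel dissociation routes, diagnosing the convergence of
those estimates, featurizing protein–ligand complexes as signed voxel
maps, and training a small convolutional network to predict MD outcomes
from docked poses so that an iterative selection loop can spend expensive
simulations only on promising candidates.  The MD and docking engines
themselves are out of scope; a seeded synthetic layer stands in for them
so every estimator can be validated offline against known ground truth.

## Replica-weighted LIE

A replica's estimate is the linear form
ΔG_i = α⟨U_lig^Coul⟩ + β⟨U_lig^LJ⟩ + γ⟨U_site^Coul⟩ + δ⟨U_site^LJ⟩ + ε·S_i
over its time-averaged interaction energies (kJ/mol) and a quasi-harmonic
rigid-body entropy term S (J mol⁻¹ K⁻¹, from the 6×6 pose covariance).
Replicas are pooled through self-referential weights w_i = ΔG_i/(k·ΣΔG)
with Σw_i = 1/k exactly; the protocol constant k defaults to 0.2, so four
identical replicas pool to five times a single estimate.  The weights are
not confined to [0, 1]; sign-mixed replica sets legitimately push them
outside, and a warning fires at |w| > 10.

Fitting uses iterated reweighted linear least squares: with the weights
frozen the pooled estimate is linear in (α…ε), so the loop alternates an
exact least-squares solve with a weight refresh until the *per-coefficient
relative* change drops below tolerance — an absolute criterion would stop
while ε (four orders of magnitude below β) is still moving.  A `free`
mask supports reduced fits with a subset of coefficients pinned to zero.

Two conventions are deliberately configurable because the published
parameter set leaves them open: the reference offsets U₀ (carried in
`LIEParams`, off by default, subtractable from the site terms via
`u0_mode="site"`), and the units of the ε·S product (S is used raw, in
entropy units; any temperature factor belongs to the caller).

## PMF estimation and standard state

Umbrella windows (harmonic bias ½κ(z−c)², reaction coordinate in nm) are
combined by the standard WHAM self-consistent equations on a histogram
grid (default 0.02 nm bins spanning the window centers ± 0.2 nm),
iterating until every window free energy moves by less than the tolerance.
Bins with fewer than 10 total samples are reported as unsampled rather
than letting −RT·ln of a stray count carve a spurious minimum; this
matters because profiles are minimum-shifted for presentation, and a
profile is in any case defined only up to an additive constant — every
comparison made by the package's validation removes the mean offset first.

The per-route dissociation work is ΔW = max W over the plateau (final 20%
of the sampled range, configurable) minus the mean W over the bound region
(default z ∈ [0, 0.1] nm); a non-flat tail flags the estimate.  Parallel
routes are pooled arithmetically by default — with a handful of routes,
spread is better read as error than as Boltzmann weight — while the
exponential (Jarzynski) average is available and bounds the arithmetic
mean from below by Jensen's inequality.

The standard-state conversion ΔG° = −RT·ln(k_W·exp(−ΔW/RT)) − C_V uses the
1 M volume V° = 1/(N_A · 1 mol/L) ≈ 1661 ų computed from first
principles.  In this affine form only the combined offset RT·ln k_W + C_V
is identifiable from (ΔW, ΔG_exp) pairs — the two constants enter as one
additive term — so the calibration fit is gauge-fixed: k_W is held at a
chosen value (default 1) and C_V absorbs the offset by least squares.
Predictions are invariant under the gauge choice.  The integral form of
the conversion (with the optional −1 term in the bound-state integrand)
is available for profile-level use.

## Convergence diagnostics

Treating quasi-equilibrium sampling as a process that fixes the errors
introduced by the preceding non-equilibrium pull at a rate proportional to
the error remaining gives ΔW(t) = C₀ − C₁(1 − exp(−kt)); the asymptote
C₀ − C₁ extrapolates the estimate to infinite sampling.  The fit uses
variable projection — for fixed k the model is linear in (C₀, C₁), so k is
scanned on a signed log grid, the linear subproblem solved exactly, and
the best candidate polished by Levenberg–Marquardt.  A naive 3-parameter
descent routinely slides into the degenerate k→0 ridge (|C₁|→∞ with C₁·k
finite), which fits a noisy plateau equally well but extrapolates
nonsense.  k is unconstrained in sign: a negative value is itself the
"non-decaying" diagnostic.  Flat traces return C₁ = 0 with k marked
unidentifiable.

Outlier screening across a compound set uses two-sided robust z-scores
(median/MAD, threshold 2.0 by default) of the route spread σ_ΔW and of k,
plus the sign rule k ≤ 0 → non-decaying; flags are unioned per compound.
With a zero MAD the score degenerates and any value off the median is
flagged, with a warning.

A statistical limitation worth stating: at 5% i.i.d. multiplicative noise
on a 16-checkpoint trace of the default benchmark parameters, the
asymptote's standard error is about 2% of its value, so single-trace
recovery at that precision fails for roughly a third of noise
realizations no matter how the fit is done.  The validation therefore
scores the median over five replicate traces — replication being exactly
what the protocol prescribes for unreliable estimates.

## Voxel featurization

Atoms paint density 1 inside their ionic radius, exp(−2((r−r_ion)/(r_vdw−
r_ion))²) between the ionic and van-der-Waals radii, and 0 beyond; the
profile is intentionally discontinuous at r_vdw (left value e⁻²), and
r = r_vdw takes the exponential branch.  Five chemical channels (polar-H
donors; hydrophobic C/Cl/Br/I; N acceptors; O/F acceptors; S/P
d-elements) are populated additively — ligand atoms negative, receptor
positive — and clamped to [−1, 1] per voxel after accumulation, so mixed
contributions may cancel before clamping.  Atoms outside the five maps
(notably nonpolar hydrogens) contribute nothing, explicitly.  Polar
hydrogens are those within 1.2 Å of N/O/S.  Default radii are a
Bondi-style van-der-Waals set with Shannon-style ionic radii for the ten
relevant elements, overridable via JSON.  The default grid is 24³ voxels
at 1.0 Å centred on the ligand centroid; map similarity is cosine over the
flattened channels (zero maps score 0), with a negative-RMS alternative.

## The network

The surrogate maps a 5-channel voxel map of a docked pose to (i) the map
of the relaxed post-MD complex and (ii) the 5 LIE observables.  Encoder:
three 3³-kernel convolution stages (strides 2, 2, 1) plus one nested
innermost stage; a fully connected bottleneck; a mirrored decoder in which
each stride-2 stage is undone by nearest-neighbour ×2 upsampling followed
by a stride-1 convolution (shape-exact for even stage inputs, which the
supported grids satisfy); and a perceptron head reading the concatenated
innermost encoder and innermost decoder activations — the cross-connection
that couples the geometric and energetic channels.  All activations are
tanh; there are no pooling layers, no rectified-linear units, and no
sparsity penalty.  The final decoder tanh keeps predicted maps inside the
voxel bound.  Exact widths are configurable; published figures of such
architectures are schematic, and the defaults here (8→16→16 channels,
64-unit bottleneck, 32-unit perceptron) are desk-scale choices.

Training composes a genetic algorithm (tournament selection, uniform
crossover, Gaussian mutation, elitism) over flat weight vectors with
Polak–Ribière conjugate-gradient refinement of every individual using the
hand-derived analytic gradient (verified against central differences).
Multiple training targets per input — parallel MD replicas of one pose —
are first-class; the mean-squared loss then drives predictions toward the
conditional mean over replicas, which is the intended reading of the
ensemble.  One numerical choice matters: the LIE targets are standardized
per component inside `train` (raw kJ/mol targets are two orders of
magnitude above the bounded voxel values; they otherwise swamp the
reconstruction term and ill-condition the final layer), and the
de-standardizing affine map is folded back into the final linear layer, so
returned weights predict raw observables and the loss history stays in raw
units.

## The iterative pose loop

Each iteration trains a fresh network on all MD-evaluated poses, scores
every pose — evaluated poses from their observed replica energies,
unevaluated ones from network predictions (energetic: the single-replica
LIE form on predicted observables; geometric: maximum map similarity to
the evaluated references) — selects the top `select_n` per compound by
combined score, sends the new selections to the MD backend, and enriches
the training set.  LIE coefficients are frozen for the whole run.  The
loop terminates when it proposes no pose that has not already been
simulated.  Two scoring-combination rules exist: rank-average (default)
and a weighted sum in which one unit of map similarity is worth a
configurable energy bonus (default 5 kJ/mol).  A convergence `margin`
(default 0) requires a new proposal to beat the compound's best evaluated
pose by more than the margin before it is simulated; with a noisy
surrogate this is what keeps the loop from re-proposing marginal poses
indefinitely.

## Synthetic layer: what it emulates and what it does not

The fixtures generate toy complexes (jittered-lattice receptor with a
carved pocket, Gaussian-clustered ligand), umbrella windows drawn from
analytic PMFs by inverse-CDF sampling of the exact biased Boltzmann
density (4096-point grid), decay traces with multiplicative noise, LIE
records with known generating coefficients (observable ranges bracket
tens-to-hundreds of kJ/mol), and a stub MD backend that jitters replicas
toward a planted true pose and emits interaction energies that improve
linearly with attraction strength and pose proximity.  Everything is
bit-reproducible from its seed.

The planted-truth pose scenario mirrors the single-target study design:
20 compounds share one receptor, each with one in-pocket pose and nine
displaced decoys (2.5–7 Å); the initial training set holds the "resolved"
complexes — planted pose plus one contrast decoy — of the first 6
compounds, a known-structure fraction comparable to a real pose-prediction
campaign.  In this scenario the loop runs with the weighted combination
and a 5 kJ/mol margin: at desk scale the reconstruction channel carries
little signal for never-simulated poses, and rank-averaging would dilute
an otherwise near-perfect energetic channel.  Scenario sizes (8³ voxel
grids at 2 Å, a reduced 4→6→6-channel network, populations of 3–4, tens of
CG iterations, 2 replicas per evaluation) are chosen so the full loop
finishes in minutes on one CPU.

Passing these scenarios demonstrates that the estimators recover known
ground truth under their own model assumptions — Boltzmann-distributed
window samples, exponential-decay convergence, linear energy models, a
geometry-correlated favourability signal.  It does not demonstrate
force-field accuracy, real conformational sampling, solvent effects, or
chemotype generalization beyond what the toy geometry encodes; on real
systems the dominant errors live exactly in those places.

## Other numerical choices and degenerate inputs

WHAM requires center-adjacent windows to share a sampled bin and reports
the gap otherwise; iteration failure raises with the residual.  Windows
with zero spring constant are allowed (plain histogramming).  The entropy
estimator floors covariance eigenvalues (warning) instead of failing on
rigid trajectories.  Weight pooling refuses ΣΔG = 0.  `combine_scores`
breaks ties by stable input order.  Superposition needs three
non-collinear anchors and uses Kabsch via scipy; collinearity is detected
from the singular values of the centred anchor cloud.  The backend
protocol treats per-pose failures as data (pose flagged, loop continues).
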