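"""Encoder–decoder network predicting MD outcomes from docked poses.

The network takes a signed 5-channel voxel map of a docked complex and
produces (i) the voxel map the complex is expected to relax into under MD
and (ii) a 5-vector of LIE observables (four interaction-energy averages
plus the entropy term).  The architecture is a 3D convolutional encoder
(three stages plus one nested innermost stage), a fully connected
bottleneck, a mirrored convolutional decoder, and a perceptron head that
reads the two innermost convolutional activations — the cross-connection
that couples the geometric and energetic hypothesis channels.  There are
no pooling layers and no rectified-linear units; every activation is tanh
(the final decoder tanh also bounds the output map to (−1, 1)).

Training is deliberately gradient-hungry: a genetic algorithm explores
weight space globally while each individual is refined locally with
Polak–Ribière conjugate gradients on analytic gradients.

Everything is plain numpy in float64; batches are the leading axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize

from .lie import LIEParams, ReplicaObservables, replica_dg
from .voxel import GridSpec, VoxelMap, voxel_similarity

__all__ = [
    "NetworkSpec",
    "WeightSet",
    "TrainingExample",
    "init_weights",
    "forward",
    "loss",
    "loss_and_grad",
    "train",
    "score_pose",
    "save_weights",
    "load_weights",
]

N_LIE = 5


# ---------------------------------------------------------------------------
# Specification


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-parameters and derived layer plan of the network.

    The published architecture is schematic (three encoder/decoder stage
    pairs plus one nested innermost pair); widths and kernels here are the
    package defaults and fully configurable.  Stride-2 stages require even
    spatial extents so the mirrored upsampling restores shapes exactly.
    """

    input_shape: tuple[int, int, int, int] = (5, 24, 24, 24)
    encoder_channels: tuple[int, ...] = (8, 16, 16)
    encoder_strides: tuple[int, ...] = (2, 2, 1)
    nested_channels: int = 16
    kernel: int = 3
    mid_sizes: tuple[int, ...] = (64,)
    perceptron_sizes: tuple[int, ...] = (32,)
    activation: str = "tanh"

    def __post_init__(self):
        if self.activation != "tanh":
            raise ValueError("only the smooth sigmoidal 'tanh' activation is supported")
        if len(self.encoder_channels) != len(self.encoder_strides):
            raise ValueError("encoder_channels and encoder_strides length mismatch")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.input_shape[0] != N_LIE:
            raise ValueError("input must have 5 channels")
        self.layers  # validate shape arithmetic eagerly

    # -- derived layer plan -------------------------------------------------

    @property
    def layers(self) -> list[dict]:
        """Ordered layer descriptors with parameter shapes."""
        k = self.kernel
        plan: list[dict] = []
        ci, dims = self.input_shape[0], list(self.input_shape[1:])
        for i, (co, s) in enumerate(zip(self.encoder_channels, self.encoder_strides)):
            if s not in (1, 2):
                raise ValueError("strides must be 1 or 2")
            if s == 2 and any(d % 2 for d in dims):
                raise ValueError(f"stride-2 encoder stage {i} needs even dims, got {dims}")
            plan.append({"kind": "conv", "name": f"enc{i}", "w": (co, ci, k, k, k),
                         "b": (co,), "stride": s})
            ci, dims = co, [(d + 1) // s if s == 2 else d for d in dims]
        cn = self.nested_channels
        plan.append({"kind": "conv", "name": "enc_nested", "w": (cn, ci, k, k, k),
                     "b": (cn,), "stride": 1})
        f = cn * int(np.prod(dims))
        sizes = (f, *self.mid_sizes, f)
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            plan.append({"kind": "dense", "name": f"mid{i}", "w": (b, a), "b": (b,)})
        plan.append({"kind": "conv", "name": "dec_nested", "w": (ci, cn, k, k, k),
                     "b": (ci,), "stride": 1})
        chans = (self.input_shape[0], *self.encoder_channels)
        for j, i in enumerate(reversed(range(len(self.encoder_channels)))):
            plan.append({"kind": "deconv", "name": f"dec{j}",
                         "w": (chans[i], chans[i + 1], k, k, k), "b": (chans[i],),
                         "upsample": self.encoder_strides[i] == 2})
        f_dec = ci * int(np.prod(dims))
        psizes = (f + f_dec, *self.perceptron_sizes, N_LIE)
        for i, (a, b) in enumerate(zip(psizes[:-1], psizes[1:])):
            plan.append({"kind": "dense", "name": f"perc{i}", "w": (b, a), "b": (b,)})
        return plan

    @property
    def bottleneck_shape(self) -> tuple[int, ...]:
        dims = list(self.input_shape[1:])
        for s in self.encoder_strides:
            dims = [(d + 1) // s if s == 2 else d for d in dims]
        return (self.nested_channels, *dims)

    def param_index(self) -> list[tuple[str, tuple[int, ...], int]]:
        idx, off = [], 0
        for layer in self.layers:
            for part in ("w", "b"):
                shape = layer[part]
                idx.append((f"{layer['name']}.{part}", shape, off))
                off += int(np.prod(shape))
        return idx

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for _, s, _ in self.param_index())

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": self.input_shape,
                "encoder_channels": self.encoder_channels,
                "encoder_strides": self.encoder_strides,
                "nested_channels": self.nested_channels,
                "kernel": self.kernel,
                "mid_sizes": self.mid_sizes,
                "perceptron_sizes": self.perceptron_sizes,
                "activation": self.activation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclass
class WeightSet:
    """Flat parameter vector with the spec's per-layer shape index."""

    vector: np.ndarray
    index: list[tuple[str, tuple[int, ...], int]]

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        expected = sum(int(np.prod(s)) for _, s, _ in self.index)
        if self.vector.size != expected:
            raise ValueError(f"weight vector length {self.vector.size} != {expected}")

    def get(self, name: str) -> np.ndarray:
        for n, shape, off in self.index:
            if n == name:
                return self.vector[off : off + int(np.prod(shape))].reshape(shape)
        raise KeyError(name)


@dataclass
class TrainingExample:
    """(docked-pose map, post-MD map, observed LIE 5-vector).  Several
    examples may share one input map — parallel MD replicas of one pose."""

    input_map: VoxelMap
    target_map: VoxelMap
    target_lie: np.ndarray

    def __post_init__(self):
        if self.input_map.grid != self.target_map.grid:
            raise ValueError("input and target maps must share one grid")
        self.target_lie = np.asarray(self.target_lie, dtype=float).ravel()
        if self.target_lie.size != N_LIE:
            raise ValueError("target_lie must have 5 components")


def init_weights(spec: NetworkSpec, rng: np.random.Generator, scale: float = 1.0) -> WeightSet:
    """Fan-in-scaled Gaussian initialization."""
    index = spec.param_index()
    vec = np.empty(spec.n_params)
    for name, shape, off in index:
        n = int(np.prod(shape))
        if name.endswith(".b"):
            vec[off : off + n] = 0.0
        else:
            fan_in = int(np.prod(shape[1:]))
            vec[off : off + n] = rng.normal(0.0, scale / np.sqrt(fan_in), n)
    return WeightSet(vec, index)


# ---------------------------------------------------------------------------
# Primitive ops (batched, float64)


def _conv3d_fwd(x, w, b, stride):
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::stride, ::stride, ::stride]
    y = np.einsum("bidhwxyz,oixyz->bodhw", win, w, optimize=True)
    y += b[None, :, None, None, None]
    return y, (win, xp.shape, w, stride, x.shape)


def _conv3d_bwd(gy, cache):
    win, xp_shape, w, stride, x_shape = cache
    k = w.shape[-1]
    p = k // 2
    gw = np.einsum("bidhwxyz,bodhw->oixyz", win, gy, optimize=True)
    gb = gy.sum(axis=(0, 2, 3, 4))
    gxp = np.zeros(xp_shape)
    do, ho, wo = gy.shape[2:]
    for a, c, e in product(range(k), range(k), range(k)):
        sl = (
            slice(None),
            slice(None),
            slice(a, a + stride * (do - 1) + 1, stride),
            slice(c, c + stride * (ho - 1) + 1, stride),
            slice(e, e + stride * (wo - 1) + 1, stride),
        )
        gxp[sl] += np.einsum("oi,bodhw->bidhw", w[:, :, a, c, e], gy, optimize=True)
    gx = gxp[:, :, p:-p, p:-p, p:-p] if p else gxp
    return gx, gw, gb


def _upsample2_fwd(x):
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def _upsample2_bwd(gy):
    b, c, d, h, w = gy.shape
    return gy.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


def _dense_fwd(x, w, b):
    return x @ w.T + b[None, :]


def _dense_bwd(gy, x, w):
    return gy @ w, gy.T @ x, gy.sum(axis=0)


# ---------------------------------------------------------------------------
# Forward / backward


def _split_params(spec: NetworkSpec, vector: np.ndarray) -> dict[str, np.ndarray]:
    params = {}
    for name, shape, off in spec.param_index():
        params[name] = vector[off : off + int(np.prod(shape))].reshape(shape)
    return params


def _forward_batch(spec: NetworkSpec, vector: np.ndarray, x: np.ndarray, keep: bool):
    """Run the full network on a batch.  Returns (pred_map, pred_lie, tape)."""
    p = _split_params(spec, vector)
    plan = spec.layers
    tape: dict = {"acts": {}}
    b = x.shape[0]

    h = x
    conv_caches = {}
    for layer in plan:
        name = layer["name"]
        if layer["kind"] == "conv" and name.startswith("enc"):
            h, cache = _conv3d_fwd(h, p[f"{name}.w"], p[f"{name}.b"], layer["stride"])
            h = np.tanh(h)
            if keep:
                conv_caches[name] = cache
                tape["acts"][name] = h
    a_enc = h  # innermost encoder activation
    bott = a_enc.shape[1:]

    h = a_enc.reshape(b, -1)
    mid_layers = [l for l in plan if l["name"].startswith("mid")]
    mid_inputs = []
    for layer in mid_layers:
        mid_inputs.append(h)
        h = np.tanh(_dense_fwd(h, p[f"{layer['name']}.w"], p[f"{layer['name']}.b"]))
    m = h.reshape((b, *bott))

    h, cache = _conv3d_fwd(m, p["dec_nested.w"], p["dec_nested.b"], 1)
    h = np.tanh(h)
    a_dec = h
    if keep:
        conv_caches["dec_nested"] = cache

    dec_layers = [l for l in plan if l["kind"] == "deconv"]
    dec_pre_up = []
    for layer in dec_layers:
        dec_pre_up.append(h.shape)
        if layer["upsample"]:
            h = _upsample2_fwd(h)
        h, cache = _conv3d_fwd(h, p[f"{layer['name']}.w"], p[f"{layer['name']}.b"], 1)
        h = np.tanh(h)
        if keep:
            conv_caches[layer["name"]] = cache
            tape["acts"][layer["name"]] = h
    pred_map = h

    pin = np.concatenate([a_enc.reshape(b, -1), a_dec.reshape(b, -1)], axis=1)
    perc_layers = [l for l in plan if l["name"].startswith("perc")]
    perc_inputs, hp = [], pin
    for i, layer in enumerate(perc_layers):
        perc_inputs.append(hp)
        hp = _dense_fwd(hp, p[f"{layer['name']}.w"], p[f"{layer['name']}.b"])
        if i < len(perc_layers) - 1:
            hp = np.tanh(hp)
    pred_lie = hp

    if keep:
        tape.update(
            params=p, conv=conv_caches, a_enc=a_enc, a_dec=a_dec, mid_inputs=mid_inputs,
            mid_layers=mid_layers, dec_layers=dec_layers, perc_inputs=perc_inputs,
            perc_layers=perc_layers, pin=pin, pred_map=pred_map, pred_lie=pred_lie, bott=bott,
        )
    return pred_map, pred_lie, tape


def forward(
    spec: NetworkSpec, weights: WeightSet, input_map: VoxelMap
) -> tuple[VoxelMap, np.ndarray]:
    """Predict (post-MD voxel map, LIE feature 5-vector) for one pose map.

    Deterministic given (spec, weights, input); the output map passes
    through tanh so its values respect the voxel bound |v| < 1.
    """
    if input_map.values.shape != spec.input_shape:
        raise ValueError(
            f"input map shape {input_map.values.shape} != spec {spec.input_shape}"
        )
    pm, pl, _ = _forward_batch(spec, weights.vector, input_map.values[None], keep=False)
    return VoxelMap(input_map.grid, pm[0]), pl[0]


def loss(pred_map, target_map, pred_lie, target_lie, mix: float = 1.0) -> float:
    """Mean-squared voxel reconstruction error + mix · mean-squared LIE error."""
    pm = pred_map.values if isinstance(pred_map, VoxelMap) else np.asarray(pred_map)
    tm = target_map.values if isinstance(target_map, VoxelMap) else np.asarray(target_map)
    if pm.shape != tm.shape:
        raise ValueError("map shape mismatch")
    pl, tl = np.asarray(pred_lie, dtype=float), np.asarray(target_lie, dtype=float)
    if pl.shape != tl.shape:
        raise ValueError("LIE vector shape mismatch")
    return float(np.mean((pm - tm) ** 2) + mix * np.mean((pl - tl) ** 2))


def loss_and_grad(
    spec: NetworkSpec,
    vector: np.ndarray,
    inputs: np.ndarray,
    target_maps: np.ndarray,
    target_lies: np.ndarray,
    mix: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Batch loss and its analytic gradient w.r.t. the flat weight vector."""
    pm, pl, tape = _forward_batch(spec, vector, inputs, keep=True)
    b = inputs.shape[0]
    map_n = b * int(np.prod(pm.shape[1:]))
    lie_n = b * N_LIE
    l_val = float(np.mean((pm - target_maps) ** 2) + mix * np.mean((pl - target_lies) ** 2))

    grads = {name: None for name, _, _ in spec.param_index()}
    p = tape["params"]

    # LIE head
    g_lie = 2.0 * mix * (pl - target_lies) / lie_n
    hp_grad = g_lie
    for i in reversed(range(len(tape["perc_layers"]))):
        layer = tape["perc_layers"][i]
        xin = tape["perc_inputs"][i]
        if i < len(tape["perc_layers"]) - 1:
            act = np.tanh(_dense_fwd(xin, p[f"{layer['name']}.w"], p[f"{layer['name']}.b"]))
            hp_grad = hp_grad * (1.0 - act**2)
        gx, gw, gb = _dense_bwd(hp_grad, xin, p[f"{layer['name']}.w"])
        grads[f"{layer['name']}.w"] = gw
        grads[f"{layer['name']}.b"] = gb
        hp_grad = gx
    f_enc = tape["a_enc"].reshape(b, -1).shape[1]
    g_a_enc_perc = hp_grad[:, :f_enc].reshape(tape["a_enc"].shape)
    g_a_dec_perc = hp_grad[:, f_enc:].reshape(tape["a_dec"].shape)

    # map head back through decoder stages
    g = 2.0 * (pm - target_maps) / map_n
    for i in reversed(range(len(tape["dec_layers"]))):
        layer = tape["dec_layers"][i]
        act = tape["acts"][layer["name"]]
        g = g * (1.0 - act**2)
        g, gw, gb = _conv3d_bwd(g, tape["conv"][layer["name"]])
        grads[f"{layer['name']}.w"] = gw
        grads[f"{layer['name']}.b"] = gb
        if layer["upsample"]:
            g = _upsample2_bwd(g)

    # nested decoder conv (activation a_dec gets both branches)
    g = (g + g_a_dec_perc) * (1.0 - tape["a_dec"] ** 2)
    g, gw, gb = _conv3d_bwd(g, tape["conv"]["dec_nested"])
    grads["dec_nested.w"] = gw
    grads["dec_nested.b"] = gb

    # mid dense chain
    g = g.reshape(b, -1)
    for i in reversed(range(len(tape["mid_layers"]))):
        layer = tape["mid_layers"][i]
        xin = tape["mid_inputs"][i]
        act = np.tanh(_dense_fwd(xin, p[f"{layer['name']}.w"], p[f"{layer['name']}.b"]))
        g = g * (1.0 - act**2)
        gx, gw, gb = _dense_bwd(g, xin, p[f"{layer['name']}.w"])
        grads[f"{layer['name']}.w"] = gw
        grads[f"{layer['name']}.b"] = gb
        g = gx

    # encoder (innermost activation a_enc gets mid + perceptron branches)
    g = g.reshape(tape["a_enc"].shape) + g_a_enc_perc
    enc_names = ["enc_nested"] + [f"enc{i}" for i in reversed(range(len(spec.encoder_channels)))]
    for name in enc_names:
        act = tape["acts"][name]
        g = g * (1.0 - act**2)
        g, gw, gb = _conv3d_bwd(g, tape["conv"][name])
        grads[f"{name}.w"] = gw
        grads[f"{name}.b"] = gb

    flat = np.empty_like(vector)
    for name, shape, off in spec.param_index():
        flat[off : off + int(np.prod(shape))] = grads[name].ravel()
    return l_val, flat


# ---------------------------------------------------------------------------
# Training: GA outer loop + Polak–Ribière CG local refinement


def _stack_dataset(dataset: Sequence[TrainingExample]):
    x = np.stack([e.input_map.values for e in dataset])
    tm = np.stack([e.target_map.values for e in dataset])
    tl = np.stack([e.target_lie for e in dataset])
    return x, tm, tl


def train(
    dataset: Sequence[TrainingExample],
    spec: NetworkSpec,
    seed: int = 0,
    ga_config: Optional[dict] = None,
    cg_config: Optional[dict] = None,
    mix: float = 1.0,
    standardize_lie: bool = True,
) -> tuple[WeightSet, list[float]]:
    """Fit the network to a training set.

    A genetic algorithm (tournament selection, uniform crossover, Gaussian
    mutation, elitism) maintains a population of flat weight vectors; every
    individual is refined by Polak–Ribière conjugate gradients (scipy's CG
    with the analytic gradient) before evaluation.  Returns the best
    individual and the best-so-far loss history — entry 0 is the best loss
    of the unrefined initial population, then one entry per generation.
    Fully reproducible from ``seed``; non-finite individuals are discarded
    with a warning and replaced by fresh random draws.

    ``standardize_lie`` (default on) optimizes against per-component
    standardized LIE targets — raw interaction energies are two orders of
    magnitude larger than the bounded voxel values, which both swamps the
    reconstruction term and ill-conditions the final linear layer.  The
    de-standardizing affine map is folded back into that layer afterwards,
    so the returned weights predict raw observables and the reported loss
    history stays in raw units.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training example")
    ga = {"population": 6, "generations": 10, "elite": 1,
          "mutation_sigma": 0.05, "mutation_rate": 0.1, "init_scale": 1.0}
    ga.update(ga_config or {})
    cg = {"max_iters": 50}
    cg.update(cg_config or {})
    if ga["population"] < 2:
        raise ValueError("population must be >= 2")

    x, tm, tl = _stack_dataset(dataset)
    for e in dataset:
        if e.input_map.values.shape != spec.input_shape:
            raise ValueError("training example shape does not match spec")

    if standardize_lie:
        lie_mu = tl.mean(axis=0)
        lie_sd = np.maximum(tl.std(axis=0), 1e-8)
    else:
        lie_mu = np.zeros(N_LIE)
        lie_sd = np.ones(N_LIE)
    tl_int = (tl - lie_mu) / lie_sd

    last = [l for l in spec.layers if l["name"].startswith("perc")][-1]["name"]

    def descale(vec: np.ndarray) -> np.ndarray:
        """Fold the target de-standardization into the final linear layer."""
        if not standardize_lie:
            return vec
        out = vec.copy()
        for name, shape, off in spec.param_index():
            if name == f"{last}.w":
                w = out[off : off + int(np.prod(shape))].reshape(shape)
                out[off : off + int(np.prod(shape))] = (lie_sd[:, None] * w).ravel()
            elif name == f"{last}.b":
                out[off : off + int(np.prod(shape))] = lie_sd * out[off : off + shape[0]] + lie_mu
        return out

    def raw_loss(vec: np.ndarray) -> float:
        pm, pl, _ = _forward_batch(spec, descale(vec), x, keep=False)
        return float(np.mean((pm - tm) ** 2) + mix * np.mean((pl - tl) ** 2))

    def fun(vec):
        return loss_and_grad(spec, vec, x, tm, tl_int, mix=mix)

    def refine(vec):
        res = minimize(fun, vec, jac=True, method="CG",
                       options={"maxiter": cg["max_iters"], "gtol": 1e-12})
        return res.x, float(res.fun)

    rng = np.random.default_rng(seed)
    index = spec.param_index()
    pop = [init_weights(spec, rng, ga["init_scale"]).vector for _ in range(ga["population"])]
    history = [min(raw_loss(v) for v in pop)]

    scored: list[tuple[float, np.ndarray]] = []
    for vec in pop:
        v, f = refine(vec)
        scored.append((f, v))
    scored = _purge_nonfinite(scored, spec, rng, ga, refine)
    best_raw, best_v = min(((raw_loss(v), v) for _, v in scored), key=lambda t: t[0])

    for _ in range(ga["generations"]):
        scored.sort(key=lambda t: t[0])
        next_pop = [v for _, v in scored[: ga["elite"]]]
        while len(next_pop) < ga["population"]:
            pa = _tournament(scored, rng)
            pb = _tournament(scored, rng)
            mask = rng.random(pa.size) < 0.5
            child = np.where(mask, pa, pb)
            mut = rng.random(child.size) < ga["mutation_rate"]
            child = child.copy()
            child[mut] += rng.normal(0.0, ga["mutation_sigma"], int(mut.sum()))
            next_pop.append(child)
        scored = []
        for vec in next_pop:
            v, f = refine(vec)
            scored.append((f, v))
        scored = _purge_nonfinite(scored, spec, rng, ga, refine)
        gen_raw, gen_v = min(((raw_loss(v), v) for _, v in scored), key=lambda t: t[0])
        if gen_raw < best_raw:
            best_raw, best_v = gen_raw, gen_v
        history.append(best_raw)
    return WeightSet(descale(best_v), index), history


def _tournament(scored, rng, k: int = 2) -> np.ndarray:
    picks = rng.integers(0, len(scored), size=k)
    best = min(picks, key=lambda i: scored[i][0])
    return scored[best][1]


def _purge_nonfinite(scored, spec, rng, ga, refine):
    clean = [(f, v) for f, v in scored if np.isfinite(f) and np.isfinite(v).all()]
    n_bad = len(scored) - len(clean)
    if n_bad:
        warnings.warn(f"discarding {n_bad} non-finite individual(s)", stacklevel=2)
        for _ in range(n_bad):
            v, f = refine(init_weights(spec, rng, ga["init_scale"]).vector)
            if np.isfinite(f):
                clean.append((f, v))
    if not clean:
        raise RuntimeError("all individuals produced non-finite losses")
    return clean


# ---------------------------------------------------------------------------
# Pose scoring


def score_pose(
    weights: WeightSet,
    spec: NetworkSpec,
    pose_map: VoxelMap,
    lie_params: LIEParams,
    reference_maps: Sequence[VoxelMap],
) -> tuple[float, float]:
    """Dual score of a docked pose.

    Energetic: the single-replica LIE form applied to the network's
    predicted 5 observables (lower = more favourable).  Geometric: the
    maximum voxel similarity between the predicted post-MD map and the
    reference maps of resolved/MD-evaluated complexes (higher = closer).
    """
    if not reference_maps:
        raise ValueError("reference_maps must be non-empty")
    pred_map, pred_lie = forward(spec, weights, pose_map)
    energetic = replica_dg(ReplicaObservables.from_vector(pred_lie), lie_params)
    geometric = max(voxel_similarity(pred_map, ref) for ref in reference_maps)
    return energetic, geometric


# ---------------------------------------------------------------------------
# Serialization: flat binary weights + JSON-indexed sidecar


def save_weights(weights: WeightSet, spec: NetworkSpec, path: str | Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), weights.vector)
    meta = {"spec": json.loads(spec.to_json()),
            "index": [[n, list(s), o] for n, s, o in weights.index]}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_weights(path: str | Path) -> tuple[WeightSet, NetworkSpec]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec.from_json(json.dumps(meta["spec"]))
    vec = np.load(path.with_suffix(".npy"))
    index = [(n, tuple(s), o) for n, s, o in meta["index"]]
    return WeightSet(vec, index), spec
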