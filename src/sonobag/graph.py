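"""Correlation graph over image features and the aggregate encoder.

A subject's S per-image embeddings become the nodes of an undirected
graph: images s and r are linked when the Pearson correlation of their
embeddings reaches a threshold tau (default 0.995). A permutation-
equivariant graph encoder ψ (GAT or GIN blocks) transforms the node
embeddings over that graph, a global max pooling layer θ collapses them
into a single summary vector z — converting equivariance into
invariance to image order — and a multinomial-logit head turns z into
class scores σ_1..σ_K with the diagnosis k̂ = argmax_k σ_k.

Ablation baselines ignore the graph: ``mlp`` applies the same 1- or
2-block MLP to each row independently before pooling; ``max`` pools the
raw features directly.

Block internals follow the canonical cited architectures: a GAT block
is a (multi-head) attention layer with LeakyReLU(0.2) attention logits,
softmax over the self-loop-augmented neighbourhood, ELU output and an
identity residual when dimensions match; a GIN block sums neighbour
features plus an (1+ε)-weighted self term through a two-layer ReLU MLP
(ε covers the self contribution, so GIN adjacency carries no self
loops).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .encoding import FeatureMatrix

__all__ = [
    "SubjectGraph",
    "AggregateEncoderSpec",
    "HeadParams",
    "ScoreVector",
    "pearson_correlation",
    "build_graph",
    "init_params",
    "gat_block",
    "gin_block",
    "mlp_block",
    "global_max_pool",
    "classify_scores",
    "forward_subject",
    "forward_tensor",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_TAU = 0.995


@dataclass
class SubjectGraph:
    """Binary symmetric adjacency over a subject's S images."""

    adjacency: np.ndarray  # S x S, 0/1, zero diagonal
    tau: float = DEFAULT_TAU

    @property
    def S(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class AggregateEncoderSpec:
    """Which aggregate encoder ψ to use and its sizes."""

    kind: str = "gat"  # gat | gin | mlp | max
    n_blocks: int = 1  # 1 or 2 (ignored for max)
    hidden_dim: int = 512
    heads: int = 1  # gat only
    epsilon: float = 0.0  # gin only

    def __post_init__(self):
        if self.kind not in {"gat", "gin", "mlp", "max"}:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.n_blocks not in (1, 2):
            raise ValueError("n_blocks must be 1 or 2")
        if self.hidden_dim < 1 or self.heads < 1:
            raise ValueError("hidden_dim and heads must be >= 1")
        if self.kind == "gat" and self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")


@dataclass
class HeadParams:
    """Multinomial-logit output layer: σ_k ∝ exp(δ_k + β_kᵀ z)."""

    deltas: np.ndarray  # (K,)
    betas: np.ndarray  # (K, dim)


@dataclass
class ScoreVector:
    sigma: np.ndarray  # length-K simplex vector
    k_hat: int  # 1-based argmax, ties to the smallest index
    summary: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------

def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation, with a deterministic rule for the
    degenerate case: if either vector has zero variance the statistic is
    undefined; we return 1.0 for exactly equal vectors and 0.0 otherwise
    (conservative: no edge)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    ac = a - a.mean()
    bc = b - b.mean()
    va = ac @ ac
    vb = bc @ bc
    if va == 0.0 or vb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.clip((ac @ bc) / np.sqrt(va * vb), -1.0, 1.0))


def build_graph(F: FeatureMatrix | np.ndarray, tau: float = DEFAULT_TAU) -> SubjectGraph:
    """Link images s != r when Corr(h_s, h_r) >= tau."""
    X = F.features if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    S = X.shape[0]
    adj = np.zeros((S, S), dtype=np.int8)
    if S > 1:
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((Xc * Xc).sum(axis=1))
        ok = norms > 0
        safe = np.where(ok, norms, 1.0)
        C = np.clip((Xc / safe[:, None]) @ (Xc / safe[:, None]).T, -1.0, 1.0)
        # degenerate rows: corr = 1 iff exactly equal, else 0
        for s in np.nonzero(~ok)[0]:
            C[s, :] = [1.0 if np.array_equal(X[s], X[r]) else 0.0 for r in range(S)]
            C[:, s] = C[s, :]
        adj = (C >= tau).astype(np.int8)
        np.fill_diagonal(adj, 0)
    return SubjectGraph(adjacency=adj, tau=tau)


# ---------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)),
                  requires_grad=True)


def init_params(spec: AggregateEncoderSpec, d_in: int, K: int, seed: int = 0) -> dict:
    """Glorot-uniform block parameters plus a zero-initialised head.

    Returns a flat dict name -> Tensor; the head input dimension is
    `d_in` for the max baseline (which bypasses ψ) and `hidden_dim`
    otherwise.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    dh = spec.hidden_dim
    if spec.kind == "gat":
        per_head = dh // spec.heads
        din = d_in
        for b in range(spec.n_blocks):
            for h in range(spec.heads):
                params[f"block{b}_head{h}_W"] = _glorot(rng, din, per_head)
                params[f"block{b}_head{h}_asrc"] = _glorot(rng, per_head, 1, (per_head, 1))
                params[f"block{b}_head{h}_adst"] = _glorot(rng, per_head, 1, (per_head, 1))
            din = dh
        head_dim = dh
    elif spec.kind == "gin":
        din = d_in
        for b in range(spec.n_blocks):
            params[f"block{b}_W1"] = _glorot(rng, din, dh)
            params[f"block{b}_b1"] = Tensor(np.zeros((1, dh)), requires_grad=True)
            params[f"block{b}_W2"] = _glorot(rng, dh, dh)
            params[f"block{b}_b2"] = Tensor(np.zeros((1, dh)), requires_grad=True)
            din = dh
        head_dim = dh
    elif spec.kind == "mlp":
        din = d_in
        for b in range(spec.n_blocks):
            params[f"block{b}_W"] = _glorot(rng, din, dh)
            params[f"block{b}_b"] = Tensor(np.zeros((1, dh)), requires_grad=True)
            din = dh
        head_dim = dh
    else:  # max baseline: no ψ parameters
        head_dim = d_in
    params["head_delta"] = Tensor(np.zeros((1, K)), requires_grad=True)
    params["head_beta"] = Tensor(
        rng.normal(0.0, 1.0 / np.sqrt(head_dim), size=(K, head_dim)), requires_grad=True
    )
    return params


# ---------------------------------------------------------------------
# blocks (Tensor in, Tensor out — differentiable)
# ---------------------------------------------------------------------

def gat_block(H: Tensor, graph: SubjectGraph, params: dict, block: int,
              heads: int) -> Tensor:
    S = graph.S
    if H.shape[0] != S:
        raise ValueError("graph size does not match node count")
    mask = graph.adjacency.astype(np.float64) + np.eye(S)  # self-loops
    outs = []
    for h in range(heads):
        W = params[f"block{block}_head{h}_W"]
        Wh = H @ W
        f = Wh @ params[f"block{block}_head{h}_asrc"]  # (S,1)
        g = Wh @ params[f"block{block}_head{h}_adst"]  # (S,1)
        E = (f + g.T).leaky_relu(0.2)
        alpha = E.softmax_rows(mask)
        outs.append(alpha @ Wh)
    out = outs[0]
    for o in outs[1:]:  # concatenate heads along features
        out = _concat_cols(out, o)
    out = out.elu()
    if out.shape == H.shape:  # identity residual when dims match
        out = out + H
    return out


def _concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Column-concatenation via padding matmuls (keeps the op set small)."""
    na, nb = a.shape[1], b.shape[1]
    Pa = np.zeros((na, na + nb))
    Pa[:, :na] = np.eye(na)
    Pb = np.zeros((nb, na + nb))
    Pb[:, na:] = np.eye(nb)
    return a @ Tensor(Pa) + b @ Tensor(Pb)


def gin_block(H: Tensor, graph: SubjectGraph, params: dict, block: int,
              epsilon: float = 0.0) -> Tensor:
    if H.shape[0] != graph.S:
        raise ValueError("graph size does not match node count")
    A = Tensor(graph.adjacency.astype(np.float64))  # no self loops: ε term covers self
    agg = H * (1.0 + epsilon) + A @ H
    hidden = (agg @ params[f"block{block}_W1"] + params[f"block{block}_b1"]).relu()
    return hidden @ params[f"block{block}_W2"] + params[f"block{block}_b2"]


def mlp_block(H: Tensor, params: dict, block: int) -> Tensor:
    return (H @ params[f"block{block}_W"] + params[f"block{block}_b"]).relu()


def global_max_pool(U: Tensor | np.ndarray) -> Tensor | np.ndarray:
    """Column-wise max over nodes: z_j = max_s U[s, j]."""
    if isinstance(U, Tensor):
        if U.shape[0] < 1:
            raise ValueError("empty input")
        return U.max(axis=0, keepdims=True)  # (1, d)
    U = np.asarray(U, dtype=np.float64)
    if U.shape[0] < 1:
        raise ValueError("empty input")
    return U.max(axis=0)


def classify_scores(z: np.ndarray, head: HeadParams) -> ScoreVector:
    """σ_k = softmax(δ_k + β_kᵀ z), overflow-safe; ties go to the
    smallest class index."""
    z = np.asarray(z, dtype=np.float64).ravel()
    logits = head.deltas.ravel() + head.betas @ z
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    logits = logits - logits.max()
    e = np.exp(logits)
    sigma = e / e.sum()
    return ScoreVector(sigma=sigma, k_hat=int(np.argmax(sigma)) + 1, summary=z)


# ---------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------

def forward_tensor(F: np.ndarray, spec: AggregateEncoderSpec, params: dict,
                   tau: float = DEFAULT_TAU, F_graph: np.ndarray | None = None) -> Tensor:
    """Differentiable forward pass to the logits (shape (1, K)).

    `F_graph` optionally supplies the matrix the correlation graph is
    built from (e.g. raw encoder features when the node attributes have
    been rescaled); defaults to `F` itself.
    """
    H = Tensor(np.atleast_2d(np.asarray(F, dtype=np.float64)))
    if spec.kind == "max":
        z = global_max_pool(H)
    else:
        if spec.kind in ("gat", "gin"):
            graph = build_graph(H.data if F_graph is None else np.atleast_2d(F_graph), tau)
        U = H
        for b in range(spec.n_blocks):
            if spec.kind == "gat":
                U = gat_block(U, graph, params, b, spec.heads)
            elif spec.kind == "gin":
                U = gin_block(U, graph, params, b, spec.epsilon)
            else:
                U = mlp_block(U, params, b)
        z = global_max_pool(U)
    return z @ params["head_beta"].T + params["head_delta"]


def forward_subject(F: FeatureMatrix | np.ndarray, spec: AggregateEncoderSpec,
                    params: dict, tau: float = DEFAULT_TAU,
                    F_graph: np.ndarray | None = None) -> ScoreVector:
    """Graph construction → blocks → max pooling → softmax scores."""
    X = F.features if isinstance(F, FeatureMatrix) else np.asarray(F)
    logits = forward_tensor(X, spec, params, tau, F_graph=F_graph).data.ravel()
    logits = logits - logits.max()
    e = np.exp(logits)
    sigma = e / e.sum()
    return ScoreVector(sigma=sigma, k_hat=int(np.argmax(sigma)) + 1)


def head_from_params(params: dict) -> HeadParams:
    return HeadParams(deltas=params["head_delta"].data.ravel().copy(),
                      betas=params["head_beta"].data.copy())


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

_SCHEMA = 1


def save_checkpoint(path: str | Path, spec: AggregateEncoderSpec, params: dict,
                    tau: float, extra: dict | None = None) -> None:
    """Single JSON archive with spec, tau and all parameters."""
    payload = {
        "schema": _SCHEMA,
        "tau": tau,
        "spec": {"kind": spec.kind, "n_blocks": spec.n_blocks,
                 "hidden_dim": spec.hidden_dim, "heads": spec.heads,
                 "epsilon": spec.epsilon},
        "params": {k: v.data.tolist() for k, v in params.items()},
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {payload.get('schema')}")
    spec = AggregateEncoderSpec(**payload["spec"])
    params = {k: Tensor(np.asarray(v), requires_grad=True)
              for k, v in payload["params"].items()}
    return spec, params, payload["tau"], payload.get("extra", {})
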