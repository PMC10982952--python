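"""Edge-biased graph-transformer encoder for sequence design.

The encoder is a pre-LN Transformer stack whose attention scores receive an
additive per-head bias derived from embedded edge features:

    A_ij = (h_i W_Q)(h_j W_K)^T / sqrt(d_K) + C_att(i, j)

where C_att is the mean of the edge-embedding dimensions routed to the
head.  Node features are embedded linearly to ``d_model``; the four edge
feature groups are joined on the last axis and passed through a two-layer
MLP whose output width equals the number of attention heads.  Six blocks
are stacked (independent weights by default; a shared-weights "recycling"
mode is available), from the second block onwards node information flows
back into the edge embedding through an additive pairwise update.  A linear
layer plus softmax over 22 classes (20 amino acids, unknown, padding) gives
per-position residue probabilities; training minimizes the mean
cross-entropy over residues.

Everything is plain float64 numpy with hand-written reverse-mode gradients
(verified against finite differences in the test suite) and an Adam
optimizer, so the package has no deep-learning framework dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .featurize import GraphFeatures, EDGE_DIM, DIHEDRAL_DIM, SS_DIM, \
    CENTRALITY_DIM, PREDESIGN_DIM

_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the published architecture: 10 heads, feed-forward
    width 1024, 6 stacked blocks, 22-way output.  ``d_model`` (unstated in
    the source method) defaults to 320, i.e. 32 per head.
    """

    d_model: int = 320
    n_heads: int = 10
    d_ffn: int = 1024
    n_blocks: int = 6
    vocab: int = 22
    d_edge_hidden: int = 64
    d_noise: int = 16
    d_edge_in: int = EDGE_DIM
    dropout: float = 0.0
    edge_update: bool = True        # node->edge flow in blocks >= 2
    shared_weights: bool = False    # recycle one block's weights

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.vocab != 22:
            raise ValueError("the sequence vocabulary is fixed at 22")

    @property
    def d_node_in(self) -> int:
        return DIHEDRAL_DIM + SS_DIM + CENTRALITY_DIM + PREDESIGN_DIM + self.d_noise

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale configuration for fixtures and CPU training."""
        return cls(d_model=96, n_heads=4, d_ffn=192, n_blocks=3,
                   d_edge_hidden=32, d_noise=8)


def _xavier(rng, shape, scale=1.0):
    limit = scale * np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _block_key(cfg: ModelConfig, k: int) -> int:
    return 0 if cfg.shared_weights else k


def init_state(cfg: ModelConfig, seed: int = 0) -> dict:
    """Fresh parameter tensors.  The output head starts near zero so an
    untrained model emits near-uniform residue probabilities."""
    rng = np.random.default_rng(seed)
    p = {
        "node_W": _xavier(rng, (cfg.d_node_in, cfg.d_model)),
        "node_b": np.zeros(cfg.d_model),
        "edge_W1": _xavier(rng, (cfg.d_edge_in, cfg.d_edge_hidden)),
        "edge_b1": np.zeros(cfg.d_edge_hidden),
        "edge_W2": _xavier(rng, (cfg.d_edge_hidden, cfg.n_heads)),
        "edge_b2": np.zeros(cfg.n_heads),
        "out_W": 0.01 * _xavier(rng, (cfg.d_model, cfg.vocab)),
        "out_b": np.zeros(cfg.vocab),
        "_step": np.zeros(1),
    }
    n_unique = 1 if cfg.shared_weights else cfg.n_blocks
    for k in range(n_unique):
        d = cfg.d_model
        p[f"blk{k}_ln1_g"] = np.ones(d)
        p[f"blk{k}_ln1_b"] = np.zeros(d)
        p[f"blk{k}_Wq"] = _xavier(rng, (d, d))
        p[f"blk{k}_Wk"] = _xavier(rng, (d, d))
        p[f"blk{k}_Wv"] = _xavier(rng, (d, d))
        p[f"blk{k}_Wo"] = _xavier(rng, (d, d))
        p[f"blk{k}_bo"] = np.zeros(d)
        p[f"blk{k}_ln2_g"] = np.ones(d)
        p[f"blk{k}_ln2_b"] = np.zeros(d)
        p[f"blk{k}_W1"] = _xavier(rng, (d, cfg.d_ffn))
        p[f"blk{k}_b1"] = np.zeros(cfg.d_ffn)
        p[f"blk{k}_W2"] = _xavier(rng, (cfg.d_ffn, d))
        p[f"blk{k}_b2"] = np.zeros(d)
        p[f"blk{k}_Wea"] = _xavier(rng, (d, cfg.n_heads))
        p[f"blk{k}_Web"] = _xavier(rng, (d, cfg.n_heads))
        p[f"blk{k}_beu"] = np.zeros(cfg.n_heads)
    return p


# --------------------------------------------------------------------------
# layer primitives (forward + cached backward)
# --------------------------------------------------------------------------

def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


def _softmax(x, axis=-1):
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def edge_bias(H_e: np.ndarray, head: int, n_heads: int | None = None) -> np.ndarray:
    """Per-head additive attention bias from the edge embedding.

    The embedded edge dimensions are split evenly across heads and the
    head's bias at (i, j) is the mean of its slice — with the edge
    embedding already at width ``n_heads`` each head reads one dimension.
    """
    d_e = H_e.shape[-1]
    if n_heads is None:
        n_heads = 1
    if d_e % n_heads != 0:
        raise ValueError("edge width must divide evenly across heads")
    chunk = d_e // n_heads
    return H_e[..., head * chunk:(head + 1) * chunk].mean(axis=-1)


def embed_features(gf: GraphFeatures, state: dict, cfg: ModelConfig):
    """Linear node embedding to d_model; two-layer edge MLP to n_heads."""
    X = gf.nodes
    E = gf.edges
    if X.shape[1] != cfg.d_node_in:
        raise ValueError(
            f"node feature width {X.shape[1]} != expected {cfg.d_node_in}")
    if E.shape[2] != cfg.d_edge_in:
        raise ValueError("edge feature width mismatch")
    H = X @ state["node_W"] + state["node_b"]
    A1 = E @ state["edge_W1"] + state["edge_b1"]
    A1r = np.maximum(A1, 0.0)
    H_e = A1r @ state["edge_W2"] + state["edge_b2"]
    return H, H_e


def attention_weights(H: np.ndarray, H_e: np.ndarray, head: int,
                      state: dict, cfg: ModelConfig, block: int = 0) -> np.ndarray:
    """Pre-softmax Graphormer attention scores for one head."""
    bk = _block_key(cfg, block)
    dk = cfg.d_head
    Wq = state[f"blk{bk}_Wq"][:, head * dk:(head + 1) * dk]
    Wk = state[f"blk{bk}_Wk"][:, head * dk:(head + 1) * dk]
    scores = (H @ Wq) @ (H @ Wk).T / np.sqrt(dk)
    return scores + edge_bias(H_e, head, cfg.n_heads)


def _split_heads(x, n_heads):
    n, d = x.shape
    return x.reshape(n, n_heads, d // n_heads).transpose(1, 0, 2)


def _merge_heads(x):
    h, n, dk = x.shape
    return x.transpose(1, 0, 2).reshape(n, h * dk)


def _block_fwd(H, H_e, state, cfg, k, mask, train_rng=None):
    bk = _block_key(cfg, k)
    p = lambda name: state[f"blk{bk}_{name}"]
    nh, dk = cfg.n_heads, cfg.d_head
    N = H.shape[0]
    cache = {"H_in": H, "H_e_in": H_e}

    Hn, ln1c = _layernorm_fwd(H, p("ln1_g"), p("ln1_b"))
    Q = _split_heads(Hn @ p("Wq"), nh)
    K = _split_heads(Hn @ p("Wk"), nh)
    V = _split_heads(Hn @ p("Wv"), nh)
    chunk = H_e.shape[-1] // nh
    bias = H_e.reshape(N, N, nh, chunk).mean(axis=-1).transpose(2, 0, 1)
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(dk) + bias
    if mask is not None and not mask.all():
        S = np.where(mask[None, None, :], S, -np.inf)
    P = _softmax(S, axis=-1)
    ctx = _merge_heads(P @ V)
    attn = ctx @ p("Wo") + p("bo")
    drop1 = None
    if train_rng is not None and cfg.dropout > 0:
        drop1 = (train_rng.random(attn.shape) >= cfg.dropout) / (1 - cfg.dropout)
        attn = attn * drop1
    H1 = H + attn

    Hn2, ln2c = _layernorm_fwd(H1, p("ln2_g"), p("ln2_b"))
    Z = Hn2 @ p("W1") + p("b1")
    Zr = np.maximum(Z, 0.0)
    F = Zr @ p("W2") + p("b2")
    drop2 = None
    if train_rng is not None and cfg.dropout > 0:
        drop2 = (train_rng.random(F.shape) >= cfg.dropout) / (1 - cfg.dropout)
        F = F * drop2
    H2 = H1 + F

    H_e_out = H_e
    if cfg.edge_update and k >= 1:
        U = H2 @ p("Wea")
        W = H2 @ p("Web")
        H_e_out = H_e + U[:, None, :] + W[None, :, :] + p("beu")
    cache.update(Hn=Hn, ln1c=ln1c, Q=Q, K=K, V=V, P=P, ctx=ctx,
                 H1=H1, Hn2=Hn2, ln2c=ln2c, Z=Z, Zr=Zr, H2=H2,
                 drop1=drop1, drop2=drop2, chunk=chunk)
    return H2, H_e_out, cache


def _block_bwd(dH2, dHe_out, cache, state, grads, cfg, k):
    bk = _block_key(cfg, k)
    p = lambda name: state[f"blk{bk}_{name}"]
    def acc(name, g):
        grads[f"blk{bk}_{name}"] = grads.get(f"blk{bk}_{name}", 0.0) + g
    nh, dk = cfg.n_heads, cfg.d_head
    H2, H_e_in = cache["H2"], cache["H_e_in"]
    N = H2.shape[0]

    dH2 = dH2.copy()
    dHe = dHe_out
    if cfg.edge_update and k >= 1:
        dU = dHe_out.sum(axis=1)
        dW = dHe_out.sum(axis=0)
        acc("beu", dHe_out.sum(axis=(0, 1)))
        acc("Wea", H2.T @ dU)
        acc("Web", H2.T @ dW)
        dH2 += dU @ p("Wea").T + dW @ p("Web").T
        dHe = dHe_out  # additive update: gradient passes through unchanged

    # FFN
    dF = dH2
    if cache["drop2"] is not None:
        dF = dF * cache["drop2"]
    dH1 = dH2.copy()
    acc("W2", cache["Zr"].T @ dF)
    acc("b2", dF.sum(axis=0))
    dZr = dF @ p("W2").T
    dZ = dZr * (cache["Z"] > 0)
    acc("W1", cache["Hn2"].T @ dZ)
    acc("b1", dZ.sum(axis=0))
    dHn2 = dZ @ p("W1").T
    dx, dg, db = _layernorm_bwd(dHn2, cache["ln2c"])
    acc("ln2_g", dg)
    acc("ln2_b", db)
    dH1 += dx

    # attention
    dattn = dH1
    if cache["drop1"] is not None:
        dattn = dattn * cache["drop1"]
    dH = dH1.copy()
    acc("Wo", cache["ctx"].T @ dattn)
    acc("bo", dattn.sum(axis=0))
    dctx = (dattn @ p("Wo").T).reshape(N, nh, dk).transpose(1, 0, 2)
    P, Q, K, V = cache["P"], cache["Q"], cache["K"], cache["V"]
    dP = dctx @ V.transpose(0, 2, 1)
    dV = P.transpose(0, 2, 1) @ dctx
    dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
    # edge bias gradient
    chunk = cache["chunk"]
    dbias = dS.transpose(1, 2, 0)                       # (N, N, nh)
    dHe = dHe + np.repeat(dbias / chunk, chunk, axis=-1)
    dQ = dS @ K / np.sqrt(dk)
    dK = dS.transpose(0, 2, 1) @ Q / np.sqrt(dk)
    Hn = cache["Hn"]
    for name, dmat in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
        merged = _merge_heads(dmat)
        acc(name, Hn.T @ merged)
    dHn = (_merge_heads(dQ) @ p("Wq").T + _merge_heads(dK) @ p("Wk").T
           + _merge_heads(dV) @ p("Wv").T)
    dx, dg, db = _layernorm_bwd(dHn, cache["ln1c"])
    acc("ln1_g", dg)
    acc("ln1_b", db)
    dH += dx
    return dH, dHe


def forward(gf: GraphFeatures, state: dict, cfg: ModelConfig,
            return_cache: bool = False):
    """Full encoder pass: (logits, probabilities) per position."""
    if gf.nodes.shape[0] == 0:
        raise ValueError("empty input (N = 0)")
    H, H_e = embed_features(gf, state, cfg)
    caches = []
    for k in range(cfg.n_blocks):
        H, H_e, c = _block_fwd(H, H_e, state, cfg, k, gf.mask)
        caches.append(c)
    logits = H @ state["out_W"] + state["out_b"]
    probs = _softmax(logits, axis=-1)
    if return_cache:
        return logits, probs, (caches, H)
    return logits, probs


def cross_entropy_loss(logits: np.ndarray, targets: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Mean cross-entropy over (non-padding) positions.

    l_n = log( sum_c exp(x_nc) / exp(x_n,y_n) ),  L = mean_n l_n.
    """
    targets = np.asarray(targets)
    if np.any(targets < 0) or np.any(targets >= logits.shape[1]):
        raise ValueError("target index outside the 22-token vocabulary")
    if mask is None:
        mask = np.ones(len(targets), dtype=bool)
    m = np.max(logits, axis=1, keepdims=True)
    lse = np.log(np.exp(logits - m).sum(axis=1)) + m[:, 0]
    l_n = lse - logits[np.arange(len(targets)), targets]
    return float(l_n[mask].mean())


def loss_and_grads(gf: GraphFeatures, targets: np.ndarray, state: dict,
                   cfg: ModelConfig, loss_mask: np.ndarray | None = None,
                   train_rng=None):
    """Forward + hand-written backward pass; returns (loss, grads dict)."""
    if gf.nodes.shape[0] == 0:
        raise ValueError("empty input (N = 0)")
    targets = np.asarray(targets)
    if np.any(targets >= cfg.vocab):
        raise ValueError("target index outside the 22-token vocabulary")
    if loss_mask is None:
        loss_mask = np.ones(len(targets), dtype=bool)

    H, H_e = embed_features(gf, state, cfg)
    caches = []
    for k in range(cfg.n_blocks):
        H, H_e, c = _block_fwd(H, H_e, state, cfg, k, gf.mask, train_rng)
        caches.append(c)
    logits = H @ state["out_W"] + state["out_b"]
    probs = _softmax(logits, axis=-1)
    loss = cross_entropy_loss(logits, targets, loss_mask)

    n_valid = int(loss_mask.sum())
    dlogits = probs.copy()
    dlogits[np.arange(len(targets)), targets] -= 1.0
    dlogits[~loss_mask] = 0.0
    dlogits /= n_valid

    grads = {
        "out_W": H.T @ dlogits,
        "out_b": dlogits.sum(axis=0),
    }
    dH = dlogits @ state["out_W"].T
    dHe = np.zeros_like(H_e)
    for k in reversed(range(cfg.n_blocks)):
        dH, dHe = _block_bwd(dH, dHe, caches[k], state, grads, cfg, k)

    # embedding backward
    grads["node_W"] = gf.nodes.T @ dH
    grads["node_b"] = dH.sum(axis=0)
    E = gf.edges
    A1 = E @ state["edge_W1"] + state["edge_b1"]
    A1r = np.maximum(A1, 0.0)
    de = dHe.shape[-1]
    grads["edge_W2"] = A1r.reshape(-1, A1r.shape[-1]).T @ dHe.reshape(-1, de)
    grads["edge_b2"] = dHe.sum(axis=(0, 1))
    dA1 = (dHe @ state["edge_W2"].T) * (A1 > 0)
    grads["edge_W1"] = E.reshape(-1, E.shape[-1]).T @ dA1.reshape(-1, dA1.shape[-1])
    grads["edge_b1"] = dA1.sum(axis=(0, 1))
    return loss, grads


def graphormer_block(H: np.ndarray, H_e: np.ndarray, state: dict,
                     cfg: ModelConfig, block_index: int,
                     mask: np.ndarray | None = None):
    """Apply one pre-LN Graphormer block; returns (H', H_e')."""
    H2, He2, _ = _block_fwd(H, H_e, state, cfg, block_index, mask)
    return H2, He2


# --------------------------------------------------------------------------
# optimizer and checkpointing
# --------------------------------------------------------------------------

@dataclass
class AdamOptimizer:
    """Adam with global-norm gradient clipping (clip at 1.0)."""

    lr: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip_norm: float = 1.0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, state: dict, grads: dict) -> None:
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, self.clip_norm / (gnorm + 1e-12))
        self.t += 1
        for key, g in grads.items():
            g = g * scale
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g ** 2
            mhat = self.m[key] / (1 - self.beta1 ** self.t)
            vhat = self.v[key] / (1 - self.beta2 ** self.t)
            state[key] = state[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        state["_step"] = state.get("_step", np.zeros(1)) + 1


def save_state(path, state: dict, cfg: ModelConfig) -> None:
    """Checkpoint: npz of parameter tensors with a JSON config header."""
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8), **state)


def load_state(path):
    """Load a checkpoint; returns (state, config) bit-identically."""
    data = np.load(path)
    cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
    state = {k: data[k] for k in data.files if k != "__config__"}
    return state, cfg
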