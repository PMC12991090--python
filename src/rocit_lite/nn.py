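"""Encoder-only transformer read classifier, implemented directly on numpy.

The network follows the pre-layer-norm encoder design: two feed-forward
input encoders (one for the 21-vector of methylation + normalized position +
19 site percentiles, one for the 84 atlas values with a learned
missing-value embedding), summed with a scaled learned absolute position
embedding, a prepended learned CLS vector, a stack of bias-free pre-LN
attention blocks with GELU feed-forward sublayers, and a linear head from
the final CLS state to one logit.

Forward and backward passes are hand-derived; the backward pass also yields
the gradient with respect to the per-CpG methylation input, which drives the
counterfactual perturbation engine.  Hot elementwise kernels (masked
softmax, GELU) are JIT-compiled with numba when available and fall back to
vectorized numpy otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy import special as sps

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# elementwise kernels
# ---------------------------------------------------------------------------

def _gelu_np(x):
    return 0.5 * x * (1.0 + sps.erf(x / _SQRT2))


def _gelu_grad_np(x):
    return 0.5 * (1.0 + sps.erf(x / _SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def _softmax_masked_np(scores, key_valid):
    # scores (B, H, S, S); key_valid (B, S)
    neg = np.finfo(scores.dtype).min / 4
    masked = np.where(key_valid[:, None, None, :], scores, neg)
    m = masked.max(axis=-1, keepdims=True)
    e = np.exp(masked - m)
    e *= key_valid[:, None, None, :]
    denom = e.sum(axis=-1, keepdims=True)
    return e / np.maximum(denom, 1e-30)


def _softmax_bwd_np(p, dp):
    inner = np.sum(p * dp, axis=-1, keepdims=True)
    return p * (dp - inner)


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _gelu_nb(x_flat, out):  # pragma: no cover - numba
        for i in range(x_flat.size):
            v = x_flat[i]
            out[i] = 0.5 * v * (1.0 + math.erf(v / _SQRT2))

    @numba.njit(cache=True, fastmath=True)
    def _gelu_grad_nb(x_flat, out):  # pragma: no cover - numba
        for i in range(x_flat.size):
            v = x_flat[i]
            out[i] = 0.5 * (1.0 + math.erf(v / _SQRT2)) + v * math.exp(-0.5 * v * v) * _INV_SQRT_2PI

    @numba.njit(cache=True, fastmath=True)
    def _softmax_masked_nb(scores, key_valid, out):  # pragma: no cover - numba
        B, R, S = scores.shape
        for b in range(B):
            for r in range(R):
                m = -1e30
                for s in range(S):
                    if key_valid[b, s] and scores[b, r, s] > m:
                        m = scores[b, r, s]
                tot = 0.0
                for s in range(S):
                    if key_valid[b, s]:
                        e = math.exp(scores[b, r, s] - m)
                        out[b, r, s] = e
                        tot += e
                    else:
                        out[b, r, s] = 0.0
                inv = 1.0 / tot
                for s in range(S):
                    out[b, r, s] *= inv

    @numba.njit(cache=True, fastmath=True)
    def _softmax_bwd_nb(p, dp, out):  # pragma: no cover - numba
        B, R, S = p.shape
        for b in range(B):
            for r in range(R):
                inner = 0.0
                for s in range(S):
                    inner += p[b, r, s] * dp[b, r, s]
                for s in range(S):
                    out[b, r, s] = p[b, r, s] * (dp[b, r, s] - inner)


def gelu(x: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA and x.dtype == np.float32:
        out = np.empty_like(x)
        _gelu_nb(x.reshape(-1), out.reshape(-1))
        return out
    return _gelu_np(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA and x.dtype == np.float32:
        out = np.empty_like(x)
        _gelu_grad_nb(x.reshape(-1), out.reshape(-1))
        return out
    return _gelu_grad_np(x)


def softmax_masked(scores: np.ndarray, key_valid: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA and scores.dtype == np.float32:
        B, H, S1, S2 = scores.shape
        flat = np.ascontiguousarray(scores).reshape(B, H * S1, S2)
        out = np.empty_like(flat)
        _softmax_masked_nb(flat, key_valid, out)
        return out.reshape(B, H, S1, S2)
    return _softmax_masked_np(scores, key_valid)


def softmax_bwd(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA and p.dtype == np.float32:
        B, H, S1, S2 = p.shape
        pf = np.ascontiguousarray(p).reshape(B, H * S1, S2)
        dpf = np.ascontiguousarray(dp).reshape(B, H * S1, S2)
        out = np.empty_like(pf)
        _softmax_bwd_nb(pf, dpf, out)
        return out.reshape(B, H, S1, S2)
    return _softmax_bwd_np(p, dp)


def sigmoid(x):
    return sps.expit(x)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters (full-scale defaults; desk() for tests)."""

    embed_dim: int = 384
    n_heads: int = 6
    n_blocks: int = 3
    ff_dim: int = 1536
    dropout: float = 0.1
    pos_embed_scale: float = 0.05
    max_cpgs: int = 511
    use_atlas: bool = True
    use_percentiles: bool = True
    n_percentiles: int = 19
    n_cell_types: int = 84
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must equal n_heads * head_dim")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def mlp_a_in(self) -> int:
        return 2 + (self.n_percentiles if self.use_percentiles else 0)

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Reduced architecture sized for CPU-only runs on synthetic biopsies."""
        kw = dict(embed_dim=64, n_heads=2, n_blocks=2, ff_dim=256, dropout=0.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def desk_small(cls, **overrides) -> "ModelConfig":
        kw = dict(embed_dim=16, n_heads=1, n_blocks=1, ff_dim=64, dropout=0.0, max_cpgs=128)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Batch:
    """Padded dense batch; ``valid`` marks real (non-padding) CpG tokens."""

    meth: np.ndarray  # (B, T)
    pos_norm: np.ndarray  # (B, T)
    percentiles: np.ndarray  # (B, T, 19)
    atlas: np.ndarray  # (B, T, 84)
    atlas_missing: np.ndarray  # (B, T, 84) bool
    valid: np.ndarray  # (B, T) bool
    labels: Optional[np.ndarray] = None  # (B,) float
    read_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.meth.shape[0]


def pad_batch(feature_sets, dtype=np.float32) -> Batch:
    from .types import N_ATLAS_CELL_TYPES, N_PERCENTILES

    B = len(feature_sets)
    T = max(fs.n_cpg for fs in feature_sets)
    meth = np.zeros((B, T), dtype)
    pos = np.zeros((B, T), dtype)
    pct = np.zeros((B, T, N_PERCENTILES), dtype)
    atlas = np.zeros((B, T, N_ATLAS_CELL_TYPES), dtype)
    missing = np.ones((B, T, N_ATLAS_CELL_TYPES), bool)
    valid = np.zeros((B, T), bool)
    labels = np.full(B, np.nan)
    for i, fs in enumerate(feature_sets):
        n = fs.n_cpg
        meth[i, :n] = fs.meth
        pos[i, :n] = fs.pos_norm
        pct[i, :n] = fs.site_percentiles
        atlas[i, :n] = fs.atlas
        missing[i, :n] = fs.atlas_missing
        valid[i, :n] = True
        if fs.label is not None:
            labels[i] = fs.label
    return Batch(
        meth, pos, pct, atlas, missing, valid,
        labels=None if np.isnan(labels).all() else labels,
        read_ids=[fs.read_id for fs in feature_sets],
    )


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _linear_init(rng, fan_in, fan_out, dtype):
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)


class TransformerClassifier:
    """Bias-free pre-LN encoder over CpG tokens with a CLS read-out."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        d, ff = config.embed_dim, config.ff_dim
        dt = self.dtype
        p: dict[str, np.ndarray] = {}
        p["Wa1"] = _linear_init(rng, config.mlp_a_in, d, dt)
        p["Wa2"] = _linear_init(rng, d, d, dt)
        if config.use_atlas:
            p["Wb1"] = _linear_init(rng, config.n_cell_types, d, dt)
            p["Wb2"] = _linear_init(rng, d, d, dt)
            p["missing_embed"] = (rng.standard_normal(config.n_cell_types) * 0.02).astype(dt)
        p["pos_table"] = (rng.standard_normal((config.max_cpgs + 1, d))).astype(dt)
        p["cls"] = (rng.standard_normal(d) * 0.02).astype(dt)
        for b in range(config.n_blocks):
            p[f"b{b}.g1"] = np.ones(d, dt)
            p[f"b{b}.Wq"] = _linear_init(rng, d, d, dt)
            p[f"b{b}.Wk"] = _linear_init(rng, d, d, dt)
            p[f"b{b}.Wv"] = _linear_init(rng, d, d, dt)
            p[f"b{b}.Wo"] = _linear_init(rng, d, d, dt)
            p[f"b{b}.g2"] = np.ones(d, dt)
            p[f"b{b}.W1"] = _linear_init(rng, d, ff, dt)
            p[f"b{b}.W2"] = _linear_init(rng, ff, d, dt)
        p["gf"] = np.ones(d, dt)
        p["Whead"] = _linear_init(rng, d, 1, dt)
        self.params = p
        self._ln_eps = 1e-5

    # -- layer norm -------------------------------------------------------
    def _ln_fwd(self, x, g):
        mu = x.mean(-1, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self._ln_eps)
        xhat = xc * inv
        return g * xhat, (xhat, inv, g)

    def _ln_bwd(self, dy, cache):
        xhat, inv, g = cache
        dxhat = dy * g
        m1 = dxhat.mean(-1, keepdims=True)
        m2 = np.mean(dxhat * xhat, axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        dg = np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        return dx, dg

    def _dropmask(self, shape, rng):
        keep = 1.0 - self.config.dropout
        return (rng.random(shape) < keep).astype(self.dtype) / keep

    # -- forward ----------------------------------------------------------
    def forward(self, batch: Batch, train: bool = False, rng: Optional[np.random.Generator] = None):
        """Return (logits, cache).  ``train`` enables dropout (requires rng)."""
        cfg, p, dt = self.config, self.params, self.dtype
        drop = train and cfg.dropout > 0
        if drop and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        B, T = batch.meth.shape
        if T > cfg.max_cpgs:
            raise ValueError(f"{T} CpG tokens exceed max_cpgs={cfg.max_cpgs}; cap first")
        cols = [batch.meth[..., None], batch.pos_norm[..., None]]
        if cfg.use_percentiles:
            cols.append(batch.percentiles)
        X = np.concatenate(cols, axis=-1).astype(dt)
        a1 = X @ p["Wa1"]
        ga1 = gelu(a1)
        tok = ga1 @ p["Wa2"]
        cacheA = (X, a1, ga1)
        cacheB = None
        if cfg.use_atlas:
            atlas_in = np.where(batch.atlas_missing, p["missing_embed"], batch.atlas.astype(dt)).astype(dt)
            b1 = atlas_in @ p["Wb1"]
            gb1 = gelu(b1)
            tok = tok + gb1 @ p["Wb2"]
            cacheB = (atlas_in, b1, gb1)
        tok = tok + cfg.pos_embed_scale * p["pos_table"][1: T + 1]
        cls = (p["cls"] + cfg.pos_embed_scale * p["pos_table"][0]).astype(dt)
        h = np.concatenate([np.broadcast_to(cls, (B, 1, cfg.embed_dim)).copy(), tok], axis=1)
        emb_mask = None
        if drop:
            emb_mask = self._dropmask(h.shape, rng)
            h = h * emb_mask
        valid = np.concatenate([np.ones((B, 1), bool), batch.valid], axis=1)
        S, H, dh = T + 1, cfg.n_heads, cfg.head_dim
        scale = 1.0 / math.sqrt(dh)
        blocks = []
        for bix in range(cfg.n_blocks):
            g1, g2 = p[f"b{bix}.g1"], p[f"b{bix}.g2"]
            u, ln1c = self._ln_fwd(h, g1)
            q = (u @ p[f"b{bix}.Wq"]).reshape(B, S, H, dh).transpose(0, 2, 1, 3)
            k = (u @ p[f"b{bix}.Wk"]).reshape(B, S, H, dh).transpose(0, 2, 1, 3)
            v = (u @ p[f"b{bix}.Wv"]).reshape(B, S, H, dh).transpose(0, 2, 1, 3)
            scores = np.matmul(q, k.transpose(0, 1, 3, 2)) * np.asarray(scale, dt)
            prob = softmax_masked(scores, valid)
            amask = None
            probd = prob
            if drop:
                amask = self._dropmask(prob.shape, rng)
                probd = prob * amask
            ctx = np.matmul(probd, v).transpose(0, 2, 1, 3).reshape(B, S, cfg.embed_dim)
            ao = ctx @ p[f"b{bix}.Wo"]
            omask = None
            if drop:
                omask = self._dropmask(ao.shape, rng)
                ao = ao * omask
            h2 = h + ao
            w, ln2c = self._ln_fwd(h2, g2)
            f1 = w @ p[f"b{bix}.W1"]
            gf1 = gelu(f1)
            f2 = gf1 @ p[f"b{bix}.W2"]
            fmask = None
            if drop:
                fmask = self._dropmask(f2.shape, rng)
                f2 = f2 * fmask
            h = h2 + f2
            blocks.append((u, ln1c, q, k, v, prob, amask, ctx, omask, h2, w, ln2c, f1, gf1, fmask))
        z, lnfc = self._ln_fwd(h[:, 0], p["gf"])
        logits = (z @ p["Whead"]).reshape(-1)
        cache = dict(
            batch=batch, X=X, cacheA=cacheA, cacheB=cacheB, emb_mask=emb_mask,
            valid=valid, blocks=blocks, z=z, lnfc=lnfc, T=T, B=B,
        )
        return logits, cache

    # -- backward ---------------------------------------------------------
    def backward(self, cache, dlogits):
        """Gradients of a scalar loss; returns (param grads, d_meth (B,T))."""
        cfg, p, dt = self.config, self.params, self.dtype
        B, T = cache["B"], cache["T"]
        S, H, dh = T + 1, cfg.n_heads, cfg.head_dim
        scale = np.asarray(1.0 / math.sqrt(dh), dt)
        g = {name: np.zeros_like(arr) for name, arr in p.items()}
        dl = np.asarray(dlogits, dt).reshape(B, 1)
        g["Whead"] += cache["z"].reshape(B, -1).T @ dl
        dz = dl @ p["Whead"].T
        dz0, dgf = self._ln_bwd(dz, cache["lnfc"])
        g["gf"] += dgf
        dhid = np.zeros((B, S, cfg.embed_dim), dt)
        dhid[:, 0] = dz0
        for bix in reversed(range(cfg.n_blocks)):
            (u, ln1c, q, k, v, prob, amask, ctx, omask, h2, w, ln2c, f1, gf1, fmask) = cache["blocks"][bix]
            df2 = dhid if fmask is None else dhid * fmask
            g[f"b{bix}.W2"] += gf1.reshape(-1, cfg.ff_dim).T @ df2.reshape(-1, cfg.embed_dim)
            dgf1 = df2 @ p[f"b{bix}.W2"].T
            df1 = dgf1 * gelu_grad(f1)
            g[f"b{bix}.W1"] += w.reshape(-1, cfg.embed_dim).T @ df1.reshape(-1, cfg.ff_dim)
            dw = df1 @ p[f"b{bix}.W1"].T
            dh2_ln, dg2 = self._ln_bwd(dw, ln2c)
            g[f"b{bix}.g2"] += dg2
            dh2 = dhid + dh2_ln
            dao = dh2 if omask is None else dh2 * omask
            g[f"b{bix}.Wo"] += ctx.reshape(-1, cfg.embed_dim).T @ dao.reshape(-1, cfg.embed_dim)
            dctx = (dao @ p[f"b{bix}.Wo"].T).reshape(B, S, H, dh).transpose(0, 2, 1, 3)
            probd = prob if amask is None else prob * amask
            dprobd = np.matmul(dctx, v.transpose(0, 1, 3, 2))
            dv = np.matmul(probd.transpose(0, 1, 3, 2), dctx)
            dprob = dprobd if amask is None else dprobd * amask
            dscores = softmax_bwd(prob, dprob)
            dq = np.matmul(dscores, k) * scale
            dk = np.matmul(dscores.transpose(0, 1, 3, 2), q) * scale
            dq = dq.transpose(0, 2, 1, 3).reshape(B, S, cfg.embed_dim)
            dk = dk.transpose(0, 2, 1, 3).reshape(B, S, cfg.embed_dim)
            dv = dv.transpose(0, 2, 1, 3).reshape(B, S, cfg.embed_dim)
            uf = u.reshape(-1, cfg.embed_dim)
            g[f"b{bix}.Wq"] += uf.T @ dq.reshape(-1, cfg.embed_dim)
            g[f"b{bix}.Wk"] += uf.T @ dk.reshape(-1, cfg.embed_dim)
            g[f"b{bix}.Wv"] += uf.T @ dv.reshape(-1, cfg.embed_dim)
            du = dq @ p[f"b{bix}.Wq"].T + dk @ p[f"b{bix}.Wk"].T + dv @ p[f"b{bix}.Wv"].T
            dh_ln, dg1 = self._ln_bwd(du, ln1c)
            g[f"b{bix}.g1"] += dg1
            dhid = dh2 + dh_ln
        if cache["emb_mask"] is not None:
            dhid = dhid * cache["emb_mask"]
        dcls = dhid[:, 0].sum(0)
        g["cls"] += dcls
        g["pos_table"][0] += cfg.pos_embed_scale * dcls
        dtok = dhid[:, 1:]
        g["pos_table"][1: T + 1] += cfg.pos_embed_scale * dtok.sum(0)
        if cfg.use_atlas:
            atlas_in, b1, gb1 = cache["cacheB"]
            db2 = dtok
            g["Wb2"] += gb1.reshape(-1, cfg.embed_dim).T @ db2.reshape(-1, cfg.embed_dim)
            dgb1 = db2 @ p["Wb2"].T
            db1 = dgb1 * gelu_grad(b1)
            g["Wb1"] += atlas_in.reshape(-1, cfg.n_cell_types).T @ db1.reshape(-1, cfg.embed_dim)
            datlas_in = db1 @ p["Wb1"].T
            g["missing_embed"] += np.sum(
                datlas_in * cache["batch"].atlas_missing, axis=(0, 1)
            ).astype(dt)
        X, a1, ga1 = cache["cacheA"]
        da2 = dtok
        g["Wa2"] += ga1.reshape(-1, cfg.embed_dim).T @ da2.reshape(-1, cfg.embed_dim)
        dga1 = da2 @ p["Wa2"].T
        da1 = dga1 * gelu_grad(a1)
        g["Wa1"] += X.reshape(-1, cfg.mlp_a_in).T @ da1.reshape(-1, cfg.embed_dim)
        dX = da1 @ p["Wa1"].T
        d_meth = dX[..., 0] * cache["batch"].valid
        return g, d_meth

    # -- inference --------------------------------------------------------
    def predict_proba(self, batch: Batch) -> np.ndarray:
        logits, _ = self.forward(batch, train=False)
        return sigmoid(logits)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def weight_hash(self) -> int:
        import zlib

        h = 0
        for k in sorted(self.params):
            h = zlib.crc32(self.params[k].tobytes(), h)
        return h

    def save(self, path: str, extra: Optional[dict] = None) -> None:
        meta = {"config": asdict(self.config), "format_version": 1}
        if extra:
            meta["extra"] = extra
        np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str) -> "TransformerClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            model = cls(ModelConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = z[k]
        return model


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class AdamW:
    """Decoupled weight-decay Adam; weight decay skips norms/embeddings."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    _NO_DECAY = ("g1", "g2", "gf", "cls", "pos_table", "missing_embed")

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        lr = self.lr * lr_scale
        for k, w in self.params.items():
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if self.wd and not any(k.endswith(s) for s in self._NO_DECAY):
                w -= lr * self.wd * w
            w -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(w.dtype)


class Adam:
    """Plain Adam for a single tensor (used on the perturbation delta)."""

    def __init__(self, shape, lr: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8,
                 dtype=np.float32):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = np.zeros(shape, dtype)
        self.v = np.zeros(shape, dtype)
        self.t = 0

    def step(self, x: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        b1, b2 = self.betas
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad * grad
        mhat = self.m / (1 - b1 ** self.t)
        vhat = self.v / (1 - b2 ** self.t)
        x -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(x.dtype)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def weighted_bce_with_logits(logits, labels, pos_weight: float = 1.0):
    """Mean weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    labels = np.asarray(labels, np.float64)
    z = np.asarray(logits, np.float64)
    # log(1 + e^-|z|) formulation for stability
    log_sig = -np.logaddexp(0.0, -z)
    log_one_minus = -np.logaddexp(0.0, z)
    per = -(pos_weight * labels * log_sig + (1 - labels) * log_one_minus)
    sig = sps.expit(z)
    dper = pos_weight * labels * (sig - 1.0) + (1 - labels) * sig
    n = len(z)
    return float(per.mean()), dper / n
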