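"""Counterfactual interpretation of the read classifier.

A per-read perturbation delta on the methylation vector is optimized, with
the model frozen, to invert the predicted origin while staying sparse: the
loss combines binary cross-entropy toward the inverted label, a clip
penalty keeping the perturbed methylation in [0, 1], and a smooth-L0
penalty delta^2 / (delta^2 + eps(t)^2) whose smoothness eps(t) anneals down
and strength lambda(t) anneals up after a warm-up delay.  Downstream
analyses quantify spatial clustering of perturbed CpGs (a nearest-neighbor
permutation statistic) and their concordance with cell-type marker sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureSet, cap_cpgs_stable
from .nn import Adam, Batch, TransformerClassifier, pad_batch, sigmoid

CONFIDENCE_LOW = 0.2
CONFIDENCE_HIGH = 0.8


@dataclass
class PerturbationConfig:
    gamma: float = 50.0
    eps_max: float = 0.5
    eps_min: float = 0.01
    lambda_min: float = 0.0
    lambda_max: float = 5.0
    t0: int = 25
    warmup_steps: int = 975  # T_W; total optimization steps = T_W + t0
    lr: float = 0.01
    batch_size: int = 1024
    delta_threshold: float = 0.1
    confidence_bounds: tuple[float, float] = (CONFIDENCE_LOW, CONFIDENCE_HIGH)

    @property
    def n_steps(self) -> int:
        return self.warmup_steps + self.t0


@dataclass
class PerturbationResult:
    read_id: str
    delta: np.ndarray  # thresholded per-CpG perturbation, length n_cpg
    p_before: float
    p_after: float
    success: bool
    lambda_max: float

    @property
    def perturbed_mask(self) -> np.ndarray:
        return np.abs(self.delta) > 0.1

    @property
    def n_perturbed(self) -> int:
        return int(self.perturbed_mask.sum())

    @property
    def direction(self) -> str:
        return "tumor_to_non_tumor" if self.p_before >= 0.5 else "non_tumor_to_tumor"


def schedule(t: int, cfg: PerturbationConfig) -> tuple[float, float]:
    """Piecewise-linear (epsilon, lambda) at optimization step t.

    Both parameters hold their start value for the first t0 steps, then move
    linearly, reaching (eps_min, lambda_max) at step T_W.
    """
    span = cfg.warmup_steps - cfg.t0
    progress = min(max(t - cfg.t0, 0), span) / span
    eps = cfg.eps_max - (cfg.eps_max - cfg.eps_min) * progress
    lam = cfg.lambda_min + (cfg.lambda_max - cfg.lambda_min) * progress
    return eps, lam


def perturbation_loss(
    logits: np.ndarray,
    x_tilde: np.ndarray,
    delta: np.ndarray,
    y: np.ndarray,
    t: int,
    cfg: PerturbationConfig,
    n_attended: np.ndarray,
    valid: np.ndarray,
):
    """Batch-mean total loss and its gradients.

    Returns (loss, dlogits, ddelta_direct) where ddelta_direct holds the
    clip + smooth-L0 terms (the class term reaches delta through the model).
    All per-read sums are averaged over that read's attended CpG count.
    """
    B = len(logits)
    z = np.asarray(logits, np.float64)
    sig = sigmoid(z)
    l_class = -(y * np.log(np.maximum(sig, 1e-12)) + (1 - y) * np.log(np.maximum(1 - sig, 1e-12)))
    dlogits = (sig - y) / B

    eps, lam = schedule(t, cfg)
    inv_n = (1.0 / n_attended)[:, None]
    over = np.maximum(x_tilde - 1.0, 0.0)
    under = np.maximum(-x_tilde, 0.0)
    l_clip = cfg.gamma * ((over + under) * valid * inv_n).sum(axis=1)
    d_clip = cfg.gamma * inv_n * ((x_tilde > 1.0).astype(np.float64) - (x_tilde < 0.0)) * valid / B

    d2 = delta.astype(np.float64) ** 2
    denom = d2 + eps * eps
    l_l0 = lam * ((d2 / denom) * valid * inv_n).sum(axis=1)
    d_l0 = lam * inv_n * (2.0 * delta * eps * eps / (denom * denom)) * valid / B

    loss = float(np.mean(l_class + l_clip + l_l0))
    return loss, dlogits, (d_clip + d_l0)


def select_confident(feature_sets: Sequence[FeatureSet], probabilities: np.ndarray,
                     cfg: Optional[PerturbationConfig] = None):
    """Keep reads whose unperturbed tumor probability is <= 0.2 or >= 0.8."""
    lo, hi = (cfg or PerturbationConfig()).confidence_bounds
    keep = (probabilities <= lo) | (probabilities >= hi)
    return [fs for fs, k in zip(feature_sets, keep) if k], probabilities[keep]


def perturb_batch(
    model: TransformerClassifier,
    feature_sets: Sequence[FeatureSet],
    cfg: PerturbationConfig,
    seed: int = 0,
) -> list[PerturbationResult]:
    """Optimize one delta per confident read; model weights are never touched.

    Adam on the batch-mean loss for T_W + t0 steps; the final delta is
    element-wise thresholded at |delta| < 0.1 and the perturbed methylation
    clipped to [0, 1] before the post-perturbation probability is measured.
    """
    capped = [cap_cpgs_stable(fs, seed, model.config.max_cpgs) for fs in feature_sets]
    results: list[PerturbationResult] = []
    order = np.argsort([fs.n_cpg for fs in capped], kind="stable")
    for lo in range(0, len(order), cfg.batch_size):
        idx = order[lo: lo + cfg.batch_size]
        results.extend(_perturb_one_batch(model, [capped[i] for i in idx], cfg))
    results.sort(key=lambda r: r.read_id)
    return results


def _perturb_one_batch(model, fsets, cfg: PerturbationConfig) -> list[PerturbationResult]:
    batch = pad_batch(fsets)
    logits0, _ = model.forward(batch, train=False)
    p0 = sigmoid(logits0)
    lo, hi = cfg.confidence_bounds
    confident = (p0 <= lo) | (p0 >= hi)
    if not confident.all():
        # the caller should pre-filter; re-capped subsamples can still move a
        # borderline read inside the bounds, so drop those here
        fsets = [fs for fs, c in zip(fsets, confident) if c]
        if not fsets:
            return []
        batch = pad_batch(fsets)
        logits0, _ = model.forward(batch, train=False)
        p0 = sigmoid(logits0)
    base_meth = batch.meth.copy()
    y = (p0 < 0.5).astype(np.float64)  # inverted hard prediction
    valid = batch.valid.astype(np.float64)
    n_att = valid.sum(axis=1)
    delta = np.zeros_like(base_meth)
    opt = Adam(delta.shape, lr=cfg.lr, dtype=base_meth.dtype)
    for t in range(cfg.n_steps):
        x_tilde = base_meth + delta
        batch.meth = x_tilde
        logits, cache = model.forward(batch, train=False)
        _, dlogits, d_direct = perturbation_loss(
            logits, x_tilde.astype(np.float64), delta, y, t, cfg, n_att, valid
        )
        _, d_meth = model.backward(cache, dlogits)
        grad = (d_meth + d_direct).astype(delta.dtype) * batch.valid
        opt.step(delta, grad)
        delta *= batch.valid
    delta_thr = np.where(np.abs(delta) >= cfg.delta_threshold, delta, 0.0)
    batch.meth = np.clip(base_meth + delta_thr, 0.0, 1.0).astype(base_meth.dtype)
    logits1, _ = model.forward(batch, train=False)
    p1 = sigmoid(logits1)
    out = []
    for i, fs in enumerate(fsets):
        n = fs.n_cpg
        success = bool(
            (p0[i] <= lo and p1[i] >= hi) or (p0[i] >= hi and p1[i] <= lo)
        )
        out.append(
            PerturbationResult(
                read_id=fs.read_id,
                delta=delta_thr[i, :n].astype(np.float64),
                p_before=float(p0[i]),
                p_after=float(p1[i]),
                success=success,
                lambda_max=cfg.lambda_max,
            )
        )
    return out


def best_by_read(results: Sequence[PerturbationResult]) -> dict[str, PerturbationResult]:
    """Across lambda_max runs, keep per read the successful conversion with
    fewest perturbed CpGs."""
    best: dict[str, PerturbationResult] = {}
    for r in results:
        if not r.success:
            continue
        cur = best.get(r.read_id)
        if cur is None or r.n_perturbed < cur.n_perturbed:
            best[r.read_id] = r
    return best


# ---------------------------------------------------------------------------
# clustering coefficient
# ---------------------------------------------------------------------------

def _mean_nn_distance(sorted_idx: np.ndarray) -> float:
    gaps = np.diff(sorted_idx)
    prev = np.concatenate([[np.iinfo(np.int64).max], gaps])
    nxt = np.concatenate([gaps, [np.iinfo(np.int64).max]])
    return float(np.minimum(prev, nxt).mean())


def clustering_coefficient(
    perturbed_mask: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> Optional[float]:
    """Nearest-neighbor clustering statistic of perturbed CpGs on a read.

    C = -log2(observed mean NN distance / permutation-mean NN distance) in
    CpG-index coordinates, with the permutation null drawing the same number
    of perturbed sites uniformly across the read's CpGs.  Positive C means
    clustered; None (undefined) for fewer than two perturbed CpGs.
    """
    mask = np.asarray(perturbed_mask, bool)
    n_cpgs = len(mask)
    obs_idx = np.flatnonzero(mask)
    k = len(obs_idx)
    if k < 2:
        return None
    if k == n_cpgs:
        return 0.0  # permutations can only reproduce the observed set
    d_obs = _mean_nn_distance(obs_idx)
    rng = np.random.default_rng(seed)
    # vectorized permutations: first k of a random argsort per row
    keys = rng.random((n_perm, n_cpgs))
    perm_idx = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
    gaps = np.diff(perm_idx, axis=1)
    big = np.full((n_perm, 1), np.iinfo(np.int64).max)
    nn = np.minimum(np.concatenate([big, gaps], axis=1), np.concatenate([gaps, big], axis=1))
    d_perm = nn.mean(axis=1).mean()
    return float(-np.log2(d_obs / d_perm))


# ---------------------------------------------------------------------------
# cell-type concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTally:
    tumor_like: int = 0
    non_tumor_like: int = 0
    n_marker_cpgs: int = 0


def cell_type_concordance(
    results: Sequence[PerturbationResult],
    feature_sets: Sequence[FeatureSet],
    cell_type_names: Sequence[str],
    min_markers: int = 20,
    marker_diff: float = 0.5,
) -> dict[str, ConcordanceTally]:
    """Tally tumor-like / non-tumor-like shifts at cell-type marker CpGs.

    A marker site for a cell type deviates from the cross-cell-type mean by
    at least ``marker_diff``.  For probability-increasing perturbations a
    shift toward the cell type's value counts as tumor-like; for
    probability-decreasing perturbations the sign is inverted.  Cell types
    with fewer than ``min_markers`` marker CpGs across all successfully
    perturbed reads are dropped.
    """
    fs_by_id = {fs.read_id: fs for fs in feature_sets}
    tallies = {name: ConcordanceTally() for name in cell_type_names}
    for res in results:
        if not res.success:
            continue
        fs = fs_by_id[res.read_id]
        atlas = fs.atlas.astype(np.float64)
        present = ~fs.atlas_missing
        with np.errstate(invalid="ignore"):
            row_mean = np.where(
                present.sum(1) > 0, (atlas * present).sum(1) / np.maximum(present.sum(1), 1), np.nan
            )
        is_marker = present & (np.abs(atlas - row_mean[:, None]) >= marker_diff)
        increases_p = res.p_before < 0.5
        perturbed = res.perturbed_mask
        x = fs.meth.astype(np.float64)
        x_new = np.clip(x + res.delta, 0.0, 1.0)
        for j, name in enumerate(cell_type_names):
            sites = np.flatnonzero(is_marker[:, j])
            tallies[name].n_marker_cpgs += len(sites)
            for i in sites:
                if not perturbed[i]:
                    continue
                toward = abs(x_new[i] - atlas[i, j]) < abs(x[i] - atlas[i, j])
                tumor_like = toward if increases_p else not toward
                if tumor_like:
                    tallies[name].tumor_like += 1
                else:
                    tallies[name].non_tumor_like += 1
    return {
        name: t for name, t in tallies.items() if t.n_marker_cpgs >= min_markers
    }


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSummary:
    n_reads: int
    n_converted: int
    fraction_converted: float
    mean_fraction_perturbed: Optional[float]
    fraction_increased: Optional[float]
    clustering_by_direction: dict[str, list[float]] = field(default_factory=dict)


def summarize_perturbations(
    results: Sequence[PerturbationResult],
    feature_sets: Sequence[FeatureSet],
    n_perm: int = 5000,
    seed: int = 0,
) -> PerturbationSummary:
    """Per-sample conversion rate, perturbed-CpG statistics and C by direction."""
    n_by_id = {fs.read_id: fs.n_cpg for fs in feature_sets}
    converted = [r for r in results if r.success]
    frac_conv = len(converted) / len(results) if results else 0.0
    if not converted:
        return PerturbationSummary(len(results), 0, frac_conv, None, None, {})
    frac_pert = [r.n_perturbed / n_by_id[r.read_id] for r in converted]
    n_up = sum(int((r.delta > 0.1).sum()) for r in converted)
    n_tot = sum(r.n_perturbed for r in converted)
    clustering: dict[str, list[float]] = {"tumor_to_non_tumor": [], "non_tumor_to_tumor": []}
    for r in converted:
        c = clustering_coefficient(r.perturbed_mask, n_perm=n_perm, seed=seed)
        if c is not None:
            clustering[r.direction].append(c)
    return PerturbationSummary(
        n_reads=len(results),
        n_converted=len(converted),
        fraction_converted=frac_conv,
        mean_fraction_perturbed=float(np.mean(frac_pert)),
        fraction_increased=n_up / n_tot if n_tot else None,
        clustering_by_direction=clustering,
    )
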