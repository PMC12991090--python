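"""Per-read feature assembly: methylation vector, normalized CpG positions,
19-percentile sample site distributions, and 84-cell-type atlas rows."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    N_ATLAS_CELL_TYPES,
    N_PERCENTILES,
    CellTypeAtlas,
    MethylRead,
    SampleSiteDistribution,
)

logger = logging.getLogger(__name__)

MAX_CPGS = 511
POSITION_SCALE_BP = 20_000.0


def normalize_positions(positions: np.ndarray) -> np.ndarray:
    """Scale sorted reference positions to (R - min(R)) / 20000 - 0.5.

    The fixed denominator encodes read length implicitly: values start at
    -0.5 and exceed +0.5 for reads longer than 20 kb (deliberately
    unclipped).
    """
    r = np.asarray(positions, dtype=np.float64)
    if r.size == 0:
        raise ValueError("need at least one position")
    if np.any(np.diff(r) < 0):
        raise ValueError("positions must be sorted")
    return (r - r[0]) / POSITION_SCALE_BP - 0.5


@dataclass
class FeatureSet:
    """Model input for one read; all blocks aligned on the read's N CpGs."""

    read_id: str
    chromosome: str
    meth: np.ndarray  # (N,) float32 in [0, 1]
    pos_norm: np.ndarray  # (N,) float32
    site_percentiles: np.ndarray  # (N, 19) float32
    atlas: np.ndarray  # (N, 84) float32, zero-filled where missing
    atlas_missing: np.ndarray  # (N, 84) bool
    label: Optional[int] = None  # 1 tumor / 0 non-tumor

    @property
    def n_cpg(self) -> int:
        return len(self.meth)


def build_feature_set(
    read: MethylRead,
    site_dist: SampleSiteDistribution,
    atlas: CellTypeAtlas,
    label: Optional[int] = None,
) -> Optional[FeatureSet]:
    """Assemble the four feature blocks for a read; None for zero-CpG reads."""
    if read.n_cpg == 0:
        return None
    pct, _found = site_dist.lookup(read.chromosome, read.cpg_positions)
    atlas_vals, missing = atlas.lookup(read.chromosome, read.cpg_positions)
    return FeatureSet(
        read_id=read.read_id,
        chromosome=read.chromosome,
        meth=read.meth_prob.astype(np.float32),
        pos_norm=normalize_positions(read.cpg_positions).astype(np.float32),
        site_percentiles=pct.astype(np.float32),
        atlas=atlas_vals.astype(np.float32),
        atlas_missing=missing,
        label=label,
    )


def build_feature_sets(
    reads: Sequence[MethylRead],
    site_dist: SampleSiteDistribution,
    atlas: CellTypeAtlas,
    labels: Optional[dict[str, int]] = None,
) -> list[FeatureSet]:
    out = []
    n_skipped = 0
    for read in reads:
        label = labels.get(read.read_id) if labels else None
        fs = build_feature_set(read, site_dist, atlas, label=label)
        if fs is None:
            n_skipped += 1
            continue
        out.append(fs)
    if n_skipped:
        logger.info("skipped %d zero-CpG reads during feature extraction", n_skipped)
    return out


def cap_cpgs(fs: FeatureSet, rng: np.random.Generator, max_n: int = MAX_CPGS) -> FeatureSet:
    """Subsample reads with more than ``max_n`` CpGs, preserving order.

    During training this is re-drawn every epoch; at inference a single
    seeded draw is used (see :func:`cap_cpgs_stable`).
    """
    if fs.n_cpg <= max_n:
        return fs
    keep = np.sort(rng.choice(fs.n_cpg, size=max_n, replace=False))
    return replace(
        fs,
        meth=fs.meth[keep],
        pos_norm=fs.pos_norm[keep],
        site_percentiles=fs.site_percentiles[keep],
        atlas=fs.atlas[keep],
        atlas_missing=fs.atlas_missing[keep],
    )


def cap_cpgs_stable(fs: FeatureSet, seed: int, max_n: int = MAX_CPGS) -> FeatureSet:
    """Inference-time capping with a per-read seeded draw.

    The subsample depends only on (seed, read_id), so a read's capped
    features — and hence its prediction — are invariant to batch composition
    and ordering.
    """
    if fs.n_cpg <= max_n:
        return fs
    rng = np.random.default_rng([seed, zlib.crc32(fs.read_id.encode())])
    return cap_cpgs(fs, rng, max_n)


def save_feature_cache(path: str, feature_sets: Sequence[FeatureSet]) -> None:
    """Compressed on-disk cache keyed by read_id."""
    counts = np.array([fs.n_cpg for fs in feature_sets], dtype=np.int64)
    np.savez_compressed(
        path,
        read_id=np.array([fs.read_id for fs in feature_sets]),
        chromosome=np.array([fs.chromosome for fs in feature_sets]),
        label=np.array([-1 if fs.label is None else fs.label for fs in feature_sets], np.int64),
        counts=counts,
        meth=np.concatenate([fs.meth for fs in feature_sets]) if counts.size else np.empty(0, np.float32),
        pos_norm=np.concatenate([fs.pos_norm for fs in feature_sets]) if counts.size else np.empty(0, np.float32),
        site_percentiles=np.concatenate([fs.site_percentiles for fs in feature_sets])
        if counts.size
        else np.empty((0, N_PERCENTILES), np.float32),
        atlas=np.concatenate([fs.atlas for fs in feature_sets])
        if counts.size
        else np.empty((0, N_ATLAS_CELL_TYPES), np.float32),
        atlas_missing=np.concatenate([fs.atlas_missing for fs in feature_sets])
        if counts.size
        else np.empty((0, N_ATLAS_CELL_TYPES), bool),
    )


def load_feature_cache(path: str) -> list[FeatureSet]:
    out = []
    with np.load(path, allow_pickle=False) as z:
        # materialize each compressed member once; indexing the lazy handle
        # inside the loop would re-decompress the full array per read
        d = {k: z[k] for k in z.files}
    offsets = np.concatenate([[0], np.cumsum(d["counts"])])
    for i in range(len(d["counts"])):
        lo, hi = offsets[i], offsets[i + 1]
        label = int(d["label"][i])
        out.append(
            FeatureSet(
                read_id=str(d["read_id"][i]),
                chromosome=str(d["chromosome"][i]),
                meth=d["meth"][lo:hi],
                pos_norm=d["pos_norm"][lo:hi],
                site_percentiles=d["site_percentiles"][lo:hi],
                atlas=d["atlas"][lo:hi],
                atlas_missing=d["atlas_missing"][lo:hi],
                label=None if label < 0 else label,
            )
        )
    return out
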