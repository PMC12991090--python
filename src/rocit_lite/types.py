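"""Shared domain types for the read-origin classification pipeline.

Coordinates are 0-based half-open everywhere inside the package; the only
1-based surface is the VCF boundary in :mod:`rocit_lite.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_PERCENTILES = 19
PERCENTILE_GRID = np.arange(5, 100, 5, dtype=np.float64)  # 5, 10, ..., 95
N_ATLAS_CELL_TYPES = 84


@dataclass
class MethylRead:
    """One primary-alignment long read with per-CpG methylation calls.

    ``cpg_positions`` are reference coordinates of the forward-strand C of
    each symmetric CpG covered by the read; calls without a reference
    position (insertions, soft-clips) are dropped on load.  ``meth_raw``
    holds the caller's 0-255 binned probability; ``meth_prob`` the midpoint
    rescaling ``(raw + 0.5) / 256``.
    """

    read_id: str
    chromosome: str
    cpg_positions: np.ndarray  # int64, strictly increasing
    meth_raw: np.ndarray  # uint8/int, same length
    meth_prob: np.ndarray  # float64 in (0, 1)
    haplotype: Optional[int] = None  # 1, 2 or None (unphased)
    phase_block_id: Optional[str] = None
    # (0-based position, observed base) at loci of interest
    variant_observations: list[tuple[int, str]] = field(default_factory=list)
    reference_start: int = 0
    reference_end: int = 0

    def __post_init__(self) -> None:
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=np.int64)
        self.meth_raw = np.asarray(self.meth_raw, dtype=np.int64)
        self.meth_prob = np.asarray(self.meth_prob, dtype=np.float64)
        if len(self.meth_raw) != len(self.cpg_positions):
            raise ValueError(
                f"read {self.read_id}: {len(self.meth_raw)} methylation calls "
                f"for {len(self.cpg_positions)} CpG positions"
            )
        if len(self.cpg_positions) > 1 and np.any(np.diff(self.cpg_positions) <= 0):
            raise ValueError(f"read {self.read_id}: CpG positions not strictly increasing")
        if self.haplotype not in (None, 1, 2):
            raise ValueError(f"read {self.read_id}: haplotype must be 1, 2 or None")
        if self.reference_end <= self.reference_start and len(self.cpg_positions):
            self.reference_start = int(self.cpg_positions[0])
            self.reference_end = int(self.cpg_positions[-1]) + 1

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def observed_base_at(self, position: int) -> Optional[str]:
        for pos, base in self.variant_observations:
            if pos == position:
                return base
        return None


@dataclass
class VariantRecord:
    """A somatic SNV with its read support and (optional) clonal annotation."""

    chromosome: str
    position: int  # 0-based internally
    ref: str
    alt: str
    alt_read_count: int = 0
    total_read_count: int = 0
    haplotype_of_alt: Optional[int] = None
    caller_status: dict[str, str] = field(default_factory=dict)  # caller -> PASS/FAIL
    cluster_id: Optional[int] = None
    multiplicity: Optional[int] = None
    allele: Optional[str] = None  # "major" / "minor"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chromosome}:{self.position} is not an SNV")
        if not (0 <= self.alt_read_count <= self.total_read_count):
            raise ValueError(
                f"{self.chromosome}:{self.position}: alt count {self.alt_read_count} "
                f"outside [0, {self.total_read_count}]"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


@dataclass
class CopyNumberSegment:
    """Allele-specific tumor copy number over a 0-based half-open interval."""

    chromosome: str
    start: int
    end: int
    n_total: int
    n_minor: int
    n_normal: int = 2

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chromosome}:{self.start}-{self.end} is empty")
        if self.n_total < 0 or self.n_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.n_total > 0 and self.n_minor > self.n_total - self.n_minor:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                f"minor copy number {self.n_minor} exceeds major"
            )

    @property
    def n_major(self) -> int:
        return self.n_total - self.n_minor

    @property
    def is_loh(self) -> bool:
        return self.n_minor == 0 and self.n_total > 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position < self.end

    def overlap(self, chromosome: str, start: int, end: int) -> int:
        if chromosome != self.chromosome:
            return 0
        return max(0, min(end, self.end) - max(start, self.start))


@dataclass
class SamplePurity:
    """Tumor cell fraction rho of the bulk biopsy, in (0, 1]."""

    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.rho}")


@dataclass
class Cluster:
    cluster_id: int
    ccf: float
    n_assigned_variants: int

    def __post_init__(self) -> None:
        if self.ccf < 0:
            raise ValueError("cluster CCF must be non-negative")
        if self.n_assigned_variants < 0:
            raise ValueError("cluster size must be non-negative")


@dataclass
class ClusterModel:
    """Subclonal cluster summary: per cluster a CCF and assigned-variant count."""

    clusters: list[Cluster]

    @property
    def total_variants(self) -> int:
        return sum(c.n_assigned_variants for c in self.clusters)

    def by_id(self, cluster_id: int) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


class CellTypeAtlas:
    """Per-CpG average methylation across 84 reference cell populations.

    Backed by a dense (n_sites, 84) float32 matrix with a per-chromosome
    position index; ``lookup`` returns values plus a missing mask for sites
    absent from the atlas (NaN entries are also treated as missing).
    """

    def __init__(
        self,
        cell_type_names: list[str],
        positions_by_chrom: dict[str, np.ndarray],
        values: np.ndarray,
        row_offset: dict[str, int],
    ) -> None:
        if len(cell_type_names) < 1:
            raise ValueError("atlas needs at least one cell-type column")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("atlas methylation values must lie in [0, 1]")
        self.cell_type_names = list(cell_type_names)
        self.positions_by_chrom = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
        self.values = np.asarray(values, dtype=np.float32)
        self.row_offset = dict(row_offset)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_type_names)

    def lookup(self, chromosome: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, missing_mask) of shape (n, n_cell_types) / (n, n_cell_types).

        Rows for positions absent from the atlas are zero-filled and fully
        masked; NaN entries at present sites are masked individually.
        """
        positions = np.asarray(positions, dtype=np.int64)
        n = len(positions)
        out = np.zeros((n, self.n_cell_types), dtype=np.float32)
        missing = np.ones((n, self.n_cell_types), dtype=bool)
        site_pos = self.positions_by_chrom.get(chromosome)
        if site_pos is None or len(site_pos) == 0:
            return out, missing
        idx = np.searchsorted(site_pos, positions)
        idx_clip = np.minimum(idx, len(site_pos) - 1)
        found = site_pos[idx_clip] == positions
        rows = self.row_offset[chromosome] + idx_clip[found]
        vals = self.values[rows]
        nan = ~np.isfinite(vals)
        vals = np.where(nan, 0.0, vals)
        out[found] = vals
        miss_rows = np.ones_like(vals, dtype=bool)
        miss_rows[:] = nan
        missing[found] = miss_rows
        return out, missing


class SampleSiteDistribution:
    """19-percentile summary (5%..95%) of meth_prob per covered CpG site."""

    def __init__(self, positions_by_chrom: dict[str, np.ndarray], percentiles: np.ndarray, row_offset: dict[str, int]):
        self.positions_by_chrom = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
        self.percentiles = np.asarray(percentiles, dtype=np.float32)
        if self.percentiles.ndim != 2 or self.percentiles.shape[1] != N_PERCENTILES:
            raise ValueError(f"percentile matrix must have {N_PERCENTILES} columns")
        if np.any(np.diff(self.percentiles, axis=1) < -1e-9):
            raise ValueError("percentile vectors must be non-decreasing")
        self.row_offset = dict(row_offset)

    def lookup(self, chromosome: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (percentile rows, found mask); absent sites zero-filled."""
        positions = np.asarray(positions, dtype=np.int64)
        n = len(positions)
        out = np.zeros((n, N_PERCENTILES), dtype=np.float32)
        found = np.zeros(n, dtype=bool)
        site_pos = self.positions_by_chrom.get(chromosome)
        if site_pos is None or len(site_pos) == 0:
            return out, found
        idx = np.searchsorted(site_pos, positions)
        idx_clip = np.minimum(idx, len(site_pos) - 1)
        hit = site_pos[idx_clip] == positions
        out[hit] = self.percentiles[self.row_offset[chromosome] + idx_clip[hit]]
        found[hit] = True
        return out, found


@dataclass
class LabeledRead:
    """A read with a derived ground-truth origin label and its evidence."""

    read_id: str
    label: str  # "tumor" / "non_tumor"
    evidence: str  # snv_carrier / missing_all_copies_snv / loh_lost_haplotype / normal_biopsy
    locus: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("tumor", "non_tumor"):
            raise ValueError(f"bad label {self.label}")
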