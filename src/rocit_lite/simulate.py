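"""Synthetic bulk-biopsy generator with known per-read cell of origin.

The simulator emulates a tumor biopsy sequenced with modified-base-tagged
long reads: a mixture of one tumor population and several normal cell types,
each with its own per-site methylation propensity; planted clonal/subclonal
SNVs whose allele fractions follow the purity/copy-number expectation
f = n c rho / (rho N_T + (1 - rho) N_N); phase blocks, LOH segments, and
per-molecule stochastic methylation calls with caller noise re-quantized to
the 0-255 grid.

Methylation model: each CpG site has a base propensity drawn from a
Beta(a, b) prior; each cell type keeps the base value except at a
cell-type-specific fraction of sites where it redraws, and the tumor
additionally shifts a fraction of sites by a fixed amount toward the
opposite extreme.  A molecule's binary state is Bernoulli(site mean) and the
reported probability is the state plus clipped Gaussian caller noise.

Haplotype convention: haplotype 1 carries the major allele of every segment
(so LOH segments emit no tumor reads on haplotype 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .types import (
    Cluster,
    ClusterModel,
    CopyNumberSegment,
    MethylRead,
    SamplePurity,
    VariantRecord,
)


@dataclass
class SegmentSpec:
    chromosome: str
    start: int
    end: int
    n_total: int
    n_minor: int


@dataclass
class SubclonalClusterSpec:
    ccf: float
    n_variants: int


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic biopsy (defaults are desk scale)."""

    seed: int = 0
    n_reads: int = 20_000
    read_length_mean: float = 15_000.0
    read_length_sd: float = 3_000.0
    read_length_min: int = 500
    cpg_density_per_kb: float = 10.0
    purity: float = 0.6
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 5_000_000,
            "chr2": 5_000_000,
            "chr4": 5_000_000,
            "chr5": 5_000_000,
            "chr21": 5_000_000,
            "chr22": 5_000_000,
        }
    )
    segments: list[SegmentSpec] = field(
        default_factory=lambda: [
            SegmentSpec("chr1", 0, 5_000_000, 2, 1),
            SegmentSpec("chr2", 0, 2_000_000, 1, 0),
            SegmentSpec("chr2", 2_000_000, 5_000_000, 2, 1),
            SegmentSpec("chr4", 0, 5_000_000, 2, 1),
            SegmentSpec("chr5", 0, 2_500_000, 2, 1),
            SegmentSpec("chr5", 2_500_000, 5_000_000, 3, 1),
            SegmentSpec("chr21", 0, 2_500_000, 3, 1),
            SegmentSpec("chr21", 2_500_000, 5_000_000, 4, 1),
            SegmentSpec("chr22", 0, 2_000_000, 1, 0),
            SegmentSpec("chr22", 2_000_000, 5_000_000, 2, 0),
        ]
    )
    n_clonal_snvs: int = 150
    subclonal_clusters: list[SubclonalClusterSpec] = field(
        default_factory=lambda: [SubclonalClusterSpec(0.6, 60), SubclonalClusterSpec(0.35, 40)]
    )
    frac_multiplicity_max: float = 0.5  # clonal SNVs on amplified majors at full multiplicity
    n_normal_cell_types: int = 5
    normal_mixture_weights: tuple[float, ...] = (0.4, 0.25, 0.15, 0.12, 0.08)
    n_atlas_cell_types: int = 84
    beta_a: float = 0.3
    beta_b: float = 0.3
    cell_type_specific_fraction: float = 0.2
    tumor_differential_fraction: float = 0.25
    tumor_mean_shift: float = 0.5
    caller_noise_sd: float = 0.1
    sequencing_error_rate: float = 0.002
    phasing_rate: float = 0.9
    phase_block_length_range: tuple[int, int] = (800_000, 2_200_000)
    atlas_missing_site_fraction: float = 0.08

    def __post_init__(self) -> None:
        if abs(sum(self.normal_mixture_weights) - 1.0) > 1e-8:
            raise ValueError("normal mixture weights must sum to 1")
        if len(self.normal_mixture_weights) != self.n_normal_cell_types:
            raise ValueError("one mixture weight per normal cell type")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        for c in self.subclonal_clusters:
            if c.ccf > 1.0:
                raise ValueError(f"subclonal CCF {c.ccf} exceeds 1")
        for s in self.segments:
            CopyNumberSegment(s.chromosome, s.start, s.end, s.n_total, s.n_minor)

    @classmethod
    def no_signal(cls, **overrides) -> "SimulationConfig":
        """All cell populations (tumor included) share identical site means."""
        return cls(
            tumor_differential_fraction=0.0,
            cell_type_specific_fraction=0.0,
            **overrides,
        )


@dataclass
class VariantTruth:
    cluster_id: int
    ccf: float
    multiplicity: int
    haplotype: int
    allele: str


@dataclass
class GroundTruth:
    """Per-read origin / haplotype and per-variant clonal structure."""

    origin: dict[str, str]  # read_id -> "tumor" | "normal:<type>"
    haplotype: dict[str, int]
    variants: dict[tuple[str, int], VariantTruth]

    def is_tumor(self, read_id: str) -> bool:
        return self.origin[read_id] == "tumor"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": list(self.origin),
                "origin": [self.origin[r] for r in self.origin],
                "haplotype": [self.haplotype[r] for r in self.origin],
            }
        )


@dataclass
class Biopsy:
    """Everything one synthetic biopsy emits, in memory."""

    reads: list[MethylRead]
    variants: list[VariantRecord]
    segments: list[CopyNumberSegment]
    clusters: ClusterModel
    atlas: "rio.CellTypeAtlas"
    purity: SamplePurity
    truth: GroundTruth
    config: SimulationConfig
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _methylation_means(cfg: SimulationConfig, rng: np.random.Generator, n_sites: int):
    """Site means for the tumor, the real normal cell types, and atlas decoys."""
    base = rng.beta(cfg.beta_a, cfg.beta_b, size=n_sites)
    n_types = cfg.n_atlas_cell_types
    means = np.tile(base, (n_types, 1))
    specific = rng.random((n_types, n_sites)) < cfg.cell_type_specific_fraction
    means[specific] = rng.beta(cfg.beta_a, cfg.beta_b, size=int(specific.sum()))
    tumor = base.copy()
    diff = rng.random(n_sites) < cfg.tumor_differential_fraction
    shift = np.where(base < 0.5, cfg.tumor_mean_shift, -cfg.tumor_mean_shift)
    tumor[diff] = np.clip(base[diff] + shift[diff], 0.02, 0.98)
    return tumor.astype(np.float64), means.astype(np.float64)


def simulate_biopsy(config: SimulationConfig) -> Biopsy:
    """Generate a complete synthetic biopsy; deterministic given config.seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chromosomes)

    # CpG sites and methylation means, per chromosome
    site_pos: dict[str, np.ndarray] = {}
    tumor_mean: dict[str, np.ndarray] = {}
    cell_means: dict[str, np.ndarray] = {}  # (84, n_sites)
    for chrom in chroms:
        length = cfg.chromosomes[chrom]
        n_sites = int(length * cfg.cpg_density_per_kb / 1000)
        pos = np.sort(rng.choice(length - 2, size=n_sites, replace=False))
        pos = pos[np.concatenate([[True], np.diff(pos) > 1])]
        site_pos[chrom] = pos.astype(np.int64)
        tm, cm = _methylation_means(cfg, rng, len(pos))
        tumor_mean[chrom], cell_means[chrom] = tm, cm

    segments = [
        CopyNumberSegment(s.chromosome, s.start, s.end, s.n_total, s.n_minor) for s in cfg.segments
    ]
    purity = SamplePurity(cfg.purity) if cfg.purity > 0 else None
    rho = cfg.purity

    # phase blocks tiling each chromosome
    block_bounds: dict[str, np.ndarray] = {}
    for chrom in chroms:
        length = cfg.chromosomes[chrom]
        bounds = [0]
        while bounds[-1] < length:
            bounds.append(bounds[-1] + int(rng.integers(*cfg.phase_block_length_range)))
        bounds[-1] = length
        block_bounds[chrom] = np.array(bounds, dtype=np.int64)

    # planted variants
    clusters = [Cluster(1, 1.0, cfg.n_clonal_snvs)] + [
        Cluster(i + 2, sc.ccf, sc.n_variants) for i, sc in enumerate(cfg.subclonal_clusters)
    ]
    cluster_model = ClusterModel(clusters)
    variant_truth: dict[tuple[str, int], VariantTruth] = {}
    bases = np.array(list("ACGT"))
    seg_by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.chromosome, []).append(seg)
    genome_len = sum(cfg.chromosomes.values())
    chrom_probs = np.array([cfg.chromosomes[c] for c in chroms]) / genome_len
    for cluster in clusters:
        for _ in range(cluster.n_assigned_variants):
            for _attempt in range(100):
                chrom = rng.choice(chroms, p=chrom_probs)
                pos = int(rng.integers(0, cfg.chromosomes[chrom] - 1))
                seg = next((s for s in seg_by_chrom[chrom] if s.start <= pos < s.end), None)
                if seg is None or seg.n_total == 0:
                    continue
                near = np.searchsorted(site_pos[chrom], pos)
                lo = max(0, near - 1)
                if np.any(np.abs(site_pos[chrom][lo: near + 1] - pos) <= 1):
                    continue  # keep SNVs off CpG sites
                if (chrom, pos) in variant_truth:
                    continue
                break
            else:
                continue
            # haplotype 1 = major; lost haplotype (2) carries no tumor variants in LOH
            hap = 1 if seg.n_minor == 0 else int(rng.integers(1, 3))
            copies = seg.n_major if hap == 1 else seg.n_minor
            mult = 1
            if cluster.cluster_id == 1 and copies > 1 and rng.random() < cfg.frac_multiplicity_max:
                mult = copies
            variant_truth[(chrom, pos)] = VariantTruth(
                cluster_id=cluster.cluster_id,
                ccf=cluster.ccf,
                multiplicity=mult,
                haplotype=hap,
                allele="major" if hap == 1 else "minor",
            )
    var_pos_by_chrom = {
        c: np.array(sorted(p for cc, p in variant_truth if cc == c), dtype=np.int64) for c in chroms
    }
    ref_alt: dict[tuple[str, int], tuple[str, str]] = {}
    for key in variant_truth:
        r, a = rng.choice(4, size=2, replace=False)
        ref_alt[key] = (str(bases[r]), str(bases[a]))

    # segment sampling weights proportional to local DNA mass
    seg_mass = np.array(
        [s.length * (rho * s.n_total + (1 - rho) * s.n_normal) for s in segments], dtype=np.float64
    )
    seg_prob = seg_mass / seg_mass.sum()

    weights = np.asarray(cfg.normal_mixture_weights)
    reads: list[MethylRead] = []
    origin: dict[str, str] = {}
    true_hap: dict[str, int] = {}
    alt_counts: dict[tuple[str, int], int] = {k: 0 for k in variant_truth}
    tot_counts: dict[tuple[str, int], int] = {k: 0 for k in variant_truth}

    seg_idx = rng.choice(len(segments), size=cfg.n_reads, p=seg_prob)
    lengths = np.maximum(
        cfg.read_length_min,
        rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=cfg.n_reads).astype(np.int64),
    )
    for i in range(cfg.n_reads):
        seg = segments[seg_idx[i]]
        chrom = seg.chromosome
        length = int(min(lengths[i], seg.length))
        start = int(rng.integers(seg.start, max(seg.start + 1, seg.end - length)))
        end = start + length
        # origin: tumor with probability rho*N_T / (rho*N_T + (1-rho)*N_N)
        p_tumor = rho * seg.n_total / (rho * seg.n_total + (1 - rho) * seg.n_normal)
        is_tumor = rng.random() < p_tumor
        if is_tumor:
            hap = 1 if rng.random() < seg.n_major / seg.n_total else 2
            cell = "tumor"
        else:
            hap = int(rng.integers(1, 3))
            cell = f"normal:{int(rng.choice(cfg.n_normal_cell_types, p=weights))}"
        pos_all = site_pos[chrom]
        s_lo, s_hi = np.searchsorted(pos_all, [start, end])
        covered = pos_all[s_lo:s_hi]
        if cell == "tumor":
            means = tumor_mean[chrom][s_lo:s_hi]
        else:
            means = cell_means[chrom][int(cell.split(":")[1]), s_lo:s_hi]
        state = rng.random(len(covered)) < means
        noisy = np.clip(state + rng.normal(0.0, cfg.caller_noise_sd, size=len(covered)), 0.0, 1.0)
        raw = rio.quantize_methylation(noisy)

        # variant observations
        obs: list[tuple[int, str]] = []
        vpos = var_pos_by_chrom[chrom]
        v_lo, v_hi = np.searchsorted(vpos, [start, end])
        for p in vpos[v_lo:v_hi]:
            key = (chrom, int(p))
            vt = variant_truth[key]
            ref, alt = ref_alt[key]
            copies = seg.n_major if vt.haplotype == 1 else seg.n_minor
            carries = (
                cell == "tumor"
                and hap == vt.haplotype
                and copies > 0
                and rng.random() < vt.ccf * vt.multiplicity / copies
            )
            if rng.random() < cfg.sequencing_error_rate:
                carries = not carries
            base = alt if carries else ref
            obs.append((int(p), base))
            tot_counts[key] += 1
            if carries:
                alt_counts[key] += 1

        # phasing tags
        reported_hap: Optional[int] = hap if rng.random() < cfg.phasing_rate else None
        block_id = None
        if reported_hap is not None:
            b = int(np.searchsorted(block_bounds[chrom], start, side="right") - 1)
            block_id = f"{chrom}_pb{b}"
        read_id = f"r{i:06d}"
        reads.append(
            MethylRead(
                read_id=read_id,
                chromosome=chrom,
                cpg_positions=covered,
                meth_raw=raw,
                meth_prob=rio.scale_methylation(raw),
                haplotype=reported_hap,
                phase_block_id=block_id,
                variant_observations=obs,
                reference_start=start,
                reference_end=end,
            )
        )
        origin[read_id] = cell
        true_hap[read_id] = hap

    variants = [
        VariantRecord(
            chromosome=c,
            position=p,
            ref=ref_alt[(c, p)][0],
            alt=ref_alt[(c, p)][1],
            alt_read_count=alt_counts[(c, p)],
            total_read_count=tot_counts[(c, p)],
            caller_status={"long_read": "PASS", "short_read": "PASS"},
        )
        for (c, p) in variant_truth
    ]

    # atlas: the exact per-cell-type means, with a fraction of sites withheld
    atlas_chroms, atlas_positions, atlas_blocks = [], [], []
    for chrom in chroms:
        keep = rng.random(len(site_pos[chrom])) >= cfg.atlas_missing_site_fraction
        atlas_chroms.append(np.full(int(keep.sum()), chrom, dtype=object))
        atlas_positions.append(site_pos[chrom][keep])
        atlas_blocks.append(cell_means[chrom][:, keep].T)
    atlas = rio.atlas_from_frame(
        np.concatenate(atlas_chroms),
        np.concatenate(atlas_positions),
        np.concatenate(atlas_blocks).astype(np.float32),
        [f"cell_type_{j:02d}" for j in range(cfg.n_atlas_cell_types)],
    )

    return Biopsy(
        reads=reads,
        variants=variants,
        segments=segments,
        clusters=cluster_model,
        atlas=atlas,
        purity=purity if purity is not None else SamplePurity(1e-9),
        truth=GroundTruth(origin, true_hap, variant_truth),
        config=cfg,
        chrom_lengths=dict(cfg.chromosomes),
    )


def simulate_normal_biopsy(config: SimulationConfig, seed_offset: int = 104729) -> Biopsy:
    """Matched adjacent-normal biopsy: same cell types and atlas regime, no tumor.

    Uses a purity of zero and no somatic variants; site means are re-drawn
    from the same priors under a shifted seed (a different genome draw, which
    is conservative for transfer experiments).
    """
    cfg = replace(
        config,
        purity=0.0,
        n_clonal_snvs=0,
        subclonal_clusters=[],
        seed=config.seed + seed_offset,
        segments=[
            SegmentSpec(s.chromosome, s.start, s.end, 2, 1) for s in config.segments
        ],
    )
    return simulate_biopsy(cfg)


def crop_reads(
    reads: Sequence[MethylRead], target_length_bp: int, seed: int
) -> list[MethylRead]:
    """Crop each read to a random contiguous window of ``target_length_bp``.

    Reads already at or below the target pass through unchanged.  CpGs and
    variant observations outside the window are dropped; reproducible per
    seed.
    """
    rng = np.random.default_rng(seed)
    out: list[MethylRead] = []
    for read in reads:
        span = read.reference_end - read.reference_start
        if span <= target_length_bp:
            out.append(read)
            continue
        start = int(rng.integers(read.reference_start, read.reference_end - target_length_bp + 1))
        end = start + target_length_bp
        lo, hi = np.searchsorted(read.cpg_positions, [start, end])
        out.append(
            MethylRead(
                read_id=read.read_id,
                chromosome=read.chromosome,
                cpg_positions=read.cpg_positions[lo:hi],
                meth_raw=read.meth_raw[lo:hi],
                meth_prob=read.meth_prob[lo:hi],
                haplotype=read.haplotype,
                phase_block_id=read.phase_block_id,
                variant_observations=[
                    (p, b) for p, b in read.variant_observations if start <= p < end
                ],
                reference_start=start,
                reference_end=end,
            )
        )
    return out


def write_biopsy(biopsy: Biopsy, out_dir: str) -> dict[str, str]:
    """Write the biopsy in the external formats the loaders consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sam": str(out / "reads.sam"),
        "vcf": str(out / "somatic.vcf"),
        "segments": str(out / "segments.tsv"),
        "clusters": str(out / "clusters.tsv"),
        "atlas": str(out / "atlas.tsv"),
        "truth": str(out / "truth.tsv"),
        "purity": str(out / "purity.txt"),
    }
    variant_bases: dict[str, dict[int, dict[str, str]]] = {}
    for read in biopsy.reads:
        for pos, base in read.variant_observations:
            variant_bases.setdefault(read.chromosome, {}).setdefault(pos, {})[read.read_id] = base
    rio.write_sam(paths["sam"], biopsy.reads, biopsy.chrom_lengths, variant_bases)
    rio.write_variants(paths["vcf"], biopsy.variants, biopsy.chrom_lengths)
    rio.write_segments(paths["segments"], biopsy.segments)
    rio.write_clusters(paths["clusters"], biopsy.clusters)
    rio.write_atlas(paths["atlas"], biopsy.atlas)
    biopsy.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    Path(paths["purity"]).write_text(f"{biopsy.purity.rho}\n")
    return paths
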