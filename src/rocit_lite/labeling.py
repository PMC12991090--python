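"""Derive ground-truth tumor / non-tumor read labels from somatic variants,
copy number, purity and phasing.

Tumor labels come from reads carrying a high-confidence somatic SNV.
Non-tumor labels come from two sources: (i) haplotype-matched reads missing a
clonal SNV that is present on all tumor copies of its haplotype, and (ii)
reads phased to the lost haplotype inside clonal LOH segments.  Every filter
is applied through an exact two-tailed binomial consistency test against the
copy-number/purity expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    ClusterModel,
    CopyNumberSegment,
    LabeledRead,
    MethylRead,
    SamplePurity,
    VariantRecord,
)

logger = logging.getLogger(__name__)

AUTOSOMES_AND_X = {f"chr{i}" for i in range(1, 23)} | {"chrX"} | {str(i) for i in range(1, 23)} | {"X"}

MIN_PHASE_BLOCK_BP = 500_000
MIN_SNV_READS = 3
MAX_TUMOR_LABEL_CCF = 1.1
PHASE_TEST_ALPHA = 0.1
LOH_MIN_SEGMENT_BP = 1_000_000
LOH_MAJOR_CN_RANGE = (1, 4)
LOH_MIN_COVERAGE = 20
LOH_MAX_FREQ_DEVIATION = 0.05
LOH_SUBINTERVAL_BP = 100_000
CLONAL_CCF_WINDOW = (0.9, 1.1)
CLONAL_MIN_VARIANT_SHARE = 0.3


# ---------------------------------------------------------------------------
# closed-form expected fractions
# ---------------------------------------------------------------------------

def expected_variant_fraction(n: int, c: float, rho: float, n_total: int, n_normal: int = 2) -> float:
    """Expected alt-read fraction of a somatic SNV.

    f = n c rho / (rho N_Total + (1 - rho) N_Normal), for multiplicity n and
    cluster cancer cell fraction c.
    """
    if n < 1:
        raise ValueError("multiplicity must be >= 1")
    if c < 0:
        raise ValueError("CCF must be non-negative")
    denom = rho * n_total + (1.0 - rho) * n_normal
    if denom <= 0:
        raise ValueError("rho*N_Total + (1-rho)*N_Normal must be positive")
    return n * c * rho / denom


def expected_minor_fraction(rho: float, n_minor: int, n_total: int, n_normal: int = 2) -> float:
    """Expected share of reads deriving from the minor allele of a segment:
    (rho N_Minor + (1 - rho)) / (rho N_Total + (1 - rho) N_Normal).

    The (1 - rho) numerator term is the single normal copy carried by each
    parental haplotype on autosomes.
    """
    denom = rho * n_total + (1.0 - rho) * n_normal
    if denom <= 0:
        raise ValueError("rho*N_Total + (1-rho)*N_Normal must be positive")
    return (rho * n_minor + (1.0 - rho)) / denom


def expected_variant_read_fraction_all_copies(rho: float, n_allele: int) -> float:
    """Expected fraction of variant-haplotype reads carrying an SNV present on
    all tumor copies of its allele: rho N_allele / (rho N_allele + (1 - rho)).
    """
    denom = rho * n_allele + (1.0 - rho)
    if denom <= 0:
        raise ValueError("rho*N_allele + (1-rho) must be positive")
    return rho * n_allele / denom


def expected_lost_allele_fraction(rho: float, n_total: int, n_normal: int = 2) -> float:
    """Expected share of reads on the lost haplotype of an LOH segment:
    (1 - rho) / (rho N_Total + (1 - rho) N_Normal)."""
    denom = rho * n_total + (1.0 - rho) * n_normal
    if denom <= 0:
        raise ValueError("rho*N_Total + (1-rho)*N_Normal must be positive")
    return (1.0 - rho) / denom


# ---------------------------------------------------------------------------
# binomial consistency test
# ---------------------------------------------------------------------------

def two_tailed_binomial_p(k: int, n: int, p: float, method: str = "minlike") -> float:
    """Exact two-tailed binomial p-value.

    ``minlike`` sums the probability of all outcomes no more likely than the
    observed one (scipy's default two-sided method); ``doubling`` doubles the
    smaller one-sided tail, capped at 1.
    """
    if n <= 0:
        raise ValueError("coverage must be positive")
    p = min(max(p, 0.0), 1.0)
    if method == "minlike":
        return float(stats.binomtest(k, n, p).pvalue)
    if method == "doubling":
        lo = stats.binom.cdf(k, n, p)
        hi = stats.binom.sf(k - 1, n, p)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown method {method}")


def phase_block_consistency_test(
    n_minor_reads: int, coverage: int, f_minor: float, method: str = "minlike"
) -> float:
    """P-value that the minor-allele read count in a phase block matches
    Binomial(coverage, f_minor); the caller filters blocks with p < 0.1."""
    return two_tailed_binomial_p(n_minor_reads, coverage, f_minor, method=method)


# ---------------------------------------------------------------------------
# cluster / multiplicity assignment
# ---------------------------------------------------------------------------

def identify_clonal_cluster(clusters: ClusterModel) -> Optional[int]:
    """The cluster with CCF in [0.9, 1.1] holding >= 30% of variants.

    Returns None if no cluster qualifies; if several do, the one assigned the
    most variants wins.
    """
    total = clusters.total_variants
    if total == 0:
        return None
    best = None
    for c in clusters.clusters:
        if CLONAL_CCF_WINDOW[0] <= c.ccf <= CLONAL_CCF_WINDOW[1] and c.n_assigned_variants / total >= CLONAL_MIN_VARIANT_SHARE:
            if best is None or c.n_assigned_variants > best.n_assigned_variants:
                best = c
    return best.cluster_id if best is not None else None


def assign_cluster_multiplicity(
    variant: VariantRecord,
    clusters: ClusterModel,
    segment: CopyNumberSegment,
    purity: SamplePurity,
) -> tuple[Optional[int], Optional[int]]:
    """Maximum binomial-likelihood cluster and multiplicity for a variant.

    For each cluster the admissible multiplicities are 1..major copy number
    if the cluster is clonal, and exactly 1 otherwise.  Each state's
    likelihood is Binom(alt | total, f) weighted by the cluster's assigned
    variant count; a cluster's likelihood sums over its multiplicities.
    Ties break to the higher-CCF cluster, then to the lower multiplicity.
    """
    if variant.total_read_count <= 0:
        return None, None
    clonal_id = identify_clonal_cluster(clusters)
    best: Optional[tuple[float, float, int]] = None  # (likelihood, ccf, cluster_id)
    best_mult: dict[int, int] = {}
    for cluster in clusters.clusters:
        max_mult = segment.n_major if cluster.cluster_id == clonal_id else 1
        max_mult = max(1, max_mult)
        mult_lik = []
        for n in range(1, max_mult + 1):
            try:
                f = expected_variant_fraction(n, cluster.ccf, purity.rho, segment.n_total, segment.n_normal)
            except ValueError:
                continue
            f = min(f, 1.0)
            lik = stats.binom.pmf(variant.alt_read_count, variant.total_read_count, f)
            mult_lik.append((n, float(lik)))
        if not mult_lik:
            continue
        total_lik = sum(l for _, l in mult_lik) * cluster.n_assigned_variants
        # within-cluster argmax multiplicity, ties to lower n
        n_best = max(mult_lik, key=lambda t: (t[1], -t[0]))[0]
        best_mult[cluster.cluster_id] = n_best
        key = (total_lik, cluster.ccf, cluster.cluster_id)
        if best is None or key[:2] > best[:2]:
            best = key
    if best is None or best[0] <= 0:
        return None, None
    cid = best[2]
    return cid, best_mult[cid]


# ---------------------------------------------------------------------------
# variant-level context assembled from reads
# ---------------------------------------------------------------------------

@dataclass
class VariantSupport:
    """Read support for one variant position, split by observed base/haplotype."""

    alt_reads: list[MethylRead] = field(default_factory=list)
    ref_reads: list[MethylRead] = field(default_factory=list)
    alt_haplotypes: set = field(default_factory=set)
    covering_haplotypes: set = field(default_factory=set)

    @property
    def n_alt(self) -> int:
        return len(self.alt_reads)

    @property
    def n_total(self) -> int:
        return len(self.alt_reads) + len(self.ref_reads)


def collect_variant_support(reads: Sequence[MethylRead], variants: Sequence[VariantRecord]) -> dict:
    """Index reads by their observed base at each variant locus."""
    keys = {v.key: v for v in variants}
    support: dict[tuple[str, int], VariantSupport] = {k: VariantSupport() for k in keys}
    for read in reads:
        for pos, base in read.variant_observations:
            key = (read.chromosome, pos)
            v = keys.get(key)
            if v is None:
                continue
            sup = support[key]
            if base == v.alt:
                sup.alt_reads.append(read)
                if read.haplotype is not None:
                    sup.alt_haplotypes.add(read.haplotype)
            else:
                sup.ref_reads.append(read)
            if read.haplotype is not None:
                sup.covering_haplotypes.add(read.haplotype)
    return support


def segment_for(segments: Sequence[CopyNumberSegment], chromosome: str, position: int) -> Optional[CopyNumberSegment]:
    for seg in segments:
        if seg.contains(chromosome, position):
            return seg
    return None


@dataclass
class PhaseBlockIndex:
    """Span and per-haplotype read membership of each phase block."""

    span: dict[str, tuple[str, int, int]] = field(default_factory=dict)  # id -> (chrom, start, end)
    reads: dict[str, list[MethylRead]] = field(default_factory=dict)

    @classmethod
    def from_reads(cls, reads: Sequence[MethylRead]) -> "PhaseBlockIndex":
        idx = cls()
        for r in reads:
            if r.phase_block_id is None:
                continue
            key = r.phase_block_id
            idx.reads.setdefault(key, []).append(r)
            if key in idx.span:
                chrom, s, e = idx.span[key]
                idx.span[key] = (chrom, min(s, r.reference_start), max(e, r.reference_end))
            else:
                idx.span[key] = (r.chromosome, r.reference_start, r.reference_end)
        return idx

    def length(self, block_id: str) -> int:
        chrom, s, e = self.span[block_id]
        return e - s


def minor_haplotype_of_block(block_reads: Sequence[MethylRead]) -> tuple[Optional[int], int, int]:
    """(minor haplotype, minor count, assigned coverage) by read majority.

    The parental haplotype with fewer phased reads is taken as the minor
    (in LOH segments: the lost) allele; ties resolve to haplotype 2.
    """
    n1 = sum(1 for r in block_reads if r.haplotype == 1)
    n2 = sum(1 for r in block_reads if r.haplotype == 2)
    if n1 + n2 == 0:
        return None, 0, 0
    minor = 1 if n1 < n2 else 2
    return minor, min(n1, n2), n1 + n2


# ---------------------------------------------------------------------------
# tumor-label variant filters
# ---------------------------------------------------------------------------

@dataclass
class LabelingConfig:
    cohort_mode: str = "strict"  # strict: short-read PASS required; relaxed: not germline-flagged
    binomial_method: str = "minlike"
    phase_alpha: float = PHASE_TEST_ALPHA
    min_phase_block_bp: int = MIN_PHASE_BLOCK_BP
    min_snv_reads: int = MIN_SNV_READS
    max_ccf: float = MAX_TUMOR_LABEL_CCF


def filter_tumor_label_variants(
    variants: Sequence[VariantRecord],
    reads: Sequence[MethylRead],
    segments: Sequence[CopyNumberSegment],
    clusters: ClusterModel,
    purity: SamplePurity,
    config: LabelingConfig | None = None,
) -> list[VariantRecord]:
    """Apply the tumor-label variant filters; annotates cluster/multiplicity.

    Retained SNVs are autosomal/chrX, PASS by the long-read caller (and by
    the short-read caller in strict mode, or merely not germline-flagged in
    relaxed mode), sit in a phase block >= 500 kb, have >= 3 alt-carrying
    reads all phased to one haplotype with both haplotypes covering the
    locus, belong to a cluster with CCF < 1.1, and lie in a phase block whose
    minor-allele read count is binomially consistent with the local copy
    number (p >= 0.1).
    """
    cfg = config or LabelingConfig()
    support = collect_variant_support(reads, variants)
    blocks = PhaseBlockIndex.from_reads(reads)
    block_pvalues = _phase_block_pvalues(blocks, segments, purity, cfg)
    retained = []
    for v in variants:
        if v.chromosome not in AUTOSOMES_AND_X:
            continue
        if v.caller_status.get("long_read", "FAIL") != "PASS":
            continue
        if cfg.cohort_mode == "strict":
            if v.caller_status.get("short_read", "FAIL") != "PASS":
                continue
        else:
            if v.caller_status.get("short_read_germline") == "FLAGGED":
                continue
        sup = support.get(v.key)
        if sup is None or sup.n_alt < cfg.min_snv_reads:
            continue
        if len(sup.covering_haplotypes) < 2 or len(sup.alt_haplotypes) != 1:
            continue
        block_ids = {r.phase_block_id for r in sup.alt_reads if r.phase_block_id is not None}
        if not block_ids:
            continue
        block_id = block_ids.pop()
        if block_ids:  # alt reads spread over several blocks
            continue
        if blocks.length(block_id) < cfg.min_phase_block_bp:
            continue
        seg = segment_for(segments, v.chromosome, v.position)
        if seg is None:
            continue
        v2 = VariantRecord(**{**v.__dict__})
        v2.alt_read_count = sup.n_alt
        v2.total_read_count = sup.n_total
        v2.haplotype_of_alt = next(iter(sup.alt_haplotypes))
        cid, mult = assign_cluster_multiplicity(v2, clusters, seg, purity)
        if cid is None:
            continue
        if clusters.by_id(cid).ccf >= cfg.max_ccf:
            continue
        pval = block_pvalues.get(block_id)
        if pval is None or pval < cfg.phase_alpha:
            continue
        v2.cluster_id, v2.multiplicity = cid, mult
        retained.append(v2)
    return retained


def _phase_block_pvalues(
    blocks: PhaseBlockIndex,
    segments: Sequence[CopyNumberSegment],
    purity: SamplePurity,
    cfg: LabelingConfig,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for block_id, block_reads in blocks.reads.items():
        chrom, start, end = blocks.span[block_id]
        seg = _max_overlap_segment(segments, chrom, start, end)
        if seg is None:
            continue
        minor_hap, n_minor, cov = minor_haplotype_of_block(block_reads)
        if cov == 0:
            continue
        f_minor = expected_minor_fraction(purity.rho, seg.n_minor, seg.n_total, seg.n_normal)
        out[block_id] = phase_block_consistency_test(n_minor, cov, f_minor, method=cfg.binomial_method)
    return out


def _max_overlap_segment(
    segments: Sequence[CopyNumberSegment], chrom: str, start: int, end: int
) -> Optional[CopyNumberSegment]:
    best, best_ov = None, 0
    for seg in segments:
        ov = seg.overlap(chrom, start, end)
        if ov > best_ov:
            best, best_ov = seg, ov
    return best


# ---------------------------------------------------------------------------
# all-copies variants (non-tumor labels)
# ---------------------------------------------------------------------------

def select_all_copies_variants(
    variants: Sequence[VariantRecord],
    reads: Sequence[MethylRead],
    segments: Sequence[CopyNumberSegment],
    clusters: ClusterModel,
    purity: SamplePurity,
    config: LabelingConfig | None = None,
) -> list[VariantRecord]:
    """From tumor-label variants, keep those on all tumor copies of their allele.

    The variant must be assigned to the clonal cluster; its allele is major
    or minor by which haplotype has more reads at the position; variants with
    multiplicity below the allele copy number are dropped, and the variant
    haplotype's alt-read count must be binomially consistent (p >= 0.1) with
    the all-copies expectation rho N_allele / (rho N_allele + 1 - rho).
    """
    cfg = config or LabelingConfig()
    clonal_id = identify_clonal_cluster(clusters)
    if clonal_id is None:
        return []
    support = collect_variant_support(reads, variants)
    out = []
    for v in variants:
        if v.cluster_id != clonal_id:
            continue
        seg = segment_for(segments, v.chromosome, v.position)
        if seg is None or v.haplotype_of_alt is None:
            continue
        sup = support[v.key]
        hap = v.haplotype_of_alt
        n_hap = sum(1 for r in sup.alt_reads + sup.ref_reads if r.haplotype == hap)
        n_other = sum(1 for r in sup.alt_reads + sup.ref_reads if r.haplotype not in (None, hap))
        allele = "major" if n_hap > n_other else "minor"
        n_allele = seg.n_major if allele == "major" else seg.n_minor
        if v.multiplicity is None or v.multiplicity < n_allele or n_allele < 1:
            continue
        n_alt_on_hap = sum(1 for r in sup.alt_reads if r.haplotype == hap)
        if n_hap == 0:
            continue
        f_reads = expected_variant_read_fraction_all_copies(purity.rho, n_allele)
        pval = two_tailed_binomial_p(n_alt_on_hap, n_hap, f_reads, method=cfg.binomial_method)
        if pval < cfg.phase_alpha:
            continue
        v2 = VariantRecord(**{**v.__dict__})
        v2.allele = allele
        out.append(v2)
    return out


# ---------------------------------------------------------------------------
# LOH labelling
# ---------------------------------------------------------------------------

def split_into_subintervals(start: int, end: int, target: int = LOH_SUBINTERVAL_BP) -> list[tuple[int, int]]:
    """Split [start, end) into equal intervals as close to ``target`` as possible.

    The interval count is round-half-to-even of length/target, floored at 1.
    """
    length = end - start
    k = max(1, int(np.round(length / target)))
    bounds = np.linspace(start, end, k + 1).round().astype(np.int64)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(k)]


def label_non_tumor_by_loh(
    reads: Sequence[MethylRead],
    segments: Sequence[CopyNumberSegment],
    purity: SamplePurity,
    config: LabelingConfig | None = None,
) -> list[LabeledRead]:
    """Label lost-haplotype reads in eligible clonal LOH segments as non-tumor.

    Segment eligibility: LOH (minor copy 0), >= 1 Mb, major copy in [1, 4],
    >= 20 covering reads, both haplotypes observed.  Within a segment, each
    phase block must satisfy |f_observed - f_minor| <= 0.05, re-checked on
    equal sub-intervals nearest 100 kb; reads whose maximum-overlap
    sub-interval fails are dropped.
    """
    del config  # thresholds are the method's fixed constants
    blocks = PhaseBlockIndex.from_reads(reads)
    labels: list[LabeledRead] = []
    for seg in segments:
        if not seg.is_loh or seg.length < LOH_MIN_SEGMENT_BP:
            continue
        if not (LOH_MAJOR_CN_RANGE[0] <= seg.n_major <= LOH_MAJOR_CN_RANGE[1]):
            continue
        seg_reads = [
            r
            for r in reads
            if r.chromosome == seg.chromosome
            and _read_max_overlap_in(r, seg.start, seg.end)
        ]
        if len(seg_reads) < LOH_MIN_COVERAGE:
            continue
        haps = {r.haplotype for r in seg_reads if r.haplotype is not None}
        if len(haps) < 2:
            continue
        f_minor = expected_lost_allele_fraction(purity.rho, seg.n_total, seg.n_normal)
        for block_id in {r.phase_block_id for r in seg_reads if r.phase_block_id is not None}:
            block_reads = [r for r in seg_reads if r.phase_block_id == block_id]
            lost_hap, n_lost, cov = minor_haplotype_of_block(block_reads)
            if cov == 0 or lost_hap is None:
                continue
            if abs(n_lost / cov - f_minor) > LOH_MAX_FREQ_DEVIATION:
                continue
            chrom, bs, be = blocks.span[block_id]
            bs, be = max(bs, seg.start), min(be, seg.end)
            if be <= bs:
                continue
            subs = split_into_subintervals(bs, be)
            sub_ok = []
            for s, e in subs:
                sub_reads = [r for r in block_reads if _read_max_overlap_in(r, s, e, subs)]
                s_lost, s_n, s_cov = minor_haplotype_of_block(sub_reads)
                if s_cov == 0:
                    sub_ok.append(False)
                    continue
                n_on_lost = sum(1 for r in sub_reads if r.haplotype == lost_hap)
                sub_ok.append(abs(n_on_lost / s_cov - f_minor) <= LOH_MAX_FREQ_DEVIATION)
            for r in block_reads:
                if r.haplotype != lost_hap:
                    continue
                idx = _max_overlap_index(r, subs)
                if idx is not None and sub_ok[idx]:
                    labels.append(
                        LabeledRead(
                            read_id=r.read_id,
                            label="non_tumor",
                            evidence="loh_lost_haplotype",
                            locus=f"{seg.chromosome}:{seg.start}-{seg.end}",
                        )
                    )
    return labels


def _read_max_overlap_in(read: MethylRead, start: int, end: int, intervals=None) -> bool:
    if intervals is None:
        mid_ov = min(read.reference_end, end) - max(read.reference_start, start)
        outside = (read.reference_end - read.reference_start) - mid_ov
        return mid_ov > 0 and mid_ov >= outside
    idx = _max_overlap_index(read, intervals)
    return idx is not None and intervals[idx] == (start, end)


def _max_overlap_index(read: MethylRead, intervals: list[tuple[int, int]]) -> Optional[int]:
    best, best_ov = None, 0
    for i, (s, e) in enumerate(intervals):
        ov = min(read.reference_end, e) - max(read.reference_start, s)
        if ov > best_ov:
            best, best_ov = i, ov
    return best


# ---------------------------------------------------------------------------
# final read labelling
# ---------------------------------------------------------------------------

def label_reads(
    reads: Sequence[MethylRead],
    tumor_variants: Sequence[VariantRecord],
    all_copies_variants: Sequence[VariantRecord],
    loh_labels: Sequence[LabeledRead] = (),
) -> list[LabeledRead]:
    """Combine SNV-carrier, missing-all-copies and LOH evidence per read.

    A read carrying a retained tumor-label SNV alt base is tumor; a
    haplotype-matched read covering an all-copies variant without its alt is
    non-tumor; LOH labels are unioned in.  Reads with conflicting evidence
    are excluded (logged).
    """
    tumor_by_key = {v.key: v for v in tumor_variants}
    allcopies_by_key = {v.key: v for v in all_copies_variants}
    votes: dict[str, dict[str, str]] = {}  # read_id -> {label: evidence-locus}

    def vote(read_id: str, label: str, evidence: str, locus: str) -> None:
        votes.setdefault(read_id, {}).setdefault(label, f"{evidence}@{locus}")

    for read in reads:
        for pos, base in read.variant_observations:
            key = (read.chromosome, pos)
            tv = tumor_by_key.get(key)
            if tv is not None and base == tv.alt:
                vote(read.read_id, "tumor", "snv_carrier", f"{read.chromosome}:{pos}")
            av = allcopies_by_key.get(key)
            if (
                av is not None
                and base != av.alt
                and read.haplotype is not None
                and read.haplotype == av.haplotype_of_alt
            ):
                vote(read.read_id, "non_tumor", "missing_all_copies_snv", f"{read.chromosome}:{pos}")
    for lab in loh_labels:
        vote(lab.read_id, lab.label, lab.evidence, lab.locus)

    out: list[LabeledRead] = []
    n_conflicts = 0
    for read_id, v in votes.items():
        if len(v) > 1:
            n_conflicts += 1
            continue
        label, ev = next(iter(v.items()))
        evidence, _, locus = ev.partition("@")
        out.append(LabeledRead(read_id=read_id, label=label, evidence=evidence, locus=locus))
    if n_conflicts:
        logger.info("excluded %d reads with conflicting tumor/non-tumor evidence", n_conflicts)
    return out


def run_labeling(
    reads: Sequence[MethylRead],
    variants: Sequence[VariantRecord],
    segments: Sequence[CopyNumberSegment],
    clusters: ClusterModel,
    purity: SamplePurity,
    config: LabelingConfig | None = None,
) -> list[LabeledRead]:
    """End-to-end labelling: variant filters, all-copies selection, LOH, union."""
    cfg = config or LabelingConfig()
    tumor_vars = filter_tumor_label_variants(variants, reads, segments, clusters, purity, cfg)
    all_copies = select_all_copies_variants(tumor_vars, reads, segments, clusters, purity, cfg)
    loh = label_non_tumor_by_loh(reads, segments, purity, cfg)
    return label_reads(reads, tumor_vars, all_copies, loh)
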