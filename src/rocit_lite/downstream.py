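"""Genome-wide application of a trained model and the downstream validations:
expected-vs-observed tumor fraction per copy-number state, SNV rescue from
short-read candidate calls, and flagging of suspect long-read somatic calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import CopyNumberSegment, MethylRead, SamplePurity, VariantRecord

TRAINING_ADJACENT_CHROMOSOMES = frozenset(
    {"chr4", "chr21", "4", "21"}
)  # validation pair; excluded with test flag off


def expected_tumor_fraction(rho: float, n_total: int, n_normal: int = 2) -> float:
    """Expected share of tumor-derived reads in a segment:
    rho N_Total / (rho N_Total + (1 - rho) N_Normal)."""
    denom = rho * n_total + (1.0 - rho) * n_normal
    if denom <= 0:
        raise ValueError("rho*N_Total + (1-rho)*N_Normal must be positive")
    return rho * n_total / denom


@dataclass
class SegmentTumorFraction:
    segment: CopyNumberSegment
    f_expected: float
    f_observed: float
    n_reads: int


def _assign_to_segments(reads: Sequence[MethylRead], segments: Sequence[CopyNumberSegment]):
    """Max-overlap segment index per read (-1 when no overlap)."""
    out = np.full(len(reads), -1, dtype=np.int64)
    for i, r in enumerate(reads):
        best, best_ov = -1, 0
        for j, s in enumerate(segments):
            ov = s.overlap(r.chromosome, r.reference_start, r.reference_end)
            if ov > best_ov:
                best, best_ov = j, ov
        out[i] = best
    return out


def observed_vs_expected(
    reads: Sequence[MethylRead],
    tumor_calls: dict[str, bool],
    segments: Sequence[CopyNumberSegment],
    purity: SamplePurity,
    exclude_chromosomes: frozenset = frozenset(),
    min_reads_per_segment: int = 20,
) -> tuple[list[SegmentTumorFraction], float]:
    """Per-segment observed tumor-call fraction vs the copy-number expectation.

    Reads are attributed to segments by maximum overlap; segments with too
    few classified reads are omitted.  The returned Pearson r is computed
    across total-copy-number states (segment fractions pooled per state,
    read-weighted), mirroring how discrete copy-number states structure the
    expectation.
    """
    use = [r for r in reads if r.chromosome not in exclude_chromosomes and r.read_id in tumor_calls]
    seg_idx = _assign_to_segments(use, segments)
    fractions: list[SegmentTumorFraction] = []
    per_state: dict[int, list[tuple[float, float, int]]] = {}
    for j, seg in enumerate(segments):
        mask = seg_idx == j
        n = int(mask.sum())
        if n < min_reads_per_segment:
            continue
        called = np.array([tumor_calls[use[i].read_id] for i in np.flatnonzero(mask)])
        f_obs = float(called.mean())
        f_exp = expected_tumor_fraction(purity.rho, seg.n_total, seg.n_normal)
        fractions.append(SegmentTumorFraction(seg, f_exp, f_obs, n))
        per_state.setdefault(seg.n_total, []).append((f_exp, f_obs, n))
    if len(per_state) >= 2:
        exp_s, obs_s = [], []
        for state, rows in sorted(per_state.items()):
            w = np.array([n for _, _, n in rows], dtype=float)
            exp_s.append(np.average([e for e, _, _ in rows], weights=w))
            obs_s.append(np.average([o for _, o, _ in rows], weights=w))
        if np.ptp(exp_s) == 0 or np.ptp(obs_s) == 0:
            r = float("nan")  # degenerate: correlation undefined
        else:
            r = float(stats.pearsonr(exp_s, obs_s)[0])
    else:
        r = float("nan")
    return fractions, r


# ---------------------------------------------------------------------------
# SNV rescue cohort
# ---------------------------------------------------------------------------

@dataclass
class SNVRescueRecord:
    variant: VariantRecord
    supporting_read_ids: list[str]
    cohort: str  # "test" (short-read PASS) or "control" (short-read FAIL)

    @property
    def n_variant_reads(self) -> int:
        return len(self.supporting_read_ids)


MIN_RESCUE_READS = 10
LONG_READ_EXCLUSION_BP = 100


def build_rescue_cohort(
    short_read_snvs: Sequence[VariantRecord],
    long_read_pass_snvs: Sequence[VariantRecord],
    reads: Sequence[MethylRead],
    normal_reads: Sequence[MethylRead] = (),
) -> list[SNVRescueRecord]:
    """Candidate SNVs for rescue: short-read calls absent from the long-read
    call set, with >= 10 alt-carrying long reads in the tumor biopsy, none in
    the adjacent normal, and > 100 bp from any long-read PASS variant.

    Short-read PASS candidates form the test cohort; FAIL the control.
    """
    lr_pos: dict[str, np.ndarray] = {}
    lr_keys = set()
    for v in long_read_pass_snvs:
        if v.caller_status.get("long_read", "PASS") == "PASS":
            lr_pos.setdefault(v.chromosome, []).append(v.position)
            lr_keys.add(v.key)
    lr_pos = {c: np.sort(np.asarray(p)) for c, p in lr_pos.items()}

    def near_long_read(chrom, pos):
        arr = lr_pos.get(chrom)
        if arr is None or not len(arr):
            return False
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) <= LONG_READ_EXCLUSION_BP:
                return True
        return False

    support: dict[tuple[str, int], list[str]] = {}
    normal_support: dict[tuple[str, int], int] = {}
    wanted = {v.key: v.alt for v in short_read_snvs}
    for r in reads:
        for pos, base in r.variant_observations:
            key = (r.chromosome, pos)
            if key in wanted and base == wanted[key]:
                support.setdefault(key, []).append(r.read_id)
    for r in normal_reads:
        for pos, base in r.variant_observations:
            key = (r.chromosome, pos)
            if key in wanted and base == wanted[key]:
                normal_support[key] = normal_support.get(key, 0) + 1

    out: list[SNVRescueRecord] = []
    for v in short_read_snvs:
        if v.key in lr_keys:
            continue
        if near_long_read(v.chromosome, v.position):
            continue
        ids = support.get(v.key, [])
        if len(ids) < MIN_RESCUE_READS:
            continue
        if normal_support.get(v.key, 0) > 0:
            continue
        cohort = "test" if v.caller_status.get("short_read", "FAIL") == "PASS" else "control"
        out.append(SNVRescueRecord(v, ids, cohort))
    return out


def tumor_read_proportion(
    record: SNVRescueRecord,
    probabilities: dict[str, float],
    hard_calls: bool = True,
    threshold: float = 0.5,
) -> float:
    """Proportion of a variant's supporting reads identified as tumor."""
    ps = np.array([probabilities[rid] for rid in record.supporting_read_ids if rid in probabilities])
    if not len(ps):
        return float("nan")
    return float((ps >= threshold).mean()) if hard_calls else float(ps.mean())


def compare_cohorts(
    records: Sequence[SNVRescueRecord],
    probabilities: dict[str, float],
    hard_calls: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-variant tumor-read proportions per cohort and the two-sided
    Mann-Whitney U p-value between them."""
    test = np.array([
        tumor_read_proportion(r, probabilities, hard_calls) for r in records if r.cohort == "test"
    ])
    control = np.array([
        tumor_read_proportion(r, probabilities, hard_calls) for r in records if r.cohort == "control"
    ])
    test, control = test[~np.isnan(test)], control[~np.isnan(control)]
    if not len(test) or not len(control):
        return test, control, float("nan")
    p = float(stats.mannwhitneyu(test, control, alternative="two-sided").pvalue)
    return test, control, p


def flag_suspect_somatic_calls(
    long_read_snvs: Sequence[VariantRecord],
    reads: Sequence[MethylRead],
    probabilities: dict[str, float],
    threshold: float = 0.5,
    exclude_training_chromosomes: bool = True,
    training_chromosomes: frozenset = frozenset(),
) -> list[tuple[VariantRecord, float, int]]:
    """Flag long-read PASS SNVs whose supporting reads look non-tumor.

    Returns (variant, mean tumor probability of alt reads, n alt reads) for
    variants below ``threshold``.  Chromosomes used in training/validation
    can be excluded.
    """
    support: dict[tuple[str, int], list[float]] = {}
    wanted = {
        v.key: v.alt
        for v in long_read_snvs
        if v.caller_status.get("long_read", "PASS") == "PASS"
    }
    for r in reads:
        if r.read_id not in probabilities:
            continue
        for pos, base in r.variant_observations:
            key = (r.chromosome, pos)
            if key in wanted and base == wanted[key]:
                support.setdefault(key, []).append(probabilities[r.read_id])
    flagged = []
    for v in long_read_snvs:
        if v.key not in wanted or v.key not in support:
            continue
        if exclude_training_chromosomes and v.chromosome in training_chromosomes:
            continue
        ps = support[v.key]
        mean_p = float(np.mean(ps))
        if mean_p < threshold:
            flagged.append((v, mean_p, len(ps)))
    return flagged
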