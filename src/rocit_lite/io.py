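"""Readers and writers for every external format the pipeline touches.

BAM/SAM with MM/ML (plus HP/PS) tags via pysam, VCF 4.2 for variants,
header-carrying TSVs for copy-number segments, subclonal clusters and the
cell-type methylation atlas, and a compressed npz container for the internal
read table.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    N_PERCENTILES,
    PERCENTILE_GRID,
    CellTypeAtlas,
    Cluster,
    ClusterModel,
    CopyNumberSegment,
    MethylRead,
    SampleSiteDistribution,
    VariantRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# methylation probability scaling
# ---------------------------------------------------------------------------

def scale_methylation(m_raw):
    """Map the caller's 0-255 binned probability to the midpoint of its bin.

    A stored value of M encodes a probability in [M/256, (M+1)/256); the
    midpoint (M + 0.5)/256 is used throughout the pipeline.  Accepts scalars
    or arrays; values outside [0, 255] raise.
    """
    arr = np.asarray(m_raw)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("raw methylation values must lie in [0, 255]")
    out = (arr.astype(np.float64) + 0.5) / 256.0
    if np.isscalar(m_raw) or arr.ndim == 0:
        return float(out)
    return out


def quantize_methylation(prob):
    """Inverse of :func:`scale_methylation`: probability -> 0-255 bin index."""
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    return np.clip(np.floor(arr * 256.0), 0, 255).astype(np.int64)


# ---------------------------------------------------------------------------
# BAM / SAM
# ---------------------------------------------------------------------------

def _cpg_calls_for_alignment(aln) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Extract (reference_position_of_forward_C, raw_0_255) for CpG 5mC calls.

    Calls without a reference coordinate (insertions, soft-clipped bases) are
    dropped.  Reverse-strand C calls are mapped onto the forward-strand C of
    the symmetric CpG (one coordinate per site).
    """
    try:
        mods = aln.modified_bases
    except Exception:
        return None
    if not mods:
        return None
    calls: dict[int, int] = {}
    qpos_to_ref = dict(
        (q, r) for q, r in aln.get_aligned_pairs(matches_only=True)
    )
    for (canonical, strand, mod), entries in mods.items():
        if canonical != "C" or mod != "m":
            continue
        for qpos, qual in entries:
            ref = qpos_to_ref.get(qpos)
            if ref is None:
                continue
            # bottom-strand call sits on the G; shift to the forward C
            site = ref - 1 if strand == 1 else ref
            if site < 0:
                continue
            calls[site] = max(calls.get(site, 0), int(qual))
    if not calls:
        return None
    pos = np.array(sorted(calls), dtype=np.int64)
    raw = np.array([calls[p] for p in pos], dtype=np.int64)
    return pos, raw


def load_reads(
    bam_path: str,
    min_mapq: int = 0,
    include_supplementary: bool = False,
    variant_loci: Optional[dict[str, Sequence[int]]] = None,
) -> list[MethylRead]:
    """Load one :class:`MethylRead` per primary alignment with CpG calls.

    Reads lacking MM/ML tags are skipped with a logged count; secondary
    alignments (and supplementary unless requested) are excluded.
    ``variant_loci`` maps chromosome -> 0-based positions whose observed base
    should be recorded on each overlapping read.
    """
    loci = {
        c: np.asarray(sorted(p), dtype=np.int64) for c, p in (variant_loci or {}).items()
    }
    reads: list[MethylRead] = []
    n_skipped_tags = 0
    with pysam.AlignmentFile(bam_path, check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.is_supplementary and not include_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            calls = _cpg_calls_for_alignment(aln)
            if calls is None:
                n_skipped_tags += 1
                continue
            pos, raw = calls
            hp = aln.get_tag("HP") if aln.has_tag("HP") else None
            ps = str(aln.get_tag("PS")) if aln.has_tag("PS") else None
            obs: list[tuple[int, str]] = []
            chrom_loci = loci.get(aln.reference_name)
            if chrom_loci is not None and len(chrom_loci):
                lo = np.searchsorted(chrom_loci, aln.reference_start)
                hi = np.searchsorted(chrom_loci, aln.reference_end)
                if hi > lo:
                    wanted = set(chrom_loci[lo:hi].tolist())
                    seq = aln.query_sequence
                    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                        if rpos in wanted and seq is not None:
                            obs.append((int(rpos), seq[qpos]))
            reads.append(
                MethylRead(
                    read_id=aln.query_name,
                    chromosome=aln.reference_name,
                    cpg_positions=pos,
                    meth_raw=raw,
                    meth_prob=scale_methylation(raw),
                    haplotype=int(hp) if hp is not None else None,
                    phase_block_id=ps,
                    variant_observations=obs,
                    reference_start=aln.reference_start,
                    reference_end=aln.reference_end,
                )
            )
    if n_skipped_tags:
        logger.info("skipped %d alignments without usable MM/ML CpG calls", n_skipped_tags)
    return reads


def write_sam(
    path: str,
    reads: Iterable[MethylRead],
    chrom_lengths: dict[str, int],
    variant_bases: Optional[dict[str, dict[int, dict[str, str]]]] = None,
) -> None:
    """Write reads as a text SAM with MM/ML (and HP/PS) tags.

    Reads carry a synthetic sequence: 'A' background with 'CG' at CpG sites,
    so the MM skip counts round-trip through standards-compliant parsers.
    ``variant_bases`` maps chromosome -> position -> {read_id: base} to plant
    observed variant bases.
    """
    names = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in names],
    }
    tid = {c: i for i, c in enumerate(names)}
    vb = variant_bases or {}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            start = int(read.reference_start)
            end = int(read.reference_end)
            length = end - start
            seq = np.full(length, ord("A"), dtype=np.uint8)
            offs = read.cpg_positions - start
            seq[offs] = ord("C")
            g = offs + 1
            seq[g[g < length]] = ord("G")
            for pos, base_by_read in vb.get(read.chromosome, {}).items():
                if start <= pos < end and read.read_id in base_by_read:
                    seq[pos - start] = ord(base_by_read[read.read_id])
            aln = pysam.AlignedSegment()
            aln.query_name = read.read_id
            aln.query_sequence = seq.tobytes().decode()
            aln.flag = 0
            aln.reference_id = tid[read.chromosome]
            aln.reference_start = start
            aln.mapping_quality = 60
            aln.cigartuples = [(0, length)]
            # skip counts over C bases in the query for "C+m"
            c_offsets = np.flatnonzero(seq == ord("C"))
            is_meth = np.isin(c_offsets, offs)
            skips = []
            since = 0
            for k, o in enumerate(c_offsets):
                if is_meth[k]:
                    skips.append(since)
                    since = 0
                else:
                    since += 1
            mm = "C+m?," + ",".join(str(s) for s in skips) + ";"
            aln.set_tag("MM", mm)
            aln.set_tag("ML", array_to_ml(read.meth_raw))
            if read.haplotype is not None:
                aln.set_tag("HP", int(read.haplotype))
            if read.phase_block_id is not None:
                aln.set_tag("PS", int(read.phase_block_id) if str(read.phase_block_id).isdigit() else read.phase_block_id)
            out.write(aln)


def array_to_ml(raw: np.ndarray):
    import array

    return array.array("B", [int(v) for v in raw])


# ---------------------------------------------------------------------------
# internal read table (npz)
# ---------------------------------------------------------------------------

def write_reads_npz(path: str, reads: Sequence[MethylRead]) -> None:
    n = len(reads)
    counts = np.array([r.n_cpg for r in reads], dtype=np.int64)
    obs_read, obs_pos, obs_base = [], [], []
    for i, r in enumerate(reads):
        for pos, base in r.variant_observations:
            obs_read.append(i)
            obs_pos.append(pos)
            obs_base.append(base)
    np.savez_compressed(
        path,
        read_id=np.array([r.read_id for r in reads]),
        chromosome=np.array([r.chromosome for r in reads]),
        haplotype=np.array([r.haplotype or 0 for r in reads], dtype=np.int8),
        phase_block=np.array([r.phase_block_id or "" for r in reads]),
        ref_start=np.array([r.reference_start for r in reads], dtype=np.int64),
        ref_end=np.array([r.reference_end for r in reads], dtype=np.int64),
        counts=counts,
        cpg_positions=np.concatenate([r.cpg_positions for r in reads]) if n else np.empty(0, np.int64),
        meth_raw=np.concatenate([r.meth_raw for r in reads]) if n else np.empty(0, np.int64),
        obs_read=np.array(obs_read, dtype=np.int64),
        obs_pos=np.array(obs_pos, dtype=np.int64),
        obs_base=np.array(obs_base),
    )


def load_reads_npz(path: str) -> list[MethylRead]:
    with np.load(path, allow_pickle=False) as z:
        # materialize once: indexing the lazy handle re-decompresses per access
        d = {k: z[k] for k in z.files}
    counts = d["counts"]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    obs: dict[int, list[tuple[int, str]]] = {}
    for i, pos, base in zip(d["obs_read"], d["obs_pos"], d["obs_base"]):
        obs.setdefault(int(i), []).append((int(pos), str(base)))
    reads = []
    for i in range(len(counts)):
        raw = d["meth_raw"][offsets[i]: offsets[i + 1]]
        hap = int(d["haplotype"][i])
        ps = str(d["phase_block"][i])
        reads.append(
            MethylRead(
                read_id=str(d["read_id"][i]),
                chromosome=str(d["chromosome"][i]),
                cpg_positions=d["cpg_positions"][offsets[i]: offsets[i + 1]],
                meth_raw=raw,
                meth_prob=scale_methylation(raw),
                haplotype=hap if hap else None,
                phase_block_id=ps if ps else None,
                variant_observations=obs.get(i, []),
                reference_start=int(d["ref_start"][i]),
                reference_end=int(d["ref_end"][i]),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# sample site distribution
# ---------------------------------------------------------------------------

def compute_site_distribution(reads: Sequence[MethylRead]) -> SampleSiteDistribution:
    """19 percentiles (5%..95%) of meth_prob per CpG site across all reads.

    Linear interpolation between closest ranks; invariant to read order.
    """
    if not reads:
        raise ValueError("need at least one read")
    by_chrom: dict[str, list[np.ndarray]] = {}
    probs_by_chrom: dict[str, list[np.ndarray]] = {}
    for r in reads:
        if r.n_cpg == 0:
            continue
        by_chrom.setdefault(r.chromosome, []).append(r.cpg_positions)
        probs_by_chrom.setdefault(r.chromosome, []).append(r.meth_prob)
    positions_by_chrom: dict[str, np.ndarray] = {}
    row_offset: dict[str, int] = {}
    blocks: list[np.ndarray] = []
    q = PERCENTILE_GRID / 100.0
    offset = 0
    for chrom in sorted(by_chrom):
        pos = np.concatenate(by_chrom[chrom])
        prob = np.concatenate(probs_by_chrom[chrom])
        order = np.lexsort((prob, pos))
        pos, prob = pos[order], prob[order]
        sites, starts, counts = np.unique(pos, return_index=True, return_counts=True)
        # vectorized linear-interpolation percentiles per site group
        rank = q[None, :] * (counts[:, None] - 1)  # (n_sites, 19)
        lo = np.floor(rank).astype(np.int64)
        frac = (rank - lo).astype(np.float64)
        hi = np.minimum(lo + 1, counts[:, None] - 1)
        base = starts[:, None]
        pct = prob[base + lo] * (1 - frac) + prob[base + hi] * frac
        positions_by_chrom[chrom] = sites
        row_offset[chrom] = offset
        offset += len(sites)
        blocks.append(pct.astype(np.float32))
    all_pct = np.concatenate(blocks) if blocks else np.empty((0, N_PERCENTILES), np.float32)
    return SampleSiteDistribution(positions_by_chrom, all_pct, row_offset)


# ---------------------------------------------------------------------------
# cell-type atlas
# ---------------------------------------------------------------------------

def load_atlas(path: str) -> CellTypeAtlas:
    """Load a TSV atlas: columns chrom, pos, then one column per cell type.

    Columns named ``<cell_type>.<replicate>`` are mean-averaged into one
    cell-type column, ignoring missing values.  Values outside [0, 1] are a
    validation error; empty cells mean the site is missing for that column.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("atlas file needs chrom, pos and at least one cell-type column")
    chrom_col, pos_col = df.columns[0], df.columns[1]
    value_cols = list(df.columns[2:])
    groups: dict[str, list[str]] = {}
    for col in value_cols:
        label = col.rsplit(".", 1)[0] if "." in col else col
        groups.setdefault(label, []).append(col)
    names = list(groups)
    mat = np.full((len(df), len(names)), np.nan, dtype=np.float32)
    for j, label in enumerate(names):
        sub = df[groups[label]].to_numpy(dtype=np.float64)
        with np.errstate(invalid="ignore"):
            mat[:, j] = np.nanmean(sub, axis=1)
    finite = mat[np.isfinite(mat)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("atlas methylation values must lie in [0, 1]")
    return atlas_from_frame(df[chrom_col].astype(str), df[pos_col].to_numpy(np.int64), mat, names)


def atlas_from_frame(chroms, positions, values, names) -> CellTypeAtlas:
    order = np.lexsort((positions, np.asarray(chroms)))
    chroms = np.asarray(chroms)[order]
    positions = np.asarray(positions)[order]
    values = np.asarray(values)[order]
    positions_by_chrom: dict[str, np.ndarray] = {}
    row_offset: dict[str, int] = {}
    offset = 0
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        positions_by_chrom[str(chrom)] = positions[mask]
        row_offset[str(chrom)] = offset
        offset += int(mask.sum())
    return CellTypeAtlas(list(names), positions_by_chrom, values, row_offset)


def write_atlas(path: str, atlas: CellTypeAtlas) -> None:
    rows = []
    for chrom, pos in atlas.positions_by_chrom.items():
        off = atlas.row_offset[chrom]
        block = pd.DataFrame(atlas.values[off: off + len(pos)], columns=atlas.cell_type_names)
        block.insert(0, "pos", pos)
        block.insert(0, "chrom", chrom)
        rows.append(block)
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def convert_bedgraph_atlas(paths_by_cell_type: dict[str, str], out_path: str) -> None:
    """Merge per-cell-type bedGraph files (chrom, start, end, value) into the TSV dialect."""
    frames = []
    for name, p in paths_by_cell_type.items():
        df = pd.read_csv(p, sep="\t", header=None, names=["chrom", "pos", "end", name], usecols=[0, 1, 3])
        frames.append(df.set_index(["chrom", "pos"])[name])
    merged = pd.concat(frames, axis=1).reset_index()
    merged.to_csv(out_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segments / clusters / purity
# ---------------------------------------------------------------------------

def load_segments(path: str) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "n_total", "n_minor"}
    if not required.issubset(df.columns):
        raise ValueError(f"segment file must have columns {sorted(required)}")
    segs = []
    for i, row in df.iterrows():
        try:
            segs.append(
                CopyNumberSegment(
                    chromosome=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_total=int(row["n_total"]),
                    n_minor=int(row["n_minor"]),
                    n_normal=int(row["n_normal"]) if "n_normal" in df.columns else 2,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"segment file line {i + 2}: {exc}") from exc
    return segs


def write_segments(path: str, segments: Sequence[CopyNumberSegment]) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chromosome,
                "start": s.start,
                "end": s.end,
                "n_total": s.n_total,
                "n_minor": s.n_minor,
                "n_normal": s.n_normal,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def load_clusters(path: str) -> ClusterModel:
    df = pd.read_csv(path, sep="\t")
    required = {"cluster_id", "ccf", "n_variants"}
    if not required.issubset(df.columns):
        raise ValueError(f"cluster file must have columns {sorted(required)}")
    clusters = []
    for i, row in df.iterrows():
        try:
            clusters.append(Cluster(int(row["cluster_id"]), float(row["ccf"]), int(row["n_variants"])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cluster file line {i + 2}: {exc}") from exc
    return ClusterModel(clusters)


def write_clusters(path: str, clusters: ClusterModel) -> None:
    pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "ccf": c.ccf, "n_variants": c.n_assigned_variants}
            for c in clusters.clusters
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alt-supporting long reads">
##INFO=<ID=TOTC,Number=1,Type=Integer,Description="Total long reads at site">
##INFO=<ID=LRS,Number=1,Type=String,Description="Long-read caller status">
##INFO=<ID=SRS,Number=1,Type=String,Description="Short-read caller status">
##INFO=<ID=SRGERM,Number=0,Type=Flag,Description="Flagged germline by short-read caller">
"""


def load_variants(vcf_path: str) -> list[VariantRecord]:
    """Load SNVs from a VCF; multi-allelic rows are split, non-SNVs dropped.

    Positions are converted to 0-based.  Caller statuses are read from the
    LRS/SRS INFO keys when present, else derived from FILTER.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    continue
                # undeclared INFO keys make pysam raise rather than default
                info = {k: v for k, v in rec.info.items()}
                filt = list(rec.filter.keys())
                default = "PASS" if (not filt or filt == ["PASS"]) else "FAIL"
                status = {
                    "long_read": str(info.get("LRS", default)),
                    "short_read": str(info.get("SRS", default)),
                }
                if "SRGERM" in info:
                    status["short_read_germline"] = "FLAGGED"
                out.append(
                    VariantRecord(
                        chromosome=rec.chrom,
                        position=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        alt_read_count=int(info.get("ALTC", 0)),
                        total_read_count=max(int(info.get("TOTC", 0)), int(info.get("ALTC", 0))),
                        caller_status=status,
                    )
                )
    return out


def write_variants(vcf_path: str, variants: Sequence[VariantRecord], chrom_lengths: dict[str, int]) -> None:
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (x.chromosome, x.position)):
            info = (
                f"ALTC={v.alt_read_count};TOTC={v.total_read_count}"
                f";LRS={v.caller_status.get('long_read', 'PASS')}"
                f";SRS={v.caller_status.get('short_read', 'PASS')}"
            )
            if v.caller_status.get("short_read_germline") == "FLAGGED":
                info += ";SRGERM"
            filt = "PASS" if v.caller_status.get("long_read", "PASS") == "PASS" else "FAIL"
            fh.write(
                f"{v.chromosome}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\n"
            )
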