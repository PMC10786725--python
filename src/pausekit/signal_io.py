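"""Fragment and peak I/O, window counting, densities, metagene profiles.

Aligned ChIP fragments enter as BED intervals (the canonical path) or via
an optional BAM adapter; counting assigns each fragment to a window by its
midpoint (default) so that a fragment straddling the promoter/body
boundary is never counted twice, or by any-overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "PeakSet",
    "CountVector",
    "load_fragments",
    "write_fragments_bed",
    "load_peaks",
    "count_fragments",
    "density",
    "cpm_normalize",
    "metagene_profile",
]


@dataclass
class FragmentSet:
    """Aligned fragments for one sample (0-based half-open intervals)."""

    sample_id: str
    fragments: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        f = self.fragments
        if len(f) and not (f["start"] < f["end"]).all():
            raise ValueError("fragments must satisfy start < end")

    @property
    def library_size(self) -> int:
        return len(self.fragments)


@dataclass
class PeakSet:
    """Called peak intervals for one sample, sorted within chromosome."""

    sample_id: str
    peaks: pd.DataFrame  # columns chrom, start, end [, score]

    def __post_init__(self) -> None:
        self.peaks = (
            self.peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )


@dataclass
class CountVector:
    """Per-region fragment counts for one sample."""

    sample_id: str
    table: pd.DataFrame  # columns region_id, length, count

    @property
    def counts(self) -> pd.Series:
        return self.table.set_index("region_id")["count"]


def load_fragments(
    path: str,
    format: str = "bed",
    sample_id: str | None = None,
    single_end_extension_bp: int = 200,
) -> FragmentSet:
    """Read fragments from BED (canonical) or BAM (optional adapter).

    BAM: properly paired reads are collapsed to template-span fragments;
    single-end reads are extended to ``single_end_extension_bp`` in the
    read orientation.  Unmapped or zero-length records are skipped with a
    logged count.
    """
    sample_id = sample_id or path
    if format == "bed":
        rows = []
        n_skipped = 0
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: unparseable BED line {lineno}")
                start, end = int(fields[1]), int(fields[2])
                if end <= start:
                    n_skipped += 1
                    continue
                rows.append((fields[0], start, end))
        if n_skipped:
            logger.info("%s: skipped %d zero-length records", path, n_skipped)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return FragmentSet(sample_id, df)
    if format == "bam":
        return _load_bam(path, sample_id, single_end_extension_bp)
    raise ValueError(f"unknown fragment format {format!r}")


def _load_bam(path: str, sample_id: str, ext: int) -> FragmentSet:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional adapter
        raise ImportError("BAM input requires pysam (pip install pausekit[bam])") from exc
    rows = []
    n_skipped = 0
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_skipped += 1
                continue
            if read.is_paired:
                # count each template once, from the leftmost mate
                if not read.is_proper_pair or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                if read.is_reverse:
                    end = read.reference_end
                    start = end - ext
                else:
                    start = read.reference_start
                    end = start + ext
            if end <= start:
                n_skipped += 1
                continue
            rows.append((read.reference_name, max(0, start), end))
    if n_skipped:
        logger.info("%s: skipped %d unmapped/invalid records", path, n_skipped)
    return FragmentSet(sample_id, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def write_fragments_bed(frags: FragmentSet, path: str) -> None:
    frags.fragments.to_csv(path, sep="\t", header=False, index=False)


def load_peaks(path: str, sample_id: str | None = None) -> PeakSet:
    """Read narrowPeak/BED peak calls (first three columns used)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: unparseable peak line {lineno}")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(sample_id or path, df)


def _regions_disjoint(starts: np.ndarray, ends: np.ndarray) -> bool:
    return bool(np.all(starts[1:] >= ends[:-1]))


def count_fragments(
    frags: FragmentSet,
    regions: pd.DataFrame,
    rule: str = "midpoint",
) -> CountVector:
    """Count fragments per region.

    midpoint — a fragment is assigned to the region containing
    floor((start+end)/2); with disjoint regions each fragment is counted
    at most once.  any_overlap — a fragment is counted in every region it
    overlaps by ≥1 bp.
    """
    if regions.empty:
        raise ValueError("regions must be non-empty")
    if rule not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown counting rule {rule!r}")

    counts = np.zeros(len(regions), dtype=np.int64)
    region_pos = {rid: i for i, rid in enumerate(regions["region_id"])}
    frag_by_chrom = dict(tuple(frags.fragments.groupby("chrom", sort=False)))

    for chrom, reg in regions.groupby("chrom", sort=False):
        fr = frag_by_chrom.get(chrom)
        if fr is None or fr.empty:
            logger.warning("no fragments on %s; zero counts", chrom)
            continue
        order = np.argsort(reg["start"].to_numpy(), kind="stable")
        starts = reg["start"].to_numpy()[order]
        ends = reg["end"].to_numpy()[order]
        ids = reg["region_id"].to_numpy()[order]
        fs = fr["start"].to_numpy()
        fe = fr["end"].to_numpy()
        if rule == "midpoint":
            mids = (fs + fe) // 2
            if _regions_disjoint(starts, ends):
                idx = np.searchsorted(starts, mids, side="right") - 1
                ok = idx >= 0
                ok[ok] &= mids[ok] < ends[idx[ok]]
                hit = np.bincount(idx[ok], minlength=len(starts))
                for i, rid in enumerate(ids):
                    counts[region_pos[rid]] += hit[i]
            else:
                tree = IntervalTree.from_tuples(
                    (s, e, rid) for s, e, rid in zip(starts, ends, ids)
                )
                for m in mids:
                    for iv in tree.at(int(m)):
                        counts[region_pos[iv.data]] += 1
        else:
            tree = IntervalTree.from_tuples(
                (s, e, rid) for s, e, rid in zip(starts, ends, ids)
            )
            for s, e in zip(fs, fe):
                for iv in tree.overlap(int(s), int(e)):
                    counts[region_pos[iv.data]] += 1

    table = pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy(),
            "length": (regions["end"] - regions["start"]).to_numpy(),
            "count": counts,
        }
    )
    if (table["length"] <= 0).any():
        raise ValueError("regions must have positive length")
    return CountVector(frags.sample_id, table)


def density(counts: CountVector, pseudocount: float = 0.0) -> pd.Series:
    """Per-region per-bp density: (count + pseudocount) / length."""
    t = counts.table
    d = (t["count"] + pseudocount) / t["length"]
    d.index = t["region_id"]
    return d


def cpm_normalize(counts: CountVector, library_size: int | None = None) -> pd.Series:
    """Counts per million fragments of library."""
    n = library_size if library_size is not None else int(counts.table["count"].sum())
    if n <= 0:
        raise ValueError("library size must be positive")
    c = counts.table["count"] * 1e6 / n
    c.index = counts.table["region_id"]
    return c


def metagene_profile(
    frags: FragmentSet,
    anchors: list[tuple[str, int, str]],
    flank_bp: int = 2000,
    bin_bp: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-oriented binned CPM coverage around anchor points.

    Returns (matrix anchors × bins, column mean).  Coverage is the number
    of fragments covering each bp, averaged per bin and scaled to CPM by
    the library size.  Rows whose window runs off the chromosome are
    zero-padded outside the chromosome (logged).
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    nbins = 2 * flank_bp // bin_bp
    lib = max(frags.library_size, 1)

    cov: dict[str, np.ndarray] = {}
    need = {}
    for chrom, pos, _ in anchors:
        need[chrom] = max(need.get(chrom, 0), pos + flank_bp)
    for chrom, group in frags.fragments.groupby("chrom", sort=False):
        length = max(int(group["end"].max()), need.get(chrom, 0)) + 1
        diff = np.zeros(length + 1, dtype=np.float64)
        np.add.at(diff, group["start"].to_numpy(), 1.0)
        np.add.at(diff, group["end"].to_numpy(), -1.0)
        cov[chrom] = np.cumsum(diff)[:-1]

    mat = np.zeros((len(anchors), nbins))
    for i, (chrom, pos, strand) in enumerate(anchors):
        c = cov.get(chrom)
        if c is None:
            logger.warning("anchor on %s has no fragment coverage", chrom)
            continue
        lo, hi = pos - flank_bp, pos + flank_bp
        window = np.zeros(2 * flank_bp)
        src_lo, src_hi = max(lo, 0), min(hi, len(c))
        if src_lo > lo or src_hi < hi:
            logger.info("anchor %s:%d window clipped; zero-padded", chrom, pos)
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = c[src_lo:src_hi]
        binned = window.reshape(nbins, bin_bp).mean(axis=1)
        if strand == "-":
            binned = binned[::-1]
        mat[i] = binned * 1e6 / lib
    return mat, mat.mean(axis=0)
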