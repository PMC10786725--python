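"""Gene models and analysis windows for RNAPII pausing quantification.

Parses gene annotations (GTF or BED12), keeps one transcript per gene
(the longest isoform), applies the exclusion filters used for pausing
analysis (short genes, genes too close to a neighbour), and constructs
the two kinds of analysis windows:

* pausing windows — a proximal-promoter window (50 bp upstream to 300 bp
  downstream of the TSS) paired with a gene-body window (300 bp downstream
  of the TSS to 3 kb past the TES), both strand-aware;
* differential-analysis promoters — symmetric ±300 bp windows around the
  TSS used for differential RNAPII enrichment.

All coordinates are 0-based half-open internally (BED convention); GTF
input (1-based inclusive) is converted on read.  The TSS of a minus-strand
gene is coordinate ``end - 1``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "WindowPair",
    "FilterReport",
    "load_annotation",
    "filter_genes",
    "make_pausing_windows",
    "make_diff_promoters",
    "promoter_regions",
    "body_regions",
    "write_bed12",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene represented by a single (longest) transcript.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    transcript span; ``tss``/``tes`` are the strand-aware 5'/3' ends.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def tss_boundary(self) -> int:
        """Half-open boundary coordinate of the 5' end.

        Equals ``start`` on + and ``end`` on -; symmetric windows around
        the TSS are centred here so both strands get equal lengths.
        """
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class WindowPair:
    """Promoter and gene-body analysis windows for one gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter: tuple[int, int]
    body: tuple[int, int]

    @property
    def promoter_length(self) -> int:
        return self.promoter[1] - self.promoter[0]

    @property
    def body_length(self) -> int:
        return self.body[1] - self.body[0]


@dataclass
class FilterReport:
    """Bookkeeping for gene-filter exclusions."""

    n_input: int = 0
    n_kept: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.excluded:
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["gene_id", "reason"])


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: str) -> list[GeneRecord]:
    # Transcript spans from 'transcript' features when present, otherwise
    # aggregated from exon features per transcript_id.
    spans: dict[tuple[str, str], list] = {}
    have_transcript_feature = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: unparseable GTF line {lineno}")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature not in ("transcript", "exon"):
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable GTF line {lineno}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: unknown strand {strand!r} at line {lineno}")
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                gid, tid = attr["gene_id"], attr["transcript_id"]
            except KeyError as exc:
                raise ValueError(
                    f"{path}: missing gene_id/transcript_id at line {lineno}"
                ) from exc
            key = (gid, tid)
            if feature == "transcript":
                have_transcript_feature = True
                spans[key] = [chrom, strand, start, end, True]
            else:
                rec = spans.get(key)
                if rec is None:
                    spans[key] = [chrom, strand, start, end, False]
                elif not rec[4]:  # do not let exons widen a transcript feature
                    rec[2] = min(rec[2], start)
                    rec[3] = max(rec[3], end)
    del have_transcript_feature
    return [
        GeneRecord(gid, tid, chrom, strand, start, end)
        for (gid, tid), (chrom, strand, start, end, _) in spans.items()
    ]


def _parse_bed12(path: str) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: unparseable BED line {lineno}")
            chrom, start_s, end_s, name, _, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable BED line {lineno}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: unknown strand {strand!r} at line {lineno}")
            gid, _, tid = name.partition("|")
            records.append(GeneRecord(gid, tid or name, chrom, strand, start, end))
    return records


def load_annotation(path: str, format: str = "gtf") -> list[GeneRecord]:
    """Load gene records, retaining the longest isoform per gene.

    Ties on length are broken by the lexicographically smallest
    transcript_id.  Returns records sorted by (chrom, start).
    """
    if format == "gtf":
        transcripts = _parse_gtf(path)
    elif format == "bed12":
        transcripts = _parse_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    by_gene: dict[str, GeneRecord] = {}
    n_dropped = 0
    for rec in sorted(transcripts, key=lambda r: (-r.length, r.transcript_id)):
        if rec.gene_id in by_gene:
            n_dropped += 1
        else:
            by_gene[rec.gene_id] = rec
    if n_dropped:
        logger.info("dropped %d shorter isoforms (multi_isoform_dropped)", n_dropped)
    return sorted(by_gene.values(), key=lambda r: (r.chrom, r.start, r.gene_id))


def filter_genes(
    genes: Iterable[GeneRecord],
    min_length_bp: int = 1000,
    min_gap_bp: int = 3000,
) -> tuple[list[GeneRecord], FilterReport]:
    """Apply the pausing-analysis gene filters.

    Genes shorter than ``min_length_bp`` are excluded (strict ``<``: a gene
    of exactly 1,000 bp is kept).  Among the remaining genes, any gene
    whose span lies closer than ``min_gap_bp`` to another gene's span on
    the same chromosome (either strand; overlap counts as distance 0) is
    excluded — both members of a violating pair.
    """
    genes = list(genes)
    report = FilterReport(n_input=len(genes))

    long_enough = []
    for g in genes:
        if g.length < min_length_bp:
            report.excluded.append((g.gene_id, "short_gene"))
        else:
            long_enough.append(g)

    proximal: set[str] = set()
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in long_enough:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end))
        # prefix running max of span ends lets the backward scan stop early
        max_end = []
        running = -(10**18)
        for g in chrom_genes:
            running = max(running, g.end)
            max_end.append(running)
        for j in range(1, len(chrom_genes)):
            gj = chrom_genes[j]
            i = j - 1
            while i >= 0 and gj.start - max_end[i] < min_gap_bp:
                gi = chrom_genes[i]
                if gj.start - gi.end < min_gap_bp:
                    proximal.add(gi.gene_id)
                    proximal.add(gj.gene_id)
                i -= 1

    kept = []
    for g in long_enough:
        if g.gene_id in proximal:
            report.excluded.append((g.gene_id, "proximal_pair"))
        else:
            kept.append(g)
    report.n_kept = len(kept)
    return kept, report


def _clip(start: int, end: int, chrom_size: int | None) -> tuple[int, int]:
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
        start = min(start, chrom_size)
    return start, end


def make_pausing_windows(
    genes: Iterable[GeneRecord],
    upstream_bp: int = 50,
    downstream_bp: int = 300,
    body_ext_bp: int = 3000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[WindowPair]:
    """Build promoter/gene-body window pairs for pausing indices.

    Plus strand: promoter [TSS-upstream, TSS+downstream), body
    [TSS+downstream, TES+body_ext).  Minus strand mirrored in the
    transcription direction.  Windows are clipped to [0, chrom_size) and
    genes whose body collapses to nothing after clipping are dropped.
    """
    chrom_sizes = chrom_sizes or {}
    out = []
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        if g.strand == "+":
            prom = (g.start - upstream_bp, g.start + downstream_bp)
            body = (g.start + downstream_bp, g.end + body_ext_bp)
        else:
            prom = (g.end - downstream_bp, g.end + upstream_bp)
            body = (g.start - body_ext_bp, g.end - downstream_bp)
        prom = _clip(*prom, size)
        body = _clip(*body, size)
        if body[1] - body[0] <= 0 or prom[1] - prom[0] <= 0:
            logger.info("dropping %s: window collapsed after clipping", g.gene_id)
            continue
        out.append(WindowPair(g.gene_id, g.chrom, g.strand, prom, body))
    return out


def make_diff_promoters(
    genes: Iterable[GeneRecord],
    halfwidth_bp: int = 300,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """±halfwidth windows around each TSS for differential enrichment.

    Returns a DataFrame with columns region_id, chrom, start, end, strand,
    one row per gene, clipped to chromosome bounds.
    """
    chrom_sizes = chrom_sizes or {}
    rows = []
    for g in genes:
        c = g.tss_boundary
        start, end = _clip(c - halfwidth_bp, c + halfwidth_bp, chrom_sizes.get(g.chrom))
        rows.append((g.gene_id, g.chrom, start, end, g.strand))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand"])


def promoter_regions(windows: Sequence[WindowPair]) -> pd.DataFrame:
    rows = [(w.gene_id, w.chrom, w.promoter[0], w.promoter[1]) for w in windows]
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def body_regions(windows: Sequence[WindowPair]) -> pd.DataFrame:
    rows = [(w.gene_id, w.chrom, w.body[0], w.body[1]) for w in windows]
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def write_bed12(genes: Iterable[GeneRecord], path: str) -> None:
    """Write gene records as BED12 (name encodes gene_id|transcript_id)."""
    with open(path, "w") as fh:
        for g in genes:
            block = f"{g.length},"
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        f"{g.gene_id}|{g.transcript_id}",
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        "1",
                        block,
                        "0,",
                    ]
                )
                + "\n"
            )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: bad chrom sizes line {lineno}")
            sizes[parts[0]] = int(parts[1])
    return sizes
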