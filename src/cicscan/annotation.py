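"""Peak loading, gene models, feature annotation and TSS profiles.

Each peak is assigned one genomic-feature category from the position of its
anchor (the narrowPeak summit when present and non-negative, otherwise the
interval midpoint) with fixed precedence

    Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > Distal Intergenic

plus a nearest gene by absolute distance to its TSS (signed strand-aware:
negative = upstream of the TSS).  The promoter window is -2000..+200 bp
around the TSS; Downstream extends 3,000 bp past the transcript end.  Both
are configurable.  UTR categories are only assigned when the annotation
provides UTR sub-features; otherwise they collapse into Exon.

Coordinates are 0-based half-open internally; GTF input/output uses the
1-based closed GTF convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CATEGORIES = (
    "Promoter",
    "5'UTR",
    "3'UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
)

PROMOTER_WINDOW = (-2000, 200)
DOWNSTREAM_EXTENT = 3000


# ---------------------------------------------------------------- peaks ----

@dataclass(frozen=True)
class PeakRecord:
    """One called peak, 0-based half-open; q_value is -log10(q) for the
    narrowPeak dialect, -1 when absent."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1  # offset from start; -1 = not called

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")

    @property
    def anchor(self) -> int:
        """Genomic anchor position: summit if called, else midpoint."""
        if self.summit >= 0:
            return self.start + self.summit
        return (self.start + self.end) // 2


class PeakParseError(ValueError):
    pass


def load_peaks(
    path: str, format: str = "narrowPeak", q_threshold: float | None = None
) -> list[PeakRecord]:
    """Load ENCODE narrowPeak (10 columns, qValue as -log10) or plain BED
    (3+ columns, column 5 as score, no q filter).

    ``q_threshold`` is a linear q-value (e.g. 0.05); narrowPeak records are
    kept when their -log10(q) column exceeds -log10(threshold).
    """
    fmt = format.lower()
    if fmt not in ("narrowpeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[PeakRecord] = []
    dropped = 0
    neglog_cut = -math.log10(q_threshold) if q_threshold is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if fmt == "narrowpeak":
                    if len(f) < 10:
                        raise ValueError(f"expected 10 columns, got {len(f)}")
                    rec = PeakRecord(
                        f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5],
                        float(f[6]), float(f[7]), float(f[8]), int(f[9]),
                    )
                else:
                    if len(f) < 3:
                        raise ValueError(f"expected 3+ columns, got {len(f)}")
                    name = f[3] if len(f) > 3 else f"peak_{lineno}"
                    score = float(f[4]) if len(f) > 4 else 0.0
                    rec = PeakRecord(f[0], int(f[1]), int(f[2]), name, score)
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
            if fmt == "narrowpeak" and neglog_cut is not None and rec.q_value <= neglog_cut:
                dropped += 1
                continue
            peaks.append(rec)
    if q_threshold is not None:
        logger.info("q < %g filter dropped %d of %d peaks", q_threshold, dropped, dropped + len(peaks))
        if not peaks:
            logger.warning("no peaks pass q < %g; downstream summaries will be empty", q_threshold)
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str) -> None:
    """Write peaks as 10-column ENCODE narrowPeak."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}"
                f"\t{p.signal:g}\t{p.p_value:g}\t{p.q_value:g}\t{p.summit}\n"
            )


# ---------------------------------------------------------- gene models ----

@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model, 0-based half-open, sorted exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty interval")
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside transcript")
        prev_end = -1
        for (s, e) in self.exons:
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: transcript start on +, end-1 on -."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(self, window: tuple[int, int] = PROMOTER_WINDOW) -> tuple[int, int]:
        """Strand-aware half-open promoter interval in reference coordinates.

        window = (upstream_offset, downstream_offset) relative to the TSS,
        e.g. (-2000, 200).  On the minus strand the window mirrors:
        TSS 10,000 with (-2000, 200) gives [9,800, 12,000).
        """
        up, down = window
        t = self.tss
        if self.strand == "+":
            return (t + up, t + down)
        return (t - down, t - up)

    def signed_tss_distance(self, pos: int) -> int:
        """Distance of a genomic position from the TSS, negative upstream."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def load_gene_models(path: str, format: str = "GTF") -> list[GeneModel]:
    """Load gene models from GTF (1-based closed) or BED12.

    When a gene carries several transcripts the longest is kept.  GTF rows
    of type ``five_prime_utr``/``three_prime_utr`` populate the UTR
    sub-features; without them UTR categories collapse into Exon.
    """
    fmt = format.upper()
    if fmt == "GTF":
        genes = _load_gtf(path)
    elif fmt == "BED12":
        genes = _load_bed12(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _load_gtf(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_gene: dict[str, GeneModel] = {}
    for t in db.features_of_type("transcript"):
        if t.strand not in "+-":
            raise ValueError(f"{path}: transcript {t.id}: unknown strand {t.strand!r}")
        gid = t.attributes.get("gene_id", [t.id])[0]

        def spans(ftype: str) -> tuple[tuple[int, int], ...]:
            # gffutils keeps GTF 1-based closed; convert to 0-based half-open
            return tuple(sorted((c.start - 1, c.end) for c in db.children(t, featuretype=ftype)))

        g = GeneModel(
            gid, t.seqid, t.strand, t.start - 1, t.end,
            spans("exon"), spans("five_prime_utr"), spans("three_prime_utr"),
        )
        prev = by_gene.get(gid)
        if prev is None or (g.end - g.start) > (prev.end - prev.start):
            by_gene[gid] = g
    return list(by_gene.values())


def _load_bed12(path: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise PeakParseError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(sorted((start + o, start + o + s) for o, s in zip(offsets, sizes)))
            g = GeneModel(name, chrom, strand, start, end, exons)
            prev = genes.get(name)
            if prev is None or (g.end - g.start) > (prev.end - prev.start):
                genes[name] = g
    return list(genes.values())


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "cicscan") -> None:
    """Write gene/transcript/exon rows in GTF (1-based closed) coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for ftype, (s, e) in [("gene", (g.start, g.end)), ("transcript", (g.start, g.end))]:
                fh.write(f"{g.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for (s, e) in g.exons or ((g.start, g.end),):
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


# ----------------------------------------------------------- annotation ----

@dataclass(frozen=True)
class PeakAnnotation:
    peak_name: str
    feature_category: str
    nearest_gene_id: str | None
    distance_to_tss: int | None  # signed, strand-aware; None when no genes


def _in(pos: int, iv: tuple[int, int]) -> bool:
    return iv[0] <= pos < iv[1]


def annotate_peak(
    peak: PeakRecord,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    downstream_extent: int = DOWNSTREAM_EXTENT,
) -> PeakAnnotation:
    """Assign a feature category and nearest gene to one peak.

    The category comes from the anchor position under the fixed precedence;
    the nearest gene minimises |signed distance to TSS| over all genes on
    the peak's chromosome (ties broken by lexicographic gene_id).
    """
    pos = peak.anchor
    chrom_genes = [g for g in genes if g.chrom == peak.chrom]
    if not chrom_genes:
        return PeakAnnotation(peak.name, "Distal Intergenic", None, None)

    nearest = min(chrom_genes, key=lambda g: (abs(g.signed_tss_distance(pos)), g.gene_id))
    dist = nearest.signed_tss_distance(pos)

    flags = {c: False for c in CATEGORIES}
    for g in chrom_genes:
        if _in(pos, g.promoter_window(promoter_window)):
            flags["Promoter"] = True
        if any(_in(pos, iv) for iv in g.utr5):
            flags["5'UTR"] = True
        if any(_in(pos, iv) for iv in g.utr3):
            flags["3'UTR"] = True
        in_exon = any(_in(pos, iv) for iv in g.exons)
        if in_exon:
            flags["Exon"] = True
        if _in(pos, (g.start, g.end)) and not in_exon and g.exons:
            flags["Intron"] = True
        elif _in(pos, (g.start, g.end)) and not g.exons:
            flags["Exon"] = True  # no exon structure: whole body counts as exonic
        if g.strand == "+":
            ds = (g.end, g.end + downstream_extent)
        else:
            ds = (g.start - downstream_extent, g.start)
        if _in(pos, ds):
            flags["Downstream"] = True
    for cat in CATEGORIES[:-1]:
        if flags[cat]:
            return PeakAnnotation(peak.name, cat, nearest.gene_id, dist)
    return PeakAnnotation(peak.name, "Distal Intergenic", nearest.gene_id, dist)


def annotate_peaks(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    downstream_extent: int = DOWNSTREAM_EXTENT,
) -> list[PeakAnnotation]:
    return [annotate_peak(p, genes, promoter_window, downstream_extent) for p in peaks]


def region_composition(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Percentage of peaks per feature category; percentages sum to 100."""
    if not annotations:
        raise ValueError("region_composition requires at least one annotation")
    n = len(annotations)
    comp = {c: 0 for c in CATEGORIES}
    for a in annotations:
        comp[a.feature_category] += 1
    return {c: 100.0 * k / n for c, k in comp.items()}


@dataclass(frozen=True)
class TssProfile:
    """Histogram of peak anchors by signed distance to the nearest TSS."""

    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]
    bin_width: int

    @property
    def total(self) -> int:
        return sum(self.counts)


def tss_profile(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    window: int = 3000,
    bin_width: int = 100,
) -> TssProfile:
    """Bin peak anchors by signed distance to their nearest TSS over
    [-window, +window); each peak contributes at most once."""
    if window % bin_width != 0:
        raise ValueError(f"bin_width {bin_width} does not divide window {window}")
    edges = tuple(range(-window, window + 1, bin_width))
    counts = np.zeros(len(edges) - 1, dtype=int)
    for p in peaks:
        ann = annotate_peak(p, genes)
        if ann.distance_to_tss is None:
            continue
        d = ann.distance_to_tss
        if -window <= d < window:
            counts[(d + window) // bin_width] += 1
    return TssProfile(edges, tuple(int(c) for c in counts), bin_width)


# ------------------------------------------------------------- writers ----

def write_annotations(annotations: Iterable[PeakAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak\tfeature_category\tnearest_gene\tdistance_to_tss\n")
        for a in annotations:
            gene = a.nearest_gene_id if a.nearest_gene_id is not None else "NA"
            dist = a.distance_to_tss if a.distance_to_tss is not None else "NA"
            fh.write(f"{a.peak_name}\t{a.feature_category}\t{gene}\t{dist}\n")


def write_composition(composition: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("feature_category\tpercent\n")
        for cat in CATEGORIES:
            fh.write(f"{cat}\t{composition.get(cat, 0.0):.6f}\n")


def write_profile(profile: TssProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, c in enumerate(profile.counts):
            fh.write(f"{profile.bin_edges[i]}\t{profile.bin_edges[i + 1]}\t{c}\n")
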