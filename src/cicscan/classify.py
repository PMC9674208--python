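"""Peak classification by motif content and ChIP-seq x RNA-seq integration.

Every peak is placed in exactly one of four categories from its two motif
presence flags (octamer_only, ggaa_only, both, neither), summarised as
counts, fractions of all loaded peaks, a Venn triple, per-category unique
nearest-gene rollups and per-category genomic-region composition.  Genes
whose strand-aware promoter window (-2000..+200 around the TSS by default)
carries a probe hit are then intersected with differentially expressed
genes (|log2FC| > 1.5 and FDR < 0.2 by default, both strict) to yield the
putative target list.

The fraction denominator is always the full set of loaded peaks (after any
q filter) and is reported alongside the fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import (
    CATEGORIES,
    GeneModel,
    PeakAnnotation,
    PeakRecord,
    PROMOTER_WINDOW,
)
from .motifs import MotifSet, default_motif_sets, extract_peak_sequences, scan_sequence

CATEGORY_ORDER = ("octamer_only", "ggaa_only", "both", "neither")

OCTAMER_SET = "CIC_octamer"
GGAA_SET = "GGAA_repeat"


@dataclass(frozen=True)
class PeakClassification:
    peak_name: str
    has_octamer: bool
    has_ggaa: bool

    @property
    def category(self) -> str:
        if self.has_octamer and self.has_ggaa:
            return "both"
        if self.has_octamer:
            return "octamer_only"
        if self.has_ggaa:
            return "ggaa_only"
        return "neither"


def classify_peaks(
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, object],
    motif_sets: Iterable[MotifSet] | None = None,
    both_strands: bool = False,
) -> list[PeakClassification]:
    """Scan each peak's extracted sequence and derive its 4-way category."""
    if motif_sets is None:
        motif_sets = default_motif_sets()
    motif_sets = list(motif_sets)
    seqs = extract_peak_sequences(genome, peaks)
    out = []
    for pk in peaks:
        res = scan_sequence(pk.name, seqs[pk.name], motif_sets, both_strands=both_strands)
        out.append(PeakClassification(pk.name, res.has(OCTAMER_SET), res.has(GGAA_SET)))
    return out


@dataclass
class ClassificationSummary:
    n_peaks: int
    counts: dict[str, int]
    fractions: dict[str, float]
    venn_peaks: tuple[int, int, int]  # (octamer-only, shared, ggaa-only)
    venn_genes: tuple[int, int, int]
    genes_per_category: dict[str, int]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    composition_per_category: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "n_peaks": self.n_peaks,
            "counts": self.counts,
            "fractions": self.fractions,
            "fraction_denominator": self.n_peaks,
            "venn_peaks": list(self.venn_peaks),
            "venn_genes": list(self.venn_genes),
            "genes_per_category": self.genes_per_category,
            "gene_sets": self.gene_sets,
            "composition_per_category": self.composition_per_category,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def summarize(
    classifications: Sequence[PeakClassification],
    annotations: Sequence[PeakAnnotation],
) -> ClassificationSummary:
    """Counts, fractions, Venn triples and per-category gene/region rollups.

    The two inputs must cover the same peak set; genes are rolled up through
    each peak's nearest-gene annotation, each unique gene counted once per
    category.
    """
    cls_names = {c.peak_name for c in classifications}
    ann_names = {a.peak_name for a in annotations}
    if cls_names != ann_names:
        raise ValueError(
            f"classification/annotation peak sets differ "
            f"({len(cls_names - ann_names)} only classified, "
            f"{len(ann_names - cls_names)} only annotated)"
        )
    ann_by_peak = {a.peak_name: a for a in annotations}
    n = len(classifications)
    counts = {c: 0 for c in CATEGORY_ORDER}
    genes: dict[str, set[str]] = {c: set() for c in CATEGORY_ORDER}
    cat_counts: dict[str, dict[str, int]] = {c: {f: 0 for f in CATEGORIES} for c in CATEGORY_ORDER}
    oct_genes: set[str] = set()
    ggaa_genes: set[str] = set()
    for c in classifications:
        cat = c.category
        counts[cat] += 1
        ann = ann_by_peak[c.peak_name]
        cat_counts[cat][ann.feature_category] += 1
        if ann.nearest_gene_id is not None:
            genes[cat].add(ann.nearest_gene_id)
            if c.has_octamer:
                oct_genes.add(ann.nearest_gene_id)
            if c.has_ggaa:
                ggaa_genes.add(ann.nearest_gene_id)
    fractions = {c: counts[c] / n if n else 0.0 for c in CATEGORY_ORDER}
    shared_genes = oct_genes & ggaa_genes
    composition = {
        cat: {
            f: (100.0 * k / counts[cat] if counts[cat] else 0.0)
            for f, k in cat_counts[cat].items()
        }
        for cat in CATEGORY_ORDER
    }
    return ClassificationSummary(
        n_peaks=n,
        counts=counts,
        fractions=fractions,
        venn_peaks=(counts["octamer_only"], counts["both"], counts["ggaa_only"]),
        venn_genes=(
            len(oct_genes - shared_genes),
            len(shared_genes),
            len(ggaa_genes - shared_genes),
        ),
        genes_per_category={c: len(genes[c]) for c in CATEGORY_ORDER},
        gene_sets={c: sorted(genes[c]) for c in CATEGORY_ORDER},
        composition_per_category=composition,
    )


# -------------------------------------------------- promoter motif scan ----

@dataclass(frozen=True)
class GeneMotifFlags:
    gene_id: str
    has_octamer: bool
    has_ggaa: bool

    @property
    def motif_classes(self) -> tuple[str, ...]:
        out = []
        if self.has_octamer:
            out.append("octamer")
        if self.has_ggaa:
            out.append("ggaa")
        return tuple(out)


def promoter_motif_search(
    genes: Sequence[GeneModel],
    genome: Mapping[str, object],
    motif_sets: Iterable[MotifSet] | None = None,
    window: tuple[int, int] = PROMOTER_WINDOW,
    annotations: Sequence[PeakAnnotation] | None = None,
    all_genes: bool = False,
    both_strands: bool = False,
) -> list[GeneMotifFlags]:
    """Scan each gene's strand-aware promoter window for both probe sets.

    By default only genes that are the nearest gene of at least one peak
    (per ``annotations``) are searched; pass ``all_genes=True`` to scan
    every gene.  Windows are clipped to chromosome bounds.  Only genes with
    at least one motif class present are returned.
    """
    if motif_sets is None:
        motif_sets = default_motif_sets()
    motif_sets = list(motif_sets)
    if not all_genes:
        if annotations is None:
            raise ValueError("annotations required unless all_genes=True")
        keep = {a.nearest_gene_id for a in annotations if a.nearest_gene_id is not None}
        genes = [g for g in genes if g.gene_id in keep]
    out: list[GeneMotifFlags] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom not in genome:
            continue
        record = genome[g.chrom]
        lo, hi = g.promoter_window(window)
        lo, hi = max(0, lo), min(len(record), hi)
        if lo >= hi:
            continue
        seq = str(record[lo:hi]).upper()
        res = scan_sequence(g.gene_id, seq, motif_sets, both_strands=both_strands)
        flags = GeneMotifFlags(g.gene_id, res.has(OCTAMER_SET), res.has(GGAA_SET))
        if flags.has_octamer or flags.has_ggaa:
            out.append(flags)
    return out


# --------------------------------------------------------- DE + targets ----

REQUIRED_DE_COLUMNS = ("gene_id", "log2fc", "fdr")


def load_de_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing column(s): {', '.join(missing)}")
    return df


def filter_degs(
    de_table: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.2
) -> set[str]:
    """Genes with |log2fc| > fc_threshold AND fdr < fdr_threshold (strict)."""
    missing = [c for c in REQUIRED_DE_COLUMNS if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing column(s): {', '.join(missing)}")
    mask = (de_table["log2fc"].abs() > fc_threshold) & (de_table["fdr"] < fdr_threshold)
    return set(de_table.loc[mask, "gene_id"])


@dataclass
class IntegrationResult:
    """Putative targets: promoter-motif genes intersected with DEGs."""

    motif_genes: list[GeneMotifFlags]
    deg_genes: set[str]
    putative_targets: pd.DataFrame  # gene_id, motif_classes, log2fc, fdr

    @property
    def target_ids(self) -> set[str]:
        return set(self.putative_targets["gene_id"])


def intersect_targets(
    motif_genes: Sequence[GeneMotifFlags],
    deg_genes: set[str],
    de_table: pd.DataFrame | None = None,
) -> IntegrationResult:
    """Intersect promoter-motif genes with the DEG set, with provenance.

    Output rows are sorted by gene_id so reruns are byte-identical.
    """
    flags_by_gene = {g.gene_id: g for g in motif_genes}
    hits = sorted(set(flags_by_gene) & deg_genes)
    stats: dict[str, tuple[float, float]] = {}
    if de_table is not None:
        sub = de_table[de_table["gene_id"].isin(hits)]
        stats = {r.gene_id: (r.log2fc, r.fdr) for r in sub.itertuples()}
    rows = []
    for gid in hits:
        lfc, fdr = stats.get(gid, (float("nan"), float("nan")))
        rows.append((gid, ",".join(flags_by_gene[gid].motif_classes), lfc, fdr))
    df = pd.DataFrame(rows, columns=["gene_id", "motif_classes", "log2fc", "fdr"])
    return IntegrationResult(list(motif_genes), set(deg_genes), df)


# -------------------------------------------------------------- writers ----

def write_classifications(classifications: Iterable[PeakClassification], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak\thas_octamer\thas_ggaa\tcategory\n")
        for c in classifications:
            fh.write(f"{c.peak_name}\t{int(c.has_octamer)}\t{int(c.has_ggaa)}\t{c.category}\n")


def write_targets(result: IntegrationResult, path: str) -> None:
    result.putative_targets.to_csv(path, sep="\t", index=False, float_format="%g")
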