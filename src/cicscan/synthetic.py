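"""Self-contained synthetic fixture bundle with planted ground truth.

The generator emulates the statistical structure of the real inputs without
any download: a toy genome whose background is guaranteed free of all five
probe strings (by rejection resampling), non-overlapping peaks carrying
planted motif instances per a drawn four-way category, strand-balanced
single-transcript gene models — a configurable fraction with a peak planted
inside their promoter window — a differential-expression table with assigned
effect sizes and FDRs, and tied ordinal 0-3 score pairs with a controllable
concordance.  Identical configuration (including seed) yields a
byte-identical bundle.

FDR values are assigned, not computed: the fixture emulates the output table
of a differential-expression fit, not the fit itself.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .annotation import GeneModel, PeakRecord, write_gtf, write_peaks
from .motifs import (
    GGAA_UNIT,
    cic_octamer,
    find_ggaa_repeats,
    find_octamer_hits,
    probe_inventory,
)

CATEGORY_NAMES = ("octamer_only", "ggaa_only", "both", "neither")

_MAX_REJECTION_PASSES = 200
_MAX_PLACEMENT_TRIES = 1000


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its constraints."""


@dataclass
class SyntheticConfig:
    """All tunables of the fixture bundle.

    category_proportions order follows CATEGORY_NAMES:
    (octamer_only, ggaa_only, both, neither).
    de_effect is a |log2 fold change|; ihc_concordance in [-1, 1] sets the
    direction/strength of the planted ordinal association.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS1": 200_000})
    n_genes: int = 20
    n_peaks: int = 50
    category_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    peak_width: int = 200
    ggaa_run_units: int = 2
    de_effect: float = 2.0
    de_fdr_true: float = 0.05
    de_fdr_null: float = 0.5
    de_responder_fraction: float = 0.5
    n_ihc: int = 100
    ihc_concordance: float = -0.5
    promoter_peak_fraction: float = 0.5

    def validate(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category_proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in self.category_proportions):
            raise ValueError("category_proportions must be non-negative")
        if self.peak_width < 8:
            raise ValueError("peak_width must be >= 8 to fit an octamer")
        if self.n_genes <= 0 or self.n_peaks <= 0 or self.n_ihc <= 0:
            raise ValueError("all counts must be positive")
        if self.ggaa_run_units < 2:
            raise ValueError("ggaa_run_units must be >= 2")
        for chrom, length in self.chrom_lengths.items():
            if length < 10 * self.peak_width:
                raise ValueError(
                    f"chromosome {chrom}: length {length} < 10 x peak_width {self.peak_width}"
                )
        if not -1.0 <= self.ihc_concordance <= 1.0:
            raise ValueError("ihc_concordance must lie in [-1, 1]")
        if not 0.0 <= self.promoter_peak_fraction <= 1.0:
            raise ValueError("promoter_peak_fraction must lie in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class GroundTruth:
    """Planted truth the recovery tests compare against."""

    peak_categories: dict[str, str] = field(default_factory=dict)
    gene_promoter_motif: dict[str, bool] = field(default_factory=dict)
    gene_de_responder: dict[str, bool] = field(default_factory=dict)

    @property
    def expected_targets(self) -> set[str]:
        """Genes with a promoter motif AND a planted DE response."""
        return {
            g for g, has_motif in self.gene_promoter_motif.items()
            if has_motif and self.gene_de_responder.get(g, False)
        }

    def to_json(self) -> str:
        payload = asdict(self)
        payload["expected_targets"] = sorted(self.expected_targets)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(d["peak_categories"], d["gene_promoter_motif"], d["gene_de_responder"])


# -------------------------------------------------------------- genome ----

def _probe_free(seq: str, probes: Sequence[str]) -> bool:
    return not any(p in seq for p in probes)


def _random_clean_sequence(rng: np.random.Generator, length: int, probes: Sequence[str]) -> str:
    """Random ACGT sequence with no occurrence of any probe string.

    Resamples a window around each residual hit; the per-position hit
    probability is ~5 * 4^-8, so a few passes suffice for any toy genome.
    """
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bytearray(rng.choice(bases, size=length).tobytes())
    pad = max(len(p) for p in probes)
    for _ in range(_MAX_REJECTION_PASSES):
        text = seq.decode()
        dirty = []
        for p in probes:
            start = text.find(p)
            while start != -1:
                dirty.append((start, start + len(p)))
                start = text.find(p, start + 1)
        if not dirty:
            return text
        for (s, e) in dirty:
            lo, hi = max(0, s - pad), min(length, e + pad)
            seq[lo:hi] = rng.choice(bases, size=hi - lo).tobytes()
    raise GenerationError(
        f"motif-free rejection did not converge in {_MAX_REJECTION_PASSES} passes "
        f"(length {length})"
    )


def generate_genome(config: SyntheticConfig) -> dict[str, str]:
    """One motif-free sequence per configured chromosome."""
    config.validate()
    rng = config.rng(1)
    probes = sorted(probe_inventory(min_units=2))
    return {
        chrom: _random_clean_sequence(rng, length, probes)
        for chrom, length in sorted(config.chrom_lengths.items())
    }


# --------------------------------------------------------------- peaks ----

def _plant_peak_sequence(
    rng: np.random.Generator, width: int, category: str, run_units: int, probes: Sequence[str]
) -> str:
    """Build one peak sequence carrying exactly the planted motifs.

    Verifies after planting that the octamer hit set and the GGAA-run set
    are exactly as requested (insertion junctions can create accidental
    probes, in which case the draw is repeated).
    """
    octamers = sorted(cic_octamer().literals)
    run = GGAA_UNIT * run_units
    want_oct = category in ("octamer_only", "both")
    want_run = category in ("ggaa_only", "both")
    need = (8 if want_oct else 0) + (len(run) if want_run else 0)
    if width < need:
        raise GenerationError(f"peak_width {width} cannot fit planted motifs for {category!r}")
    for _ in range(_MAX_PLACEMENT_TRIES):
        seq = list(_random_clean_sequence(rng, width, probes))
        slots: list[tuple[int, str]] = []
        if want_oct:
            slots.append((8, octamers[rng.integers(len(octamers))]))
        if want_run:
            slots.append((len(run), run))
        rng.shuffle(slots)
        # left-to-right placement in disjoint sub-intervals
        cursor = 0
        remaining = sum(l for l, _ in slots)
        ok = True
        for length, motif in slots:
            hi = width - (remaining - length)
            if cursor > hi - length:
                ok = False
                break
            pos = int(rng.integers(cursor, hi - length + 1))
            seq[pos : pos + length] = motif
            cursor = pos + length
            remaining -= length
        if not ok:
            continue
        text = "".join(seq)
        n_oct = len(find_octamer_hits(text))
        runs = find_ggaa_repeats(text, min_units=2)
        if n_oct == (1 if want_oct else 0) and len(runs) == (1 if want_run else 0):
            if not want_run or runs[0].run_units == run_units:
                return text
    raise GenerationError(f"could not plant a clean {category!r} peak in {_MAX_PLACEMENT_TRIES} tries")


def generate_peaks(
    config: SyntheticConfig, genome: dict[str, str]
) -> tuple[list[PeakRecord], GroundTruth]:
    """Place non-overlapping peaks and plant their category motifs.

    The genome dict is updated in place with the planted peak sequences.
    Peaks are kept >= 2 x peak_width apart so nearest-gene assignment stays
    unambiguous downstream.
    """
    config.validate()
    rng = config.rng(2)
    probes = sorted(probe_inventory(min_units=2))
    w = config.peak_width
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    spots: list[tuple[str, int]] = []
    tries = 0
    while len(spots) < config.n_peaks:
        tries += 1
        if tries > _MAX_PLACEMENT_TRIES * config.n_peaks:
            raise GenerationError(
                f"cannot place {config.n_peaks} non-overlapping peaks of width {w} "
                f"on a genome of {int(lengths.sum())} bp"
            )
        c = chroms[rng.choice(len(chroms), p=weights)]
        limit = len(genome[c]) - w
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit + 1))
        if all(abs(start - s0) >= 2 * w for s0, _ in placed[c]):
            placed[c].append((start, start + w))
            spots.append((c, start))
    spots.sort()

    cats = rng.choice(len(CATEGORY_NAMES), size=config.n_peaks, p=list(config.category_proportions))
    truth = GroundTruth()
    peaks: list[PeakRecord] = []
    for i, ((chrom, start), ci) in enumerate(zip(spots, cats)):
        category = CATEGORY_NAMES[ci]
        seq = _plant_peak_sequence(rng, w, category, config.ggaa_run_units, probes)
        g = genome[chrom]
        genome[chrom] = g[:start] + seq + g[start + w :]
        name = f"peak_{i:05d}"
        peaks.append(
            PeakRecord(chrom, start, start + w, name, score=1000.0, strand=".",
                       signal=10.0, p_value=5.0, q_value=3.0, summit=w // 2)
        )
        truth.peak_categories[name] = category
    return peaks, truth


# --------------------------------------------------------- gene models ----

def generate_gene_models(
    config: SyntheticConfig,
    genome: dict[str, str],
    peaks: Sequence[PeakRecord],
    truth: GroundTruth,
    promoter_window: tuple[int, int] = (-2000, 200),
    gene_length: int = 2000,
) -> list[GeneModel]:
    """Strand-balanced single-transcript genes; a configurable fraction get
    a previously generated peak planted inside their promoter window.

    A gene's promoter-motif flag in the ground truth is true iff its
    assigned promoter peak carries at least one planted motif (category is
    not "neither"); genes without a promoter peak are placed so no peak
    falls within +-(|window| + peak width) of their TSS.
    """
    config.validate()
    rng = config.rng(3)
    up, down = promoter_window
    span = abs(up) + abs(down)
    n_with_peak = int(round(config.promoter_peak_fraction * config.n_genes))

    # peaks far enough from chromosome ends to host a gene on either strand
    pad = gene_length + span
    eligible = [
        i for i, p in enumerate(peaks)
        if p.start >= pad and p.end + pad <= len(genome[p.chrom])
    ]
    rng.shuffle(eligible)

    def window_exclusive(g: GeneModel, own: PeakRecord) -> bool:
        """The promoter window contains its own peak and no other."""
        lo, hi = g.promoter_window(promoter_window)
        if not (lo <= own.start and own.end <= hi):
            return False
        return not any(
            p.name != own.name and p.chrom == g.chrom and p.start < hi and p.end > lo
            for p in peaks
        )

    genes: list[GeneModel] = []
    used: list[tuple[str, int, int]] = []
    for gi in range(config.n_genes):
        gene_id = f"gene_{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        if gi < n_with_peak:
            placed: GeneModel | None = None
            while eligible:
                pk = peaks[eligible[0]]
                margin = int(rng.integers(10, max(11, abs(down) - 10))) if abs(down) > 20 else 0
                if strand == "+":
                    # window [tss+up, tss+down): peak just upstream of the TSS
                    tss = pk.end + margin
                    start, end = tss, tss + gene_length
                else:
                    # window [tss-down, tss-up): peak just downstream in reference coords
                    tss = pk.start - 1 - margin
                    start, end = tss + 1 - gene_length, tss + 1
                cand = GeneModel(gene_id, pk.chrom, strand, start, end, ((start, end),))
                eligible.pop(0)
                if window_exclusive(cand, pk):
                    placed = cand
                    truth.gene_promoter_motif[gene_id] = (
                        truth.peak_categories[pk.name] != "neither"
                    )
                    break
            if placed is None:
                raise GenerationError(
                    f"no remaining peak can seed the promoter of gene {gene_id}"
                )
            genes.append(placed)
            used.append((placed.chrom, placed.start, placed.end))
            continue
        # motif-free promoter: keep the TSS clear of every peak
        placed_ok = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            chrom = sorted(genome)[int(rng.integers(len(genome)))]
            limit = len(genome[chrom]) - gene_length - span
            if limit <= span:
                continue
            start = int(rng.integers(span, limit))
            end = start + gene_length
            tss = start if strand == "+" else end - 1
            clear = span + config.peak_width
            if any(
                p.chrom == chrom and p.start < tss + clear and p.end > tss - clear
                for p in peaks
            ):
                continue
            if any(c == chrom and s < end and e > start for c, s, e in used):
                continue
            placed_ok = True
            break
        if not placed_ok:
            raise GenerationError(f"genome too small to place gene {gene_id} away from all peaks")
        g = GeneModel(gene_id, chrom, strand, start, end, ((start, end),))
        genes.append(g)
        used.append((chrom, start, end))
        truth.gene_promoter_motif[gene_id] = False
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ------------------------------------------------------------ DE table ----

def generate_de_table(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    fc_threshold: float = 1.5,
):
    """One row per gene (gene_id, log2fc, fdr).

    Planted responders (a seeded random fraction of all genes) get
    |log2fc| = de_effect with random sign and fdr = de_fdr_true; the rest
    get |log2fc| < fc_threshold and fdr = de_fdr_null.
    """
    import pandas as pd

    config.validate()
    if config.de_effect <= fc_threshold:
        raise ValueError(
            f"de_effect {config.de_effect} does not exceed the |log2FC| threshold "
            f"{fc_threshold}; planted responders would be unrecoverable"
        )
    rng = config.rng(4)
    n = len(genes)
    responders = rng.random(n) < config.de_responder_fraction
    rows = []
    for g, resp in zip(genes, responders):
        truth.gene_de_responder[g.gene_id] = bool(resp)
        if resp:
            lfc = config.de_effect * (1 if rng.random() < 0.5 else -1)
            fdr = config.de_fdr_true
        else:
            lfc = float(rng.uniform(-0.4, 0.4) * fc_threshold)
            fdr = config.de_fdr_null
        rows.append((g.gene_id, lfc, fdr))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])


# ----------------------------------------------------------- IHC pairs ----

def generate_ihc_scores(config: SyntheticConfig):
    """Paired ordinal scores in {0..3} with controllable concordance.

    concordance +1 yokes the two scores identically, -1 reverses them, 0
    shuffles one margin independently; intermediate values start from the
    yoked extreme and apply a proportional number of seeded transpositions.
    """
    import pandas as pd

    config.validate()
    if config.n_ihc < 2:
        raise ValueError("n_ihc must be >= 2")
    rng = config.rng(5)
    n = config.n_ihc
    c = config.ihc_concordance
    x = np.array([i % 4 for i in range(n)])
    rng.shuffle(x)
    if c >= 0:
        y = x.copy()
    else:
        y = 3 - x
    if abs(c) < 1e-12:
        y = rng.permutation(y)
    else:
        n_swaps = int(round((1.0 - abs(c)) * n))
        for _ in range(n_swaps):
            i, j = rng.integers(0, n, size=2)
            y[i], y[j] = y[j], y[i]
    return pd.DataFrame(
        {"sample_id": [f"core_{i:03d}" for i in range(n)],
         "cic_score": x.astype(int), "yap_score": y.astype(int)}
    )


# -------------------------------------------------------------- bundle ----

@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict[str, str]
    peaks: list[PeakRecord]
    genes: list[GeneModel]
    de_table: object  # pandas.DataFrame
    ihc: object  # pandas.DataFrame
    truth: GroundTruth


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Run every generator stage in order on one config."""
    genome = generate_genome(config)
    peaks, truth = generate_peaks(config, genome)
    genes = generate_gene_models(config, genome, peaks, truth)
    de = generate_de_table(config, genes, truth)
    ihc = generate_ihc_scores(config)
    return SyntheticBundle(config, genome, peaks, genes, de, ihc, truth)


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(bundle: SyntheticBundle, outdir: str) -> dict[str, str]:
    """Write the whole fixture bundle; returns the path of each artifact."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "peaks": os.path.join(outdir, "peaks.narrowPeak"),
        "genes": os.path.join(outdir, "genes.gtf"),
        "de": os.path.join(outdir, "de_table.tsv"),
        "ihc": os.path.join(outdir, "ihc_scores.tsv"),
        "truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_fasta(bundle.genome, paths["genome"])
    write_peaks(bundle.peaks, paths["peaks"])
    write_gtf(bundle.genes, paths["genes"])
    bundle.de_table.to_csv(paths["de"], sep="\t", index=False)
    bundle.ihc.to_csv(paths["ihc"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(bundle.truth.to_json() + "\n")
    return paths
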