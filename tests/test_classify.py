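"""Four-way peak classification, summaries, and ChIP x RNA integration."""

import numpy as np
import pandas as pd
import pytest

from cicscan.annotation import PeakAnnotation, annotate_peaks
from cicscan.classify import (
    PeakClassification,
    classify_peaks,
    filter_degs,
    intersect_targets,
    promoter_motif_search,
    summarize,
)
from cicscan.motifs import default_motif_sets, scan_sequence
from cicscan.synthetic import SyntheticConfig, generate_bundle


def test_category_is_pure_function_of_flags():
    assert PeakClassification("p", True, True).category == "both"
    assert PeakClassification("p", True, False).category == "octamer_only"
    assert PeakClassification("p", False, True).category == "ggaa_only"
    assert PeakClassification("p", False, False).category == "neither"


def test_classify_peak_sequences_directly():
    from cicscan.annotation import PeakRecord

    genome = {"c": "TTTT" + "TCAATGAA" + "TTTT" + "GGAAGGAA" + "TTTT" + "A" * 30}
    peaks = [PeakRecord("c", 0, 28, "both_pk"), PeakRecord("c", 28, 58, "aa_pk")]
    cls = classify_peaks(peaks, genome)
    assert cls[0].category == "both" and cls[1].category == "neither"


def test_planted_category_recovery(recovery_bundle):
    """Every planted category is recovered on the 400-peak bundle."""
    b = recovery_bundle
    cls = classify_peaks(b.peaks, b.genome)
    assert len(cls) == 400
    assert all(c.category == b.truth.peak_categories[c.peak_name] for c in cls)
    # realized counts are within multinomial sampling error of 100 each
    counts = pd.Series([c.category for c in cls]).value_counts()
    assert all(abs(counts[cat] - 100) < 4 * np.sqrt(400 * 0.25 * 0.75) for cat in counts.index)


def test_summary_arithmetic():
    cls = (
        [PeakClassification(f"g{i}", False, True) for i in range(4)]
        + [PeakClassification(f"o{i}", True, False) for i in range(3)]
        + [PeakClassification(f"b{i}", True, True) for i in range(2)]
        + [PeakClassification("n0", False, False)]
    )
    anns = [PeakAnnotation(c.peak_name, "Distal Intergenic", f"gene_{c.peak_name}", 10)
            for c in cls]
    s = summarize(cls, anns)
    assert s.counts == {"octamer_only": 3, "ggaa_only": 4, "both": 2, "neither": 1}
    assert s.fractions == {"octamer_only": 0.3, "ggaa_only": 0.4, "both": 0.2, "neither": 0.1}
    assert s.venn_peaks == (3, 2, 4)
    assert sum(s.counts.values()) == s.n_peaks == 10
    assert abs(sum(s.fractions.values()) - 1.0) < 1e-12


def test_summary_unique_gene_rollup():
    cls = [PeakClassification("p1", True, True), PeakClassification("p2", True, True)]
    anns = [PeakAnnotation("p1", "Promoter", "gShared", 0),
            PeakAnnotation("p2", "Promoter", "gShared", 5)]
    s = summarize(cls, anns)
    assert s.genes_per_category["both"] == 1
    assert s.venn_genes == (0, 1, 0)


def test_summary_rejects_mismatched_peak_sets():
    cls = [PeakClassification("p1", True, False)]
    anns = [PeakAnnotation("other", "Promoter", "g", 0)]
    with pytest.raises(ValueError, match="differ"):
        summarize(cls, anns)


def test_summary_identities_on_bundle(recovery_bundle):
    b = recovery_bundle
    cls = classify_peaks(b.peaks, b.genome)
    anns = annotate_peaks(b.peaks, b.genes)
    s = summarize(cls, anns)
    assert sum(s.counts.values()) == s.n_peaks == len(b.peaks)
    for cat in s.counts:
        assert abs(s.fractions[cat] * s.n_peaks - s.counts[cat]) < 1e-9
    assert sum(s.venn_peaks) == s.n_peaks - s.counts["neither"]
    for comp in s.composition_per_category.values():
        if any(v for v in comp.values()):
            assert abs(sum(comp.values()) - 100.0) < 1e-6


# -------------------------------------------------- promoter motif scan ----

def test_promoter_flags_equal_direct_window_scan(small_bundle):
    b = small_bundle
    anns = annotate_peaks(b.peaks, b.genes)
    found = {g.gene_id: g for g in promoter_motif_search(
        b.genes, b.genome, annotations=anns, all_genes=True
    )}
    for gene in b.genes:
        lo, hi = gene.promoter_window()
        seq = b.genome[gene.chrom][max(0, lo):hi]
        res = scan_sequence(gene.gene_id, seq, default_motif_sets())
        expected = res.has("CIC_octamer") or res.has("GGAA_repeat")
        assert (gene.gene_id in found) == expected
        if expected:
            assert found[gene.gene_id].has_octamer == res.has("CIC_octamer")
            assert found[gene.gene_id].has_ggaa == res.has("GGAA_repeat")


def test_promoter_search_matches_planted_truth(small_bundle):
    b = small_bundle
    anns = annotate_peaks(b.peaks, b.genes)
    flagged = {g.gene_id for g in promoter_motif_search(b.genes, b.genome, annotations=anns)}
    planted = {g for g, v in b.truth.gene_promoter_motif.items() if v}
    assert flagged == planted


def test_promoter_search_requires_annotations_unless_all_genes(small_bundle):
    with pytest.raises(ValueError, match="annotations"):
        promoter_motif_search(small_bundle.genes, small_bundle.genome)


def test_zero_promoter_fraction_gives_empty_motif_set():
    cfg = SyntheticConfig(
        seed=5, chrom_lengths={"chrT": 120_000}, n_peaks=15, n_genes=8,
        promoter_peak_fraction=0.0,
    )
    b = generate_bundle(cfg)
    anns = annotate_peaks(b.peaks, b.genes)
    assert promoter_motif_search(b.genes, b.genome, annotations=anns) == []
    assert b.truth.expected_targets == set()


# --------------------------------------------------------- DEG + targets ---

def test_filter_degs_strict_inequalities():
    de = pd.DataFrame(
        {"gene_id": ["a", "b", "c", "d"],
         "log2fc": [2.0, 2.0, -2.0, 1.5],
         "fdr": [0.05, 0.2, 0.1, 0.1]}
    )
    assert filter_degs(de) == {"a", "c"}  # b fails fdr (strict), d fails |fc| (strict)


def test_filter_degs_matches_bruteforce_on_random_table():
    rng = np.random.default_rng(8)
    de = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(1000)],
         "log2fc": rng.normal(0, 2, 1000),
         "fdr": rng.uniform(0, 1, 1000)}
    )
    expected = {
        r.gene_id for r in de.itertuples() if abs(r.log2fc) > 1.5 and r.fdr < 0.2
    }
    assert filter_degs(de) == expected


def test_filter_degs_monotone_in_thresholds():
    rng = np.random.default_rng(9)
    de = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(300)],
         "log2fc": rng.normal(0, 2, 300),
         "fdr": rng.uniform(0, 1, 300)}
    )
    base = filter_degs(de, 1.5, 0.2)
    assert filter_degs(de, 1.0, 0.3) >= base  # relaxing never shrinks
    assert filter_degs(de, 2.0, 0.1) <= base  # tightening never adds


def test_filter_degs_schema_error():
    with pytest.raises(ValueError, match="missing column"):
        filter_degs(pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0]}))


def test_intersect_targets_basic():
    from cicscan.classify import GeneMotifFlags

    motif = [GeneMotifFlags("A", True, False), GeneMotifFlags("B", False, True)]
    res = intersect_targets(motif, {"B", "C"})
    assert res.target_ids == {"B"}
    assert list(res.putative_targets["motif_classes"]) == ["ggaa"]
    empty = intersect_targets(motif, {"Z"})
    assert empty.target_ids == set()


def test_end_to_end_target_recovery(recovery_bundle):
    """Putative targets equal the planted set: precision = recall = 1."""
    b = recovery_bundle
    anns = annotate_peaks(b.peaks, b.genes)
    motif_genes = promoter_motif_search(b.genes, b.genome, annotations=anns)
    degs = filter_degs(b.de_table)
    res = intersect_targets(motif_genes, degs, b.de_table)
    assert res.target_ids == b.truth.expected_targets
    assert len(b.truth.expected_targets) > 0
    # tightening thresholds never adds targets
    tighter = intersect_targets(motif_genes, filter_degs(b.de_table, 2.5, 0.01), b.de_table)
    assert tighter.target_ids <= res.target_ids
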