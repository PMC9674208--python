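"""Shared fixtures: synthetic bundles and a hand-built 3-gene/10-peak toy."""

import pytest

from cicscan import GeneModel, PeakRecord, SyntheticConfig, generate_bundle

SMALL_CONFIG = dict(
    seed=11,
    chrom_lengths={"chrS1": 150_000},
    n_genes=12,
    n_peaks=24,
    peak_width=120,
    n_ihc=60,
    ihc_concordance=-0.5,
)

# the planted-recovery study condition: 400 peaks, equal category proportions
RECOVERY_CONFIG = dict(
    seed=11,
    chrom_lengths={"chrR1": 400_000, "chrR2": 400_000},
    n_genes=40,
    n_peaks=400,
    peak_width=200,
    category_proportions=(0.25, 0.25, 0.25, 0.25),
    de_effect=2.0,
    de_fdr_true=0.05,
    de_fdr_null=0.5,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SyntheticConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def recovery_bundle():
    return generate_bundle(SyntheticConfig(**RECOVERY_CONFIG))


@pytest.fixture(scope="session")
def toy_annotation_case():
    """Three genes, ten peaks, every feature category exercised; the
    expected categories and signed TSS distances are hand-computed."""
    genes = [
        GeneModel("gA", "chrT", "+", 10_000, 12_000,
                  exons=((10_000, 10_800), (11_500, 12_000))),
        GeneModel("gB", "chrT", "-", 16_000, 18_000, exons=((16_000, 18_000),)),
        GeneModel("gC", "chrT", "+", 24_000, 26_000, exons=((24_000, 26_000),)),
    ]
    peaks = [PeakRecord("chrT", s, s + 200, f"p{i}") for i, s in enumerate(
        [9_000, 10_300, 11_000, 11_600, 17_900, 16_400, 23_800, 26_500, 2_000, 13_600]
    )]
    expected = {
        "p0": ("Promoter", "gA", -900),
        "p1": ("Exon", "gA", 400),
        "p2": ("Intron", "gA", 1100),
        "p3": ("Exon", "gA", 1700),
        "p4": ("Promoter", "gB", -1),
        "p5": ("Exon", "gB", 1499),
        "p6": ("Promoter", "gC", -100),
        "p7": ("Downstream", "gC", 2600),
        "p8": ("Distal Intergenic", "gA", -7900),
        "p9": ("Downstream", "gA", 3700),
    }
    return genes, peaks, expected
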