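# Methods

## Motif model and scanning

The consensus CIC binding site is a degenerate octamer, conventionally
typeset T(G/C)AAT(G/A)AA. Written position-by-position against its four
canonical literals (TGAATGAA, TCAATGAA, TGAATGGA, TCAATGGA) the degeneracy
sits at positions 2 (G/C) and 7 (A/G), so the expander uses the positionally
exact pattern `T(G/C)AATG(A/G)A`; the Cartesian expansion of the typeset
shorthand would instead produce TGAATAAA/TCAATAAA, which are not CIC sites.
The non-consensus element is a GGAA microsatellite, [GGAA]ₙ with n ≥ 2
(GGAA is also the core ETS tetramer). Together the probe inventory is five
literal strings: GGAAGGAA plus the four octamers.

Scanning is exact substring search, which deliberately mirrors a grep-style
search over peak FASTA:

* octamer occurrences are reported at every offset, including overlaps;
* GGAA runs are reported as maximal runs (greedy left-to-right; a run's
  phase is fixed by its first unit; a reported run is not extendable by a
  whole unit on either side), with `run_units = ⌊length/4⌋`; raising the
  minimum unit count can only remove hits;
* N never matches; scanning is case-insensitive; there is no mismatch
  tolerance and no PWM scoring.

Strand handling is forward-only by default. Neither probe is palindromic,
and a plain string search over extracted peak sequences is inherently
single-stranded; `both_strands=True` additionally searches the
reverse-complement probes (TTCATTCA-family and TTCCTTCC) on the forward
sequence. This is a documented assumption, not a biological claim about
strand preference.

## Peak annotation

A peak is anchored at its narrowPeak summit when one is called
(summit ≥ 0), else at its interval midpoint. One feature category is
assigned by fixed precedence Promoter > 5'UTR > 3'UTR > Exon > Intron >
Downstream > Distal Intergenic, evaluated against all genes on the peak's
chromosome, so gene input order can never change an annotation. The
promoter window is −2000..+200 bp around the TSS, strand-aware and
half-open: a plus-strand TSS t gives [t−2000, t+200), a minus-strand TSS
gives [t−200, t+2000). The same window is reused for the promoter motif
search, keeping annotation and integration consistent. Downstream extends
3,000 bp past the transcript end (a common default; configurable). UTR
categories are only assigned when the annotation supplies UTR sub-features;
otherwise they collapse into Exon. The nearest gene minimises |signed TSS
distance| with ties broken by lexicographic gene id, making output
deterministic over unordered inputs. TSS profiles bin anchors by signed
distance over [−3000, +3000) (bin width 100 bp; the width must divide the
window), each peak contributing at most once.

narrowPeak q-values are read as −log10(q) per the ENCODE dialect, so a
linear threshold q < 0.05 keeps peaks with column value > 1.301; plain BED
input carries no q and is never q-filtered.

## Classification and integration

The four-way category is a pure function of the two presence flags and
partitions the peak set; fractions always use the full post-filter peak
count as denominator, and that denominator is reported alongside them
because percentage bases are otherwise ambiguous. Gene rollups go through
each peak's nearest-gene annotation (one gene per peak, each unique gene
counted once per category); the Venn triple is (octamer-only, both,
ggaa-only) on peaks, and on genes via the octamer-bearing and GGAA-bearing
gene sets.

DE filtering is |log₂FC| > 1.5 AND FDR < 0.2, both strict. The fold-change
scale is interpreted as log₂ (configurable): published threshold wordings
mix "absolute fold change" and "Log2FC", and the log₂ reading is both the
stricter and the internally consistent one; the threshold and scale are
plain parameters. The putative target list is the set intersection of
promoter-motif genes (restricted by default to genes annotated to at least
one peak; `--all-genes` lifts this) with the filtered DEG set, sorted by
gene id with per-gene motif classes and DE statistics attached.

## Kendall τ_b for ordinal IHC scores

With 0–3 scores over ~100 cores ties dominate, so the tie-corrected τ_b is
the right variant (and is what generic "Kendall" routines compute):
τ_b = (C − D)/√((n₀ − n₁)(n₀ − n₂)), n₀ = n(n−1)/2, n₁/n₂ the tie-pair
corrections per margin. Pair counts (concordant, discordant, tied in x
only, tied in y only, tied in both) are computed explicitly and always sum
to n₀. The default two-sided p-value uses the normal approximation with the
standard tie-corrected variance of C − D; a Monte-Carlo permutation
p-value (default 100,000 permutations, seeded, add-one corrected, two-sided
via |C − D|) is available and agrees with the normal approximation in order
of magnitude at n = 100. A constant margin makes τ undefined and raises an
error. Dichotomisation follows the conventional Low = {0,1} / High = {2,3}
split into a 2×2 table. The least-squares trend line offered for plots is
cosmetic and carries no inferential claim.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* of the real inputs:
peak intervals over a toy genome with motif instances planted at controlled
per-category proportions, strand-balanced single-transcript gene models
with strand-aware TSSs, a DE table with planted effect sizes and assigned
FDRs, and tied ordinal score pairs with controllable concordance. Key
guarantees, each enforced by construction and verified by full scans:

* **Zero-leak background.** Outside planted peaks the genome contains no
  occurrence of any of the five forward-strand probe strings (rejection
  resampling of windows around residual hits; insertion junctions are
  re-checked after planting). Background freedom is enforced for the
  forward-strand probes only, matching the default forward-only scan.
* **Planted categories.** Each peak carries exactly one octamer and/or one
  GGAA run (default 2 units, configurable) per its drawn category — or
  nothing for `neither`.
* **Unambiguous geometry.** Peaks sit ≥ 2 × width apart; each
  promoter-window gene contains exactly its own planted peak and no other,
  and motif-free genes keep every peak at least a window-plus-peak-width
  away from their TSS. This makes nearest-gene assignment and ground-truth
  recovery exact rather than probabilistic.
* **Recoverable DE truth.** Responders are a seeded random fraction
  (default 0.5) of genes with |log₂FC| = `de_effect` (default 2.0, which
  must exceed the filter threshold — otherwise generation aborts) and
  FDR = `de_fdr_true` (default 0.05); non-responders stay below threshold
  with FDR = `de_fdr_null` (default 0.5). The expected target set is, by
  definition, promoter-motif ∧ responder.
* **IHC concordance.** +1 yokes the margins, −1 reverses them, 0 shuffles
  one margin independently; intermediate values apply a proportional number
  of seeded transpositions, so only the *sign* of the planted association
  is guaranteed, not its magnitude.

What the fixtures do **not** emulate: read-level noise, fragment-size
effects, peak-caller artefacts, multi-isoform genes, overlapping promoters,
correlated FDRs, or repeat expansions embedded in low-complexity context.
Passing the recovery tests therefore demonstrates that the code implements
its stated rules exactly; it does not demonstrate robustness to the noise
sources of real ChIP-seq. Published landscape counts from real data are
context, not test assertions, because the underlying datasets are not
publicly deposited.

## Determinism and numerical choices

All randomness flows from a single integer seed through per-stage
`numpy` Generator streams (`default_rng([seed, stage])`), so a bundle and a
full pipeline run are byte-identical across reruns; the run manifest
records the tool version, a hash of the analytic configuration (the output
path is excluded) and per-stage row counts, and is written even on failure
with the failing stage recorded. Category proportions must sum to 1 within
1e-9; composition percentages sum to 100 within 1e-6; τ_b oracle
comparisons use 1e-12 absolute tolerance. Degenerate inputs fail loudly:
empty annotation sets for composition, constant score margins, peak
intervals outside the genome, sub-threshold `de_effect`, and rejection
sampling that does not converge within 200 passes.

## Problem sizes used in tests and the acceptance script

Scanner-vs-oracle checks use 1,000 random sequences up to 500 bp;
category recovery uses 400 peaks at equal proportions over an 800 kb
two-chromosome genome; target recovery uses that same bundle (40 genes);
τ_b oracle checks use 500 vectors of n ≤ 8; the null calibration uses 200
independent null score tables of n = 100 with 999 permutations each. These
sizes make every check exact or tightly calibrated while keeping the whole
suite fast on a single CPU.
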