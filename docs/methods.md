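# Methods

This note records the statistical models, conventions and design decisions
behind `cimexvir`, in the order the pipeline runs them.

## Candidate-segment co-occurrence screen

Segmented RNA viruses recovered from metatranscriptome assemblies are usually
identifiable only through their RdRp-encoding segment; the other segments
carry no universally conserved domain.  The screen recovers them from
presence/absence structure across samples.  For a candidate transcript with
occurrence sample set `S` and an anchor-positive sample set `A` (samples
containing at least one RdRp-confirmed transcript of the virus):

    V_co = |S ∩ A| / |A|        (recall against the anchor)
    T_co = |S ∩ A| / |S|        (precision of the candidate's occurrences)

A transcript passes when `V_co >= 0.75`, `T_co >= 0.5` and its longest open
reading frame strictly exceeds 500 nt.  These definitions are a formalisation
of a verbally described method: the published account states what each metric
"determines" but not its formula.  The pair chosen here reproduces the
published worked example — a companion present in 6 of 7 anchor-positive
samples plus 2 anchor-negative samples scores (6/7, 6/8) = (0.86, 0.75) at
the reporting precision — and is documented prominently as an interpretation.

Conventions fixed by this package:

* Anchor-positive status is sample-level and uses *any* anchor transcript;
  partial and complete anchor sequences count equally.
* Threshold comparisons are inclusive (`>=`) for V_co/T_co and exclusive
  (`>`) for the ORF length, reading "thresholds =" and "ORF size > 500 nt"
  literally.
* A transcript observed in no sample has no defined T_co; the screen reports
  it with `never_observed=True` and `passes=False` instead of aborting.
* Output ordering is (V_co desc, T_co desc, transcript ID asc); the ID
  tie-break makes reports reproducible.

No null model or significance test is attached to the thresholds; the method
is a fixed-threshold screen by design.

## ORF extraction

`find_orfs` scans all six frames with EMBOSS-getorf-style semantics.  The
pipeline default is the "nucleic sequence between stop codons" mode
(`stop_to_stop_nt`, getorf `-find 2`); `start_to_stop` modes require an ATG
(only ATG — no alternative starts).  Conventions the upstream tool leaves
open are fixed as follows:

* sequence ends act as virtual stop boundaries in stop-to-stop modes;
* reported ORF sequences and lengths exclude the terminating stop codon (so
  the `> 500 nt` filter is applied to the stop-free run);
* coordinates are 0-based half-open on the forward strand; minus-strand
  frames are numbered by offset on the reverse complement;
* codons containing `N` never match a start or stop and translate to `X`;
* only genetic code table 1 is wired up (the parameter exists for extension).

## Duplicate removal and p-distances

Within each sample, exact duplicate sequences (case-folded comparison) are
reduced to the first occurrence; identical sequences in different samples are
retained because they are independent detections.

The p-distance between two aligned rows is `mismatches / compared sites`.
The deletion policy is pairwise by default — per pair, sites with a gap or
`N` in either row are excluded — matching the common default of desktop
phylogenetics tools; complete deletion is available as an option.  The
published analysis does not state its policy.  A pair with zero comparable
sites is an error, not a zero.

Distances are stored as fractions; the reporting layer renders percent with
one decimal, rounding half away from zero.  Group summaries average pairwise
distances within each clade and between clade pairs; a singleton clade's
within-group mean is reported as undefined (NaN), never 0, to avoid silently
deflating summaries.

The packaged RdRp distance matrix reproduces the published clade summary to
±0.05 percentage points in five of six cells.  The Italy-vs-rest-of-world
cell recomputes to 22.25% from the printed (1-decimal) matrix against a
published 22.4%; the discrepancy is consistent with the published summary
having been computed from unrounded distances, and that cell is therefore
reported but not asserted.

## Abundance regression

`correlate` fits ordinary least squares of percent virus reads (response) on
percent Wolbachia reads (predictor), the orientation in which the published
fit is printed.  `r` is the Pearson correlation and the two-sided p-value
comes from `t = r*sqrt(n-2)/sqrt(1-r^2)` on `n-2` degrees of freedom — for a
single predictor this is identical to the regression F test, so the choice is
immaterial.  Reporting rounds slope to 3 decimals and intercept/r/p to 2.
A `drop_samples` option supports sensitivity checks against suspected
outliers (e.g. the sample with 14.9% Wolbachia reads); the default keeps all
rows, matching the published fit.

## Synthetic-data generator

The generator produces inputs with the structure the analyses assume, not
sequencing artefacts.  All randomness uses `numpy.random.default_rng`
(PCG64); `seed` is required everywhere and equal seeds give byte-identical
outputs.

**Presence matrices.**  Carrier status is sampled per virus independently per
sample (no co-infection structure), the simplest model consistent with a
per-sample detection table.  The anchor column equals the carrier indicator
exactly; fidelity and spillover apply only to non-anchor segments,
conditionally independently across segments given carrier status (the
statistics treat segments marginally).  Defaults for the recovery experiment
follow the scale of the study this emulates: 30 samples, a three-segment
virus at prevalence 0.4 with fidelity 0.9 and spillover 0.05, and 200
background transcripts at rate 0.2.

Under these exact conditions the probability that a single companion passes
the default screen, computed by exact binomial enumeration over the carrier
count, is 0.948, and the probability that *both* companions of a
three-segment virus pass in the same run is 0.899.  The test suite asserts
agreement between simulation and this enumeration; the separate requirement
that both companions pass in ≥95% of runs is *not* attainable under these
parameters (it would need fidelity ≈ 0.95 at this sample size), and the
corresponding test documents the measured rate rather than relaxing the
conditions.

**Divergent families.**  Per-site substitution with uniform choice among the
three alternative bases, no rate heterogeneity, no indels — sufficient
because p-distance is the only downstream statistic.  The expected mismatch
fraction between two sequences separated by branches with substitution
probabilities `p_i` is `(3/4)(1 − Π(1 − 4p_i/3))` (the Jukes-Cantor channel
composition); tests use this closed form as the oracle, e.g. within-clade
pairs traverse two `within` branches and between-clade pairs traverse
`within, between, between, within`.

**Abundance tables.**  `y = intercept + slope·x + N(0, noise_sd)`, truncated
at 0 after noise addition because read percentages cannot be negative
(truncation biases fits whose true line approaches 0 — tests that need exact
recovery keep the line positive).  When no x values are supplied they are
drawn from a lognormal (median ≈ 0.7%, σ = 1), mimicking the skewed
Wolbachia titres of field samples.

**ORF fixtures.**  Implanted ORFs are `ATG` + codons drawn from `{C,G}³` +
`TAA`; spacers are `TTAA` repeats.  An A/T-only spacer contains forward
stops (`TAA`) and reverse-strand stops (`TTA`) in all six frames within
12 nt, and C/G-only bodies contain no start or stop in any frame, so the only
`ATG`/`CAT` trinucleotides in the construct are the implant starts: a
start-to-stop scan provably returns exactly the implanted set.  Spacer
lengths are rounded up to a codon multiple with a floor of 12 nt, and every
block is kept a codon multiple so minus-strand frame placement is independent
of total length.

What the generator does *not* emulate: read-level noise, assembly chimeras,
coverage variation, clustering artefacts, co-infection correlation between
viruses, rate heterogeneity, or indels.  Passing tests therefore demonstrate
correctness of the statistics under their stated models, not robustness to
assembly pathology in real data.

## Problem sizes used in the automated checks

Exhaustive co-occurrence enumeration covers all anchor/transcript indicator
pairs over 5 samples (the sufficient statistic for any 5×5 matrix) plus a
literal sweep of all 3×3 matrices; ORF agreement uses 100 random 300-nt
sequences plus implanted fixtures; divergence recovery uses 25 families of
8 × 5 kb sequences; screen recovery uses 100 seeded repetitions of the
30-sample design.  These sizes give Monte-Carlo standard errors small enough
for 3–4 SE assertions while keeping the default test run around half a
minute.

## Known limitations

* The co-occurrence formalisation is this package's interpretation of a
  verbal description; a different prior formalisation could differ.
* Group means computed from a rounded published matrix inherit its rounding.
* The regression is a bivariate association check only; no robust or
  multivariate variants are provided.
* Alignment, clustering, homology search and tree inference are out of
  scope: the package consumes their outputs.
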