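# Methods

## Coverage model and formats

All stages operate on `CoverageTrack` objects: dense vectors of
non-negative per-nucleotide coverage for one strand of one library,
1-based and zero-filled, always in forward-strand coordinates (a
reverse-strand track is a separate vector, never a flipped one).  The
on-disk form is the *grp* dialect — two `#` header lines (genome id,
strand, length; library labels) followed by exactly `length`
tab-separated data lines, body line *k* being genomic position *k* — and
standard variableStep/fixedStep wiggle (span 1) for import.  Values are
printed with up to 6 significant digits (integral values without a
decimal point), so write→read round trips reproduce values to the
printed precision and identical inputs produce byte-identical files.

Library-size normalization multiplies a raw track by `scale / total`,
with `scale = 1e6` (reads-per-million style) and `total` defaulting to
the summed raw coverage of both strands of the library.  The scale
constant is immaterial downstream: every decision the pipeline takes is
a ratio.  Normalization is deliberately not idempotent — re-normalizing
an already-normalized track raises an error rather than silently
double-scaling.  Whether "library size" should mean mapped reads or
mapped nucleotides is left to the caller via the explicit `total`
argument; the default (track sum) is the nucleotide convention, which is
self-contained when only coverage files are available.

## Peak calling

Boundaries come from comparing two `w`-nt window means separated by an
`s`-nt spacer.  With `M(i)` the mean of `v[i .. i+w-1]`:

- start candidate at `i`:  `(M(i) + ε) / (M(i−s−w) + ε) ≥ f`
- end candidate at `j`:    `(M(j−w+1) + ε) / (M(j+s+1) + ε) ≥ f`

Defaults: `w = 5`, `s = 10`, `f = 1.5`, pseudocount `ε = 0.1`, coverage
fraction `c = 0.2`.  Choices the window definition leaves open were
fixed as follows:

- **Boundary placement.** A start is the first base of the high window
  and an end the last base of the high window, so a called peak contains
  only elevated coverage and a clean step is recovered exactly.
- **Run collapse.** Consecutive passing positions collapse to the
  position of maximal fold; ties break *leftmost for starts and
  rightmost for ends*.  On a noiseless step every position of the tied
  run sees the same fold, and this asymmetric rule is the only one that
  returns the full elevated region.
- **Pairing.** Left-to-right greedy: the first start opens an interval,
  interior starts are ignored, the first end at or after the open start
  closes it, dangling ends are ignored, and a dangling start is
  discarded (optionally closed at the track end).  When a start and an
  end candidate fall on the same coordinate the start is processed
  first, so single-base peaks are possible and peaks never overlap.
- **Pseudocount.** `ε` is added to both window means, keeping folds
  finite over zero background while perturbing high-coverage ratios by
  well under 1%.  Because boundary test and coverage filter are ratios,
  multiplying all coverage by `k > 0` (with `ε` co-scaled, or `ε = 0` on
  strictly positive tracks) leaves peak calls identical.
- **Coverage filter.** An interval is kept when its mean coverage is
  `≥ c ·` (grand mean per-nucleotide coverage over both strands of the
  library being called) — a global filter, so a locally clean peak in a
  low-coverage region is still dropped when the dataset is dominated by
  high-coverage regions.
- **What is peak-called.** The positionwise mean of the normalized
  pull-down replicates, with the control only used as the enrichment
  comparator.  Averaging the duplicates halves the background variance,
  which is what keeps spurious window folds (Poisson noise clearing
  `f = 1.5`) to a handful per genome.
- **Ends and circularity.** Windows that would run past the track ends
  are not evaluated by default; `circular=True` wraps them for circular
  bacterial chromosomes.

Peaks are numbered in coordinate order per strand, forward strand first,
continuing across strands.

## Enrichment

Each peak's fold change in a replicate is
`(mean pull-down + ε) / (mean control + ε)` over the peak interval
(means, not maxima — grp values are already per-nucleotide).  The
consensus rule uses a strict inequality at the threshold (default 2):
**enriched** iff *every* replicate exceeds it, **partially enriched**
iff some but not all do, **not enriched** otherwise.  A fold of exactly
2.0 therefore does not count.  All replicates are compared against a
single control library; replicate-matched controls can be handled by
repeated calls.

## Annotation

A peak is assigned to the single overlapping feature with the largest
overlap in nucleotides, either strand, with ties broken by kind
precedence (5′UTR > 3′UTR > RNA gene > CDS), then smaller feature, then
lexicographic id.  The category is the feature kind, antisense-prefixed
when the strands differ; peaks overlapping nothing are *intergenic* (a
closure category for sparse annotations, excluded from
distribution plots of real data by default).  Sense and antisense
features compete on equal footing — important for baits whose targets
are predominantly antisense RNAs.

Where a GFF3 lacks UTR records, `derive_utrs` adds fixed flanks
(defaults 100 nt 5′, 50 nt 3′), strand-aware, clipped at genome ends and
at the nearest same-strand feature; two derived intervals that still
collide are truncated at the midpoint of their overlap (the left
interval keeps the floor position).  Explicit UTRs suppress derivation
per side.  Derived UTRs never overlap any same-strand feature.  These
flanks are a documented fallback: real UTR coordinates come from TSS
maps, and category fractions computed from flank-derived UTRs are only
approximations to those from mapped UTRs.

## Statistics

**Category enrichment.** Exact one-sided hypergeometric upper tail per
functional category: `p = P[X ≥ k]` with `X ~ Hypergeom(N, K, n)` over
`N` background genes, `K` in the category, `n` targets, `k` of them in
the category.  Genes carrying several categories count once in each (no
down-weighting).  Benjamini–Hochberg adjusted values are reported
alongside raw p; significance is flagged at raw `p < α` (the
conventional reporting filter, `α = 0.05`) and, recommended, at adjusted
`p < α`.

**Rank comparison.** Kruskal–Wallis on mid-ranks with tie correction,
kept as a k-group test even though the comparison is two groups
(enriched vs non-enriched; 1 df).  The p-value comes from the χ²
approximation, except that for pooled sample sizes `N ≤ 10` all
`N! / (n₁!…n_k!)` assignments are enumerated and the exact tail
`P[H ≥ H_obs]` is reported (at `N = 10` balanced this is 252
assignments).  Degenerate inputs: all observations tied gives `H = 0`,
`p = 1`; two singleton groups always give `p = 1` because `H` is
invariant under the label swap.  The χ² approximation tracks the exact
permutation p to within 0.02 in the decision-relevant tail (exhaustive
enumeration for balanced tie-free groups of 8 gives a maximum absolute
deviation of 0.009 for exact `p ≤ 0.1`), but deviates by up to 0.046 at
mid-range p — the approximation should not be trusted for borderline
calls near `p ≈ 0.5`, which is why the exact branch exists.
Partially enriched peaks are excluded from the comparison by default.

## Synthetic data generator

The generator emulates the *processed* form of a pull-down experiment —
normalized strand-specific coverage of duplicate pull-down libraries and
one control — not reads or sequence.  Default conditions: a 70,000-nt
single-replicon genome; 60 non-overlapping genes of 200–1500 nt (≈15%
non-coding RNA genes, the rest CDS with explicitly written derived
UTRs), at least 50-nt intergenic gaps, one of ten functional categories
each; flat Poisson background with mean 25 coverage units; 30 planted
"true" peaks with multiplicative folds 2.5–6.0 and widths 30–150 nt;
10 decoys at folds 1.0–1.4; per-replicate lognormal jitter (σ = 0.1 on
the log scale) on each planted fold; and per-library lognormal depth
factors (σ = 0.3) so raw totals differ and normalization is exercised.
The genome length is sized so the gene complement packs with its
required gaps (60 genes averaging 850 nt plus gaps cannot fit in much
less; 70 kb leaves packing slack for all seeds).

Peaks are *multiplicative* on the shared background profile, mimicking
affinity capture out of a common transcriptome; additive spikes would
make the 2-fold rule depend on absolute depth and were rejected as
unrealistic.  Planted intervals are disjoint per strand with a 50-nt
margin so neighbouring boundary windows cannot interact.  Everything
derives from one integer seed through a single `numpy.random.Generator`;
identical seeds give byte-identical GFF3, grp files and truth tables.

What the generator does **not** model — and hence what passing tests do
not show about real data: transcription-unit-shaped coverage (real
background follows gene expression, not a flat mean), overdispersion
beyond the optional negative-binomial mode, fragment-length
autocorrelation along the genome, strand bleed-through, and partial or
overlapping binding sites.  Recovery rates on real libraries will be
lower than the ≥95% measured here.

Recovery scoring matches enriched calls to planted truth by reciprocal
overlap ≥ 50% on the same strand; recall is over planted true peaks,
precision over enriched calls, and with no enriched calls precision is
reported as 1.0 with an explicit flag.  Boundary errors are the absolute
start/end offsets of matched pairs.

## Pipeline and reproducibility

`run_all` executes normalize → merge → call peaks → enrich → annotate →
statistics, writing TSV tables and a `manifest.json` containing the
fully resolved configuration (no timestamps or environment state), so a
run can be repeated byte-identically from its manifest.  Any stage
failure aborts with the stage name and offending input.  Target genes
for the category-enrichment stage are the sense and antisense genes of
enriched peaks; the background is every annotated gene with a functional
category.

## Problem sizes used in the test suite

Oracle-equivalence checks run the caller against an independent
brute-force implementation on 500 random tracks of length up to
2,000 nt; the annotation classifier is checked against exhaustive
overlap enumeration on 200 peaks × 50 features; hypergeometric tails are
checked against full enumeration for all backgrounds up to 12 genes;
Kruskal–Wallis permutation nulls are enumerated up to pooled size 16;
the end-to-end recovery check uses the default generator conditions
above (seed 42).  The boundary-localisation study plants 200 peaks
(folds 2–6, widths 30–150) on Poisson background of mean 50, where ≥95%
of boundaries land within `s + w = 15` nt of truth.

## Known limitations

- Single replicon per run; no bigWig or BAM input (the pipeline consumes
  coverage, not reads).
- The caller has no sub-peak summit detection and no smoothing; two
  targets closer than the spacer+window geometry merge into one peak.
- Greedy boundary pairing can, on noisy single-track data, open an
  interval at a spurious start and close it at a distant true end;
  calling on the replicate-mean track (the default) makes this rare but
  not impossible.
- The enrichment rule is a fold threshold, not a significance test; no
  per-peak variance model is fitted.
- Flank-derived UTRs approximate, not reproduce, TSS-mapped UTRs.
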