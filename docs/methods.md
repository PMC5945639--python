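# Methods

## Problem and model

A miRNA loaded into AGO2 represses target mRNAs. Canonical targeting is
mediated by seed matches — Watson–Crick complements of miRNA nt 2–8 in the
3′UTR, graded 8mer > 7mer-m8 > 7mer-1A > 6mer — but a substantial fraction
of AGO2-bound, repressed transcripts carries no canonical site. The package
therefore treats target identification as a *statistical* problem over two
rankings of one transcript universe rather than as a site-prediction
problem: transcripts ranked by AGO2-RIP enrichment and by
post-overexpression repression, with enrichment of sequence words and set
overlap quantified exactly.

### Ranking statistics

Replicate columns are averaged (arithmetic mean) per condition and the
statistic is log₂((a + c)/(b + c)) with pseudocount c = 0.5 on the RPKM
scale. The pseudocount keeps the ratio finite at zero abundance and shrinks
ratios of barely expressed transcripts toward 0; any ratio-preserving
rescaling of the abundances (with c rescaled accordingly) leaves the
ranking unchanged. Ties are broken lexicographically by transcript id so
that ranking is a pure function of the table contents. Differential-
expression modelling (negative-binomial tests, shrinkage) is intentionally
out of scope: downstream stages consume ranks, not significance calls.

The regulation list is ordered most-down-regulated-first so that repressed
targets occupy the list head, mirroring the RIP list head; a flag reverses
the convention.

### Word-enrichment landscape

For word *w* (k ∈ {6, 7, 8}) and cutoff *n*: population N = all ranked
transcripts, K = transcripts containing *w* at least once, x = carriers in
the top-*n*. The signed score is

    score(w, n) = −log₁₀ P(X ≥ x)  if x/n > K/N   (over-represented)
                  +log₁₀ P(X ≤ x)  otherwise      (≤ 0, depletion)

Presence/absence is the default counting unit because it makes the
hypergeometric model exact; an occurrence-count mode (binomial at the
universe occurrence rate) is available behind a flag. Words containing
non-ACGT characters are never counted. No composition-bias correction
(Markov background, dinucleotide shuffles) is applied; consequently
base-composition-driven words can score on real data, which is why the
multiple-testing control is deliberately blunt: Bonferroni over
(4ᵏ words × cutoffs) per k.

The default cutoff grid is 20 evenly spaced ranks from N/20 to 19N/20 —
fine enough to localise a peak, coarse enough that the Bonferroni factor
stays interpretable.

**Numerics.** Tail probabilities are computed in log space by an exact
routine: log pmf(x) via `gammaln`, then the tail accumulated through the
term ratio pmf(i+1)/pmf(i) = (K−i)(n−i)/((i+1)(N−K−n+i+1)), truncated once
terms fall below 10⁻¹⁸ of the running sum past the distribution mean. This
keeps peak scores exact far beyond the ~10⁻³⁰⁸ double-precision underflow
limit and matches brute-force point-mass enumeration to < 10⁻¹³ on every
(N ≤ 30, K, n, x). The scalar overlap test uses `scipy.stats.hypergeom`.

### Cumulative-distribution validation

Transcripts are partitioned by their *best* site class (a transcript with
an 8mer and a 6mer counts once, as 8mer); the background is the site-free
(NONE) class, not "all transcripts", so the comparison is between carriers
and non-carriers. Each class is tested against the background with the
two-sided two-sample Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`),
asymptotic p by default, exact p when both samples are below 30. p-values
for samples under 8 trigger a warning. The report flags whether the mean
log₂ fold-change shifts order 8mer ≤ 7mer-m8 ≤ 7mer-1A ≤ 6mer ≤ 0. A
pooled "any site" row is included alongside the per-class rows, since the
figure-level claim concerns carriers versus non-carriers as a whole.

### Direct-target calling

Called targets are the intersection of the top n_rip AGO2-enriched and top
n_dw down-regulated transcripts, scored by the exact hypergeometric upper
tail P(X ≥ x) (observed value included). The universe N is the set of
transcripts present in both rankings after filtering — the conditioning set
of both statistics. Defaults n_rip = 4000 and n_dw = 1300 reflect where the
7mer-m8 site density peaks in the experiments the method was developed on;
`density_profile` recomputes that argmax for any data set with an
unweighted (classic KS-like) GSEA walk: +1/#hits per site-bearing
transcript, −1/#misses otherwise, so the walk starts and ends at zero and
its argmax marks the densest prefix. The unweighted walk was chosen over
correlation-weighted GSEA because it is parameter-free and is used only for
density localisation, not for significance.

### Seed census

Occurrences are counted with overlap because the quantity of interest is
the number of seeds in the transcriptome, not the number of carrier
transcripts. The default null is the exhaustive uniform ensemble of all 4ᵏ
same-length words (16,384 for k = 7; 65,536 for k = 8), which has no
Monte-Carlo error; a seeded sampled mode and a GC-matched word subset exist
for sensitivity analysis. The comparison ensemble includes the queried word
itself. z = (observed − ensemble mean)/ensemble sd; the percentile is the
fraction of ensemble words with census ≤ observed. Evolutionary
interpretation (why a seed is depleted or accumulated) is outside the
package's scope.

## Synthetic data generator

The generator emulates the measurement endpoint of the experimental design
— isoform-level RPKM-like tables for the two paired contrasts — without
simulating reads:

* UTRs: per-base i.i.d. with configurable GC fraction (default 0.40;
  3′UTRs are AT-rich), lengths uniform on 500–1,000 nt, 2,000 transcripts.
* Planting: site words inserted at uniform random positions with rejection
  sampling so the planted occurrence scans as exactly the intended class
  (a 6mer is never accidentally extended into a 7mer/8mer at its
  position); bounded retries, then an error. Default planted fractions
  8mer/7mer-m8/7mer-1A/6mer = 10/15/10/10%.
* Function: repression acts through *realized* site content — every
  transcript whose final UTR carries a site (planted or by chance) is a
  candidate true target and, if selected (``true_target_fraction``,
  default 1.0), receives the effect of its best class, default
  −0.8/−0.6/−0.4/−0.2 log₂ for 8mer/7mer-m8/7mer-1A/6mer, plus +1.0 log₂
  AGO2 loading in the RIP contrast. This matches the cumulative-
  distribution semantics (carriers repressed, stratified by class) and
  keeps the partition aligned with planted truth. A no-signal null is
  obtained with ``SyntheticConfig.null()``, which zeroes both planting and
  the true-target fraction — with the carriers-repressed model, "no
  planting" alone would still repress chance carriers and is not a null.
* Noise: log-normal on the abundance scale (additive Gaussian in log₂,
  sd 0.4 per replicate measurement; 2 replicates per condition); baseline
  expression log-normal with log₂ mean 5, sd 2 (typical RPKM ≈ 2–500).
* Determinism: one mandatory seed drives every draw; identical configs
  produce identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: 3′UTR composition structure (repeats, local GC,
conservation), isoform overlap, count-level sampling noise and
library-size effects, expression-dependent dispersion, competition between
transcripts for AGO2, and any noncanonical binding grammar beyond what the
word scan detects statistically.

## Problem sizes and degenerate inputs

Simulated experiments use 2,000 transcripts (a ~10× scaled-down universe;
prefixes scale accordingly, e.g. 4000/1300 → 400/130), 100 replicates for
calibration runs, and k = 7 landscapes where one word length suffices;
these sizes make every result reproducible on a laptop in minutes. Empty
UTRs scan to no sites; words absent everywhere give p = 1 at every cutoff;
a word present in every transcript scores 0; zero-hit density profiles and
empty site-free backgrounds raise errors rather than returning
meaningless statistics. N and any non-ACGT character break word matches
(never wildcards). Coordinates are 0-based half-open on the given UTR
strand; only that strand is searched.

## Known limitations

* Presence-mode landscapes ignore multiplicity of sites within one UTR;
  the occurrence mode trades exactness for it.
* The asymptotic KS p is conservative for heavily tied data; fold-change
  ties are rare in practice but possible with low-precision input tables.
* The universe definition (transcripts shared by all tables and the UTR
  FASTA) makes fold/expected values depend on the annotation used, as any
  overlap statistic does.
* Reference mature sequences for miR-100-5p and miR-125b-5p are taken from
  miRBase, consistent with their full-length LNA detection probes.
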