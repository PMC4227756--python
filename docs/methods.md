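# Methods

This document specifies the statistical models, algorithms, parameter
defaults and numerical choices implemented in `numtcaller`, together with the
simulator's realism limits and the known limitations of the approach.

## 1. Insert-size model

For each library the insert-size distribution is estimated from properly
paired, primary, non-duplicate alignments with positive template length
(up to 100,000 pairs). The top and bottom 0.5% of observed lengths are
trimmed before taking the mean and standard deviation, making the estimate
robust to chimeric outliers. Fewer than 100 usable pairs is an error.

The clustering window is

```
W_L = mean_insert + 3 · sd_insert
```

A nuclear anchor whose mate lies inside an insertion can sit at most about
one insert length away from the breakpoint, so `W_L` bounds the span of a
single-sided cluster and `2·W_L` bounds the forward→reverse cluster gap.

## 2. Discovery

1. **Candidate pair extraction.** Keep primary, non-duplicate reads with
   nuclear MAPQ ≥ 10 (`--mapq`) whose mate maps to the mitochondrial contig
   or inside a known reference-Numt interval (optional BED). The MAPQ floor
   suppresses anchors in repetitive flanks; mates of reference-Numt homologs
   are retained because a true polymorphic insertion draws mates to both the
   mitochondrial contig and its nuclear homologs.
2. **Clustering.** Single-linkage clustering of anchors per (chromosome,
   strand): consecutive anchor starts within `W_L` join the same cluster.
   The result is independent of input order.
3. **Linking.** Forward-strand clusters link to the nearest downstream
   reverse-strand cluster with gap ≤ `2·W_L` (greedy, smallest gap first).
   Unlinked clusters are retained as one-sided candidates; these can never
   yield a precise breakpoint on their own.
4. **Breakpoint localization.** Within the candidate region, soft-clipped
   alignments (clip ≥ 20 bases) vote for the reference base at which they
   break. A breakpoint is *precise* when ≥ 2 reads break at the identical
   position and the modal position's longest clipped tail realigns ungapped
   to the circular mitochondrial sequence at ≥ 90% identity (exhaustive
   sliding scan over the doubled sequence, both strands). Ties go to the
   leftmost position. Imprecise candidates report the linked-interval
   midpoint with a CIPOS confidence interval.
5. **Mitochondrial source interval.** Mate coordinates (start and inferred
   end, modulo the circle) plus the clip-tail offset are combined into the
   smallest circular interval covering all points, computed as the
   complement of the largest gap between consecutive points on the circle —
   correct for fragments spanning the origin.

## 3. Genotype likelihood

For ploidy `m` (default 2), `k` reads at a site (`k_ref` spanning the
reference junction, `k_alt` supporting the insertion), and per-read error
probabilities `e_j = 10^(−MAPQ_j/10)` clamped to `[1e−6, 0.5]`:

```
L(g) = m^(−k) · Π_{j∈ref} [(m−g)(1−e_j) + g·e_j] · Π_{j∈alt} [(m−g)·e_j + g(1−e_j)]
```

Reference-junction reads are evidence *against* carrying the insertion, so
their factor is large when `g` is small; insertion-supporting reads mirror
this. A useful identity checked by the test suite: for `m = 2`, every factor
at `g = 1` equals `(1−e)+e = 1`, giving `L(1) = 2^(−k)` exactly,
independent of the error vector.

All computation is in log space; a structurally impossible observation
(e.g. an error-free reference read under `g = m`) yields `−∞` rather than
underflow.

**Call quality** is `−10·log10( L(0) / Σ_g L(g) )`, capped at 99.99.
**Filters** (named in the VCF): `min-quality` (< 50), `min-reads`
(supporting pairs < 4), `min-depth` (ref-spanning + supporting < 5). DP is
defined as reference-spanning plus insertion-supporting reads; a
reference-spanning read must cover 20 bases on each side of the junction
without a long clip.

**Population EM.** Across `N` samples, the allele frequency is iterated as

```
AF ← ( Σ_i E[g_i | AF] + 1 ) / ( 2N + 2 )
```

(posterior-weighted allele count with a one-allele pseudocount, flooring the
estimate at `1/(2N+2)` so Hardy–Weinberg priors never become degenerate),
for at most 10 iterations or until the change is < 1e−4. Final per-sample
genotypes are posterior modes under the Hardy–Weinberg prior at the
converged frequency.

## 4. Dating by diagnostic positions

Modern and ancestral mitochondrial sequences are globally aligned
(affine gaps: match 2, mismatch −1, open −5, extend −0.5). *Diagnostic
positions* are substitution columns (indel columns excluded), indexed by
1-based modern coordinates. Each Numt is placed on the circular modern
sequence by edit-distance alignment against the doubled sequence, both
strands; the placement yields a map from modern positions to Numt bases.

With `n` diagnostic positions covered by the Numt and `m` of them carrying
the modern allele:

```
pct = round_half_even( 100·m/n )        (exact rational arithmetic)
age  = (100 − pct) · 6 / 100  MYA        (human–chimp divergence = 6 MY)
```

`pct = 100` reports `<0.1` (younger than the resolution); `n = 0` reports
`NA`. Rounding uses `fractions.Fraction`, so half-cases (e.g. 87.5 → 88,
92.5 → 92) are decided exactly, never by floating-point representation.

**Alignment ambiguity.** Two cost-equal readings exist for some placements:
a run of substitutions flanked by coincidental context matches can be
rewritten as a deletion+insertion pair, and a terminal mismatch as a
terminal insertion. Both readings erase substitutions. Because Numts are
ungapped copies of the circle, the implementation prefers an ungapped
placement whenever its Hamming distance is no worse than the gapped edit
distance, and re-anchors terminal indel columns onto adjacent circle bases
(on a circular target, terminal indels are linearization artifacts).

**Heteroplasmy screening.** A Numt's SNP profile (its substitutions relative
to modern mtDNA, requiring ≥ 90% placement identity) is intersected with
reported heteroplasmy tables on (position, allele): a reported heteroplasmic
minor allele equal to a Numt-specific allele is flagged as a possible Numt
artifact rather than true heteroplasmy.

## 5. Permutation enrichment

The test statistic defaults to the number of observed positions whose
±window flank intersects the feature track (half-open intervals; binary
search over merged, sorted intervals). Null sets preserve the per-chromosome
composition of the observed set and draw positions uniformly from non-gap
bases (assembly gaps excluded via segment-cumsum inverse sampling). The
p-value is the add-one two-tailed estimate

```
p = min(1, 2 · min(#{null ≥ obs}+1, #{null ≤ obs}+1) / (n+1))
```

so an observation more extreme than all 1000 nulls reports `2/1001`, never
zero. With a discrete statistic and few positions the estimate is
conservative (ties inflate both tails); calibration is verified in the test
suite with a continuous statistic (mean flank %GC). Flank composition
reports %GC (of non-N bases) and AT/TA dinucleotide density per position.

## 6. Simulator and its realism limits

The simulator implants mitochondrial fragments (optionally spanning the
circular origin, optionally reverse-complemented) into diploid haplotypes,
samples read pairs with Normal(insert_mean, insert_sd) insert lengths and a
flat per-base substitution error, and *projects* each read back onto the
clean reference as an idealized aligner would: the reference segment with
the longest overlap hosts the alignment and bases beyond the junction are
soft-clipped with their sequence preserved. Reads wholly inside an insert
map to the mitochondrial contig modulo circularity. An optional
`repeat_flank` interval maps with MAPQ 0 to emulate a repetitive flank.

Deliberate departures from real data, which bound what the fixtures can
validate:

- no sequencing indels and flat base quality; substitution errors only;
- perfect, deterministic alignment — no mapping ambiguity except the
  explicit `repeat_flank`, no chimeric artifacts, no duplicates;
- no target-site duplications or post-integration rearrangements at the
  junction, so breakpoints are cleaner than PCR-validated real events;
- uniform fragment sampling (no GC bias or coverage waviness).

Consequently recovery tests demonstrate correctness of the calling logic
under its own model assumptions, not performance on real libraries.

## 7. Numerical choices

- Likelihoods in natural-log space; `insertion_quality` via log-sum-exp.
- Exact rational rounding (`fractions.Fraction`) for dating percentages.
- Ungapped circular matching via a vectorized sliding-window scan of the
  doubled sequence (numpy); gapped placement via edlib (HW mode) with the
  ambiguity resolution of §4; global modern↔ancestral alignment via
  Bio.Align.PairwiseAligner.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical configurations produce
  byte-identical fixtures.

## 8. Limitations

- Insertions into repetitive nuclear regions are invisible when anchors fall
  below the MAPQ floor (by design; the simulator's `repeat_flank`
  demonstrates the failure mode).
- Two insertions closer than about one insert size may merge into a single
  candidate.
- Imprecise (no-soft-clip) calls carry interval-midpoint breakpoints with
  wide confidence intervals.
- The dating clock assumes a uniform substitution rate along the human
  lineage and a 6 MY divergence; percentages from few diagnostic positions
  are coarse (quantization of ±0.5/n · 6 MYA).
- The EM allele-frequency estimator assumes Hardy–Weinberg equilibrium and
  unrelated samples.
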