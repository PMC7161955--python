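# Methods

## Background and scope

In *Paramecium*-like ciliates, the somatic macronucleus (MAC) develops from
the germline micronucleus (MIC) at each sexual cycle, and tens of thousands
of short Internal Eliminated Sequences (IESs) are excised precisely from the
somatic genome. Each IES is a single-copy element bounded by a TA
dinucleotide at each end; excision leaves one TA at the junction. Whether a
given IES was excised in a given DNA sample is therefore visible in
junction-spanning sequencing reads: a read across the MAC junction (one TA
between the two flanks) supports excision (IES−), while a read across either
germline boundary supports retention (IES+).

`iespipe` implements the full desk-scale analysis around this observable:
a synthetic-data generator (genome pairs and whole-cell paired-end reads),
junction-read classification and per-IES retention scoring, significance
calling against a control condition, and the feature analysis of retained
IES sets (length peaks, neighbor-density enrichment, matched random-sampling
nulls, replicate overlap and correlation).

## The apparent retention score

For an IES at MAC offset `p` (germline left boundary `g`, length `L`) three
probe windows of equal width `2k + 2` are defined, each centered on a
boundary TA:

* `minus`      = `MAC[p−k : p+2+k]` (the excised junction),
* `plus_left`  = `germline[g−k : g+2+k]`,
* `plus_right` = `germline[g+L−k : g+L+2+k]`.

A read (either mate, either strand) supports a boundary when it contains the
probe *core* — `m` bases on each side of the TA, width `2m + 2` — as an
exact contiguous substring. Matching is exact because simulated reads are
error-free; approximate alignment is out of scope.

Counting is **boundary-level**: a pair matching a plus probe contributes one
vote per matched boundary (a pair spanning a whole short IES collects both);
a pair matching the junction probe supports excision at *both* boundaries
and contributes two minus votes. With this accounting the IES+ and IES−
catchments are exactly equal (each boundary has the same window width on
both forms), and the retention score

    IRS = ies_plus / (ies_plus + ies_minus)

is an unbiased estimate of the frequency of the unexcised form among
junction-covering molecules, for any IES length.

**Whole-cell dilution.** Total DNA from developing cells mixes new-MAC
molecules (where an IES is retained with probability `r`) with old-MAC
fragments that never carry IESs. If a fraction `rho` of junction-covering
DNA is new-MAC, the expected score is

    E[IRS] = rho·r / (rho·r + rho·(1−r) + (1−rho)) = rho·r,

so whole-cell scores are *apparent* retention scores, shifted down by the
old-MAC fraction. The inverse estimator `r̂ = min(1, IRS/rho)` recovers the
per-IES retention probability when `rho` is known. An exhaustive
fragment-position enumeration oracle (`iespipe.validation`) reproduces this
expectation exactly under the simulator's generative model and is used to
validate both the simulator and the scorer.

**Information floor.** At read depth `c`, read length `R` and overlap `m`,
each IES junction is covered by roughly `c·(R−2m−1)/(2R)` informative
fragments (≈ 79 at 100X with 2×100 nt reads and `m = 10`). Because plus and
minus votes from one fragment come in correlated pairs, the per-IES variance
of IRS is ≈ `rho·r(1−rho·r)` over that fragment count, so the per-IES
standard error of `r̂` at `rho = 0.5` is ≈ 0.07–0.10 across mid-range `r`.
Per-IES recovery much below that error cannot be expected at 100X; averaged
scores (e.g. the mean IRS over hundreds of IESs) are correspondingly far
more precise.

## Significance of retention against a control

Per IES, a one-sided exact test (Fisher; computed as the hypergeometric
survival function, vectorized) asks whether the IES+ proportion in the case
exceeds the control's, followed by Benjamini–Hochberg correction across all
tested IESs (`significant ⇔ q ≤ alpha`, default `alpha = 0.05`). IESs with
fewer than `min_reads` (default 10) total counts in either condition are
flagged untested.

The 2×2 tables use **fragment-level** counts (at most one vote per read pair
per IES), not the boundary-level counts that define the score: boundary
votes arrive in correlated twos, which would double the apparent evidence
and make the test anti-conservative (measured empirically as a null
false-discovery proportion of 0.20 at `alpha = 0.05` before this choice;
0.0 after). Scores and tests therefore use the same classification but
different counting units — the score needs unbiasedness, the test needs
independent sampling units.

## The synthetic-data generator

The generator emulates, at desk scale, the features of the real system that
the analysis depends on:

* **Genomes.** One or more AT-rich replicons (default GC 0.28, matching the
  strongly AT-rich somatic genome). IES insertion points are placed by an
  exact sorted-uniform minimum-gap scheme (no rejection sampling): a sparse
  background with configurable minimum spacing, plus optional dense regions
  — windows of a few kb holding ~10 IESs — into which each IES falls with
  probability `cluster_fraction`. TA is forced at every insertion point and
  the germline is the MAC with each IES sequence (starting with TA) spliced
  in; excising all annotated IESs reproduces the MAC byte-exactly.
* **Lengths.** A mixture over periodic size-peak bins: bin *k* spans
  `[26 + 10k, 30 + 10k]` bp, uniform within a bin, with the first peak
  (26–30 bp) dominant. Only the first peak's position is a biological
  anchor; subsequent peak weights are configurable placeholders. Dense
  regions may draw from their own mixture (`dense_peak_weights`), which is
  how the short-IES/dense-region confound of real IES-rich loci is planted.
* **Retention truths.** Per condition: `all_retained`, `none_retained`,
  `uniform(r)`, or `feature_logistic` with
  `r_i = logistic(b0 + b_len·1[L_i ≤ 30] + b_dens·density_i)`.
* **Reads.** Error-free paired-end fragments of fixed length `mean_insert`
  (default 300 nt; qualities are written constant — the analysis is
  count-based and a sequencing-error model would only thin counts). A
  fragment is old-MAC (relative rate `1 − rho`, template = MAC) or new-MAC
  (`rho`). New-MAC starts are uniform over germline coordinates; a start
  inside an IES body exists only on molecules that retained it, so it is
  kept with probability `r_i` (thinning) — this detail is what makes the
  plus and minus catchments equal for long IESs too. Each IES locus a
  fragment walks over is resolved independently (correlated excision of
  neighbors is not modeled). Fragment count is set so mean read depth over
  the MAC approximates the requested coverage.

What the generator does **not** emulate: sequencing errors and base
qualities, insert-size variance, partially or imprecisely excised boundaries
(variant junctions), transposon/minisatellite elimination and chromosome
fragmentation, polyploidy-resolved copy numbers, and any correlation between
neighboring excision events. Passing tests therefore demonstrate the
correctness and calibration of the counting, scoring, testing and
enrichment machinery under the stated generative model — not robustness to
alignment artifacts or error-rich real data.

## Feature analysis of retained sets

* **Neighbor density**: for each IES, the number of other IESs on the same
  replicon whose MAC insertion point lies strictly within 1 kb (default) on
  either side. Density classes are `0 … 7` and `8+` (top-coded, default
  `max_class = 8`).
* **Enrichment index**: per class,
  `EI = log2(f_retained / f_universe)`; undefined (NA, not ±∞) when either
  fraction is zero.
* **Length statistics**: fraction in the closed first peak `[26, 30]` bp and
  the empirical cumulative length curve, restrictable to < 150 bp.
* **Matched random samples**: strata are exact length in bp or density
  class; per stratum the sample draws without replacement as many universe
  members as the reference holds, taking the whole stratum on shortfall (so
  a size-matched sample can end up slightly smaller than its reference).
  Because one draw is itself noisy, the reported control quantities (mean
  length of a density-matched sample; top-class EI of a length-matched
  sample) are averaged over 20 sampling seeds.
* **Replicate agreement**: overlap fractions of significant sets and
  Spearman rank correlation of scores over shared, defined-score IESs
  (average ranks for ties; undefined below 3 shared scores). Note that
  replicate correlation is only informative when true retention varies
  across IESs: under a uniform truth (e.g. the complete-knockdown scenario)
  the ranking is pure counting noise and the expected correlation is ~0.

## Numerical and engineering choices

* Exact matching uses a base-5 rolling hash over `{A,C,G,T,N}` of the core
  width (≤ 27 bases fits a uint64 injectively, so hash equality is sequence
  equality — no collisions); both strands are handled by indexing each core
  and its reverse complement. A per-pair linear scan with identical
  semantics serves as the simple reference path, and a fully independent
  brute-force substring scanner (probe cores re-derived from genome slices)
  is kept for validation.
* Probe-core collisions between IESs (identical local context) are flagged
  at library build; matches then vote for every colliding IES, mirroring
  the brute-force semantics. A pair with evidence for both forms of the
  same IES is ambiguous for that IES and contributes to neither count.
* All randomness flows from one integer seed through deterministically
  derived stage sub-seeds; rerunning a scenario with the same configuration
  reproduces every output file byte-for-byte. Output tables carry the tool
  version, a configuration hash and the seed as header comments.
* Coordinates are 0-based half-open internally; GFF3 I/O converts to
  1-based inclusive. The GFF3 feature marks the excision-junction TA on the
  MAC and carries the germline sequence as an attribute, so MAC + GFF3
  suffice to rebuild the germline.

## Study scenarios and problem sizes

Scenario presets keep runs at desk scale while preserving the structure the
analyses need: `knockdown`/`null` use 500 IESs on a 130 kb replicon at 30X;
the estimator-recovery experiment uses 500 IESs spaced beyond the insert
length (so the enumeration oracle is exact) at 100X; `feature` uses 400 IESs
over 2×200 kb at 40X, with a ~1 kb-spaced background (density classes 0–2)
against ten 1.5 kb dense regions (classes 6+), first-peak weight 0.30
genome-wide vs 0.45 inside dense regions (a deliberately weak confound), and
logistic retention `b0 = −4, b_len = +2, b_dens = +0.65`. The whole-cell
new-MAC fraction defaults to `rho = 0.5` across scenarios.

## Known limitations

* Exact matching presumes error-free reads and identical genome builds; the
  SAM passthrough entry point is an interface stub only.
* `rho` is treated as known when inverting apparent scores; in practice it
  varies between preparations and would itself need estimation (e.g. from
  fully retained control loci).
* Per-IES retention recovery at 100X is bounded by the junction-information
  floor described above; genome-wide summaries are much more precise than
  single-IES estimates.
* Fragment length is fixed (no insert-size distribution); catchment
  geometry under a broad insert distribution would differ slightly near
  replicon ends.
* With a weak planted confound, single matched-sample draws are noisy;
  conclusions should rest on the seed-averaged controls the pipeline
  reports.
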