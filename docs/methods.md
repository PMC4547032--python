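# Methods

This note documents the statistical procedures, conventions and design
choices behind `woodwhite`, and what the packaged tests do and do not
demonstrate.

## Data model and coordinates

A locus is an aligned set of nucleotide sequences (A/C/G/T, IUPAC
ambiguity codes, `-` gaps), anchored to a reference coordinate system:
column 0 corresponds to `ref_start`, a 1-based inclusive reference
position.  All positions in reports are reference coordinates (for the
packaged COI matrix, 1526–2156 on the *D. yakuba* mitochondrial genome,
631 columns); column indices are internal.  Sequences are upper-cased on
load; ambiguity codes are legal input (direct sequencing of multi-copy
genes can produce genuine double peaks) and are handled downstream by
pairwise exclusion rather than rejection.

The reference COI amplicon is described in the source material as 708 bp,
while the deposited/trimmed region spans 631 positions; the extra bases are
primer-flanked sequence outside the trimmed region.  The data model anchors
only the 631-position region.  Digestion operates on whatever amplicon
sequence is supplied, so the published 708-bp fragment patterns are used as
pattern/sum invariants in tests, never recomputed from the trimmed region.

## Polymorphic sites, diagnostic classification, consensus comparison

`build_site_table` collapses identical sequences into haplotypes carrying
specimen lists and tabulates every column with ≥ 2 states.  Columns
containing a gap or ambiguity code in any sequence are retained in the
matrix but flagged and excluded from classification — a conservative choice
that avoids calling diagnostic sites on uncertain bases.

A position is **diagnostic** for two groups iff each group is fixed for a
single state and the two states differ (disjoint singleton state sets).
Mere disjointness is not enough: a site where one group is polymorphic
cannot assign every specimen and is classified *shared*.  On the packaged
matrix this yields 15 diagnostic positions.

**Consensus comparison** builds a majority-rule consensus per group,
weighting each haplotype by its carrier count within that group (a
haplotype shared between groups contributes to both, with per-group
weights).  Ties are broken toward the state shared with the other group's
consensus when it is among the tied states — the conservative resolution
that never manufactures a between-group difference — and otherwise resolve
to the IUPAC code of the tied states; positions whose consensus is
ambiguous are not counted.  Unweighted (one vote per haplotype) mode is
provided and agrees with the weighted mode on the packaged matrix.

On the packaged matrix the two consensuses differ at 18 positions: the 15
diagnostic sites plus 1587, 1674 and 1917, where the minority haplotype of
one group carries the other group's state.  The dataset's original
narrative reports 17 consensus differences (and 22 variable sites, where
the matrix lists 21).  No symmetric majority rule reproduces 17 from the
printed matrix — any rule that counts 1587/1674 (majority fraction 3/4)
must also count 1917 (5/6) — so the package reports the recomputed 18 and
treats the published 17/22 as an internal inconsistency of the printed
table.

**Coding substitutions** are annotated with codon number ⌈pos/3⌉ and codon
position ((pos−1) mod 3)+1.  Synonymy needs the codon context, so it is
determined only when the full CDS is supplied, under an explicit genetic
code: NCBI table 1 (standard) for nuclear genes such as histone H1, table 5
(invertebrate mitochondrial) for COI.

## p-distances

`p_distance` is the uncorrected proportion of differing sites among the
jointly resolved ones; any column where either sequence carries a gap or
ambiguity code is excluded pairwise (the denominator equals the full 631 on
the gap-free reference matrix).  Group summaries average over all
cross-group **specimen** pairs — haplotypes are expanded to their carriers
first — and report the minimum over the same pairs.  Expanding to
specimens is provably equivalent to weighting haplotype pairs by
carrier-count products (tested as an oracle identity).

Two standard errors are attached: the analytic SE of the pair mean (which
understates uncertainty because the pairs share sites and specimens) and a
site bootstrap (columns resampled with replacement, 500 replicates by
default, seeded).  The reference table's printed ±0.006 is on the scale of
the site-bootstrap SE (~0.007 here), but since the original resampling
scheme is unspecified, neither SE is asserted against it.

## CAPS design and the gel model

Recognition sites are matched IUPAC-aware on the top strand; for
non-palindromic enzymes the reverse complement is scanned too and cuts are
placed at the complementary offset.  Overlapping sites all cut (complete
digestion assumed).  Ambiguity codes in the *template* never match — a
phantom marker is worse than a missed one.  Templates are linear (PCR
products); cuts landing exactly on a template end are dropped with a
warning.  Fragment lengths always sum to the template length, an invariant
fuzz-tested against random templates, with `Bio.Restriction` as an
independent oracle for the three stock enzymes.

The **gel model** makes "readable on a 1.5 % agarose gel" explicit:
fragments shorter than `min_detectable_fragment` (default 50 bp) are
invisible; two fragments closer than `min_resolvable_difference` (default
20 bp) co-migrate.  Two patterns are distinguishable iff some detectable
fragment of one has no counterpart within the resolvable difference in the
other; the score counts unmatched fragments on both sides, so a fragment
shared between species (e.g. the common 110-bp CAD fragment) contributes
nothing.  Matching uses sorted greedy pairing, which is optimal for this
interval condition.

A marker is emitted only when the pattern is *fixed within each group* —
a within-group pattern polymorphism would mis-genotype — and
distinguishable between groups.  Ranking is score descending, then total
fragment count ascending (simpler gels first), then enzyme name:
deterministic output.  Genotype calling inverts the model: an observation
matches a pattern when detectable expected and observed fragments pair off
completely within the resolvable difference; zero or multiple matching
patterns yield `ambiguous`.

Out of scope: methylation sensitivity, star activity, partial digestion
kinetics, dCAPS mismatch-primer design, and primer design itself.

## Concordance and prevalence

A specimen's multilocus genotype is *concordant* iff at least two loci
gave non-ambiguous calls and all of them agree; ambiguous or untyped loci
reduce power but never count as conflict.  The discordance rate is
discordant / (concordant + discordant), with a one-sided exact binomial
(Clopper–Pearson) upper bound (default 95 %) — informative precisely when
zero discordance is observed: 0/46 concordant specimens bound the
discordance rate below 6.3 %.

Infection prevalence is positives/tested (untested excluded), reported as
a percentage to one decimal with a Wilson score interval.  Because
screening samples often extend beyond fully-analysed specimens, prevalence
accepts either per-specimen records or pre-tabulated counts; the packaged
screen stores the printed totals (38/42 males, 18/19 females of the united
two-species sample → 56/61 = 91.8 %) alongside the 46 per-specimen rows.
A sex-ratio binomial test against 1:1 among infected specimens is reported
(male-killing endosymbionts would skew it), not used as a criterion.

## Morphometrics

Summaries use the sample SD (n−1).  Report values are rounded **half-up**
to 2 decimals (banker's rounding would alter several cells).  The S/V
ratio is the mean of per-specimen ratios, not the ratio of means, and an
explicitly tabulated per-specimen ratio takes precedence over the
recomputed one (measurement tables round the ratio independently).

Three *t* variants are implemented and labelled, because summary tables
rarely state the formula behind a printed *t*:

* `pooled` — equal-variance *t*, df = n₁+n₂−2;
* `welch` — unequal-variance *t*, Welch–Satterthwaite df;
* `welch_on_rounded_summaries` — Welch's formula on means/SDs first
  rounded half-up to 2 decimals.

The third variant exists to document how printed values arise from rounded
summary tables: it reproduces the reference saccus value 5.60 exactly,
while raw-data pooled/Welch values land within ~6 % (5.28–5.54).  The
reference ductus *t* (9.42) is not reproduced by any of the three formulas
(recomputations 5.3–8.4) and is treated as a documented discrepancy.

φ is reported as |ad−bc|/√((a+b)(c+d)(a+c)(b+d)) — the absolute-value
convention, invariant to swapping group labels or trait codes — with the
uncorrected χ² = φ²·n and its 1-df p-value.  The reference dataset's
hind-wing suffusion φ recomputes to 0.79 from the printed counts (16/0 vs
3/9), not the published 0.73; it is documented and excluded from checks,
which use the reproducible 0.50 (saccus curvature) and 0.29 (fore-wing
apex).

`gap_analysis` reports a hiatus iff the maximum of the lower-mean group is
strictly below the minimum of the higher-mean group; the interval between
them then admits a zero-error threshold classifier (asserted on the
female ductus data: 0.60–0.75 mm).  Otherwise the overlapping interval is
returned.

## Synthetic studies

The generator emulates the *structure* the analysis assumes, at the
reference study's conditions by default:

* sample sizes 16♂+13♀ vs 12♂+5♀; three loci — a maternal 631-bp locus
  with 15 diagnostic and 3-per-species intraspecific sites, biparental
  684-bp (1 diagnostic) and 571-bp (2 diagnostic) loci;
* diagnostic sites fixed-and-disjoint between species; intraspecific sites
  segregate within one species at a minor-allele frequency drawn
  uniform(0.1, 0.5), with the carrier count clamped to keep the site
  actually polymorphic in the sample (the uniform floor is an arbitrary
  but documented choice that makes polymorphism observable at small n);
* introgression modelled as a maternal-locus swap only (mitochondrial
  capture): each specimen is independently introgressed with the
  configured rate, and then carries the other species' states at all
  diagnostic sites of maternal loci — exactly the signature the
  concordance test detects;
* measurements drawn from per-species normals truncated at zero
  (means/SDs defaulting to the reference summary values, mm); binary
  characters and infection states as Bernoulli draws at the reference
  frequencies (91.8 % prevalence).

One root seed feeds independently spawned substreams (introgression,
morphometrics, infection, one per locus), so output is byte-identical
under a fixed seed and components can be regenerated independently.

What the generator does **not** emulate: coalescent genealogies,
recombination, selection, sequencing error, correlated measurement error,
or nuclear introgression.  Passing recovery tests therefore shows the
pipeline is correct under its own assumptions — not that real data meet
them.

Recovery checks (seeded): diagnostic-site counts are recovered exactly at
zero introgression; a 10 % introgression rate at n = 500 is recovered
within 3 binomial SD, with the flagged specimens exactly the planted ones;
simulated group means fall within 3·sd/√n of their targets; the Wilson
interval of a 61-specimen screen covers the configured prevalence.  The
power of the saccus Welch test at the reference effect size
(α = 0.001, n = 16 vs 12) was measured once over 200 seeded replicates and
frozen as a regression value: 0.935.

## Problem sizes and determinism

All reference-dataset computations are desk-scale (631 columns, ≤ 46
specimens) and run in seconds.  Stochastic checks use fixed seeds: the
site bootstrap defaults to 500 replicates; the digestion fuzz test uses
1,000 random templates; the introgression recovery uses one n = 500 study.
Pipeline reruns with identical configuration are byte-identical.

## Known limitations

* The consensus-difference count and the ductus *t* / suffusion φ of the
  reference dataset cannot be reconciled with their published narrative
  values from the printed tables alone (see above); the package reports
  the recomputed values.
* CAPS design on the packaged reference data cannot reproduce the
  published amplicon fragment sizes, because the primer-flanked amplicon
  sequences are not part of the deposited region; the digestion engine is
  validated on synthetic templates and invariants instead.
* The analytic pair-mean SE ignores the dependence between specimen pairs;
  use the site bootstrap when an honest SE matters.
* Concordance bounds only *detectable* introgression: with few loci, old
  or nuclear-only introgression can evade the test.
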