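# Methods

This note documents the models, defaults and design choices behind the
package, in the order data flows through the pipeline.

## Panel model

Target regions are BED-style 0-based half-open intervals; the captured
footprint of a region extends symmetrically by `flank_bp` (default 10 bp,
the designed intronic flank covering canonical splice sites), so a position
is in capture iff it lies in `[start − flank, end + flank)`. Capture
membership queries return a three-valued status — in capture, out of
capture, or *gene not on panel* — because "this panel never targets the
gene" must not be conflated with "targeted but outside the baited design".
Every gene carries exactly one of eleven disease-subgroup labels and one
inheritance mode (AR / AD / XL / other); unknown inheritance strings load
as `other` with a warning rather than failing, since a panel gene with
unclear inheritance must still flow through triage (where it is flagged
for review, never silently passed).

The packaged panels are **synthetic stand-ins**: the full per-gene design
tables were published only as supplementary spreadsheets, so the fixture
contains every gene named in the main text with hand-assigned subgroup and
inheritance, padded per subgroup with `SYN`-prefixed filler genes to the
printed totals (113 / 166, the second version a superset of the first).
Coordinates are synthetic (3–8 single-exon regions of 150 bp per gene, 2 kb
apart). Two structural facts are reproduced because tests depend on them:
only the second design captures intron 1 of UNC13D (so the deep-intronic
regulatory variant is out of capture on the first design), and the six
bait-boosted regions in five genes are marked `boosted` in the second
design.

## Synthetic cohort generator

The generator emulates the *statistics* of a 16-plex targeted capture run,
not reads or alignments. Per-region mean depth is multiplicative:

    depth(sample, region) = target × R(region) × S(sample) × C(sample, region)

with `target = 200x`, region effect `R ~ lognormal(0, 0.35)`, sample effect
`S ~ lognormal(0, 0.10)` and cell-level library/loading noise
`C ~ lognormal(0, 0.15)`. A designated fraction (default 0.022) of regions
is poorly-capturing: their region-level mean is drawn with mean 5x,
truncated at 25x — the generator's encoding of the observed low-coverage
regions. Crucially, the region effect, the low-region set and the
pseudogene (MQ0) set are drawn from a generator seeded by the *panel
design*, not by the run seed: capture efficiency is a property of the
baits, which is what makes per-region coverage highly reproducible between
runs (the packaged default gives between-run Pearson ≈ 0.99; the tests
assert a documented floor of 0.9, frozen after observing the distribution).
Only sample effects, cell noise, read counts and MQ0 jitter vary with the
run seed. Minimum per-base depth is emitted as `mean × Uniform(0.4, 0.8)`
— the coverage unit here is the region record, so the "any single
nucleotide < 30x" rule is operationalised on region minimum depth. Mapped
read counts are Poisson in `mean × length / read_length`, and a cell with
zero mapped reads has its depth forced to zero (the two must agree by
definition).

With these defaults the calibration target holds by construction:
non-designated regions essentially never fall below 30x cohort-mean
(a > 5 σ lognormal excursion), so the fraction above threshold is
1 − 0.022 ± sampling error ≈ 97.8%.

Site pileups are binomial: with true allele fraction `f` and per-base error
`e`, the alternate-read probability is `f(1−e) + (1−f)e/3` (a reference
read errors to this particular alternate base a third of the time). Truth
records materialise at their recorded read depths — germline heterozygotes
at f = 0.5, homozygotes at 1.0, mosaics at their recorded fraction; a
record lacking a depth uses the cohort default 200x with a warning.
Deletion truth records are spiked as zero-read regions. Records outside
the capture design never enter the variant table but stay in the truth
list, so validation can count them as missed for the right reason.

What the generator does **not** model: GC-content structure (region
effects are exchangeable), read-level artefacts, strand bias, mapping
ambiguity beyond a scalar MQ0 fraction, batch effects between runs, and
germline allele-fraction overdispersion. Passing tests therefore show the
pipeline's decision logic is correct under the stated statistical
assumptions, not that those assumptions exhaust real capture data.

## Coverage QC

A region is flagged low when `min_depth < threshold` (default 30, strict
inequality: exactly 30x passes). Because "2.2% of targeted regions" can be
read per sample × region or on cohort means, the summary reports both
granularities plus the any-sample aggregate; `fraction_regions_above` and
`fraction_flagged_by_mean` are exact complements on cohort-mean depth.
Genes with any region whose mean MQ0 fraction exceeds 0.9 are listed
separately as pseudogene-interference genes. Run concordance is the
Pearson (and Spearman) correlation of per-region cohort-mean depths and
requires identical region sets; mismatches are rejected listing the
difference.

## Deletion calling

A cell (sample, region) is called deleted when the sample has at most
`max_sample_reads` (default 0) mapped reads and the leave-one-out cohort
mean depth is at least `min_cohort_mean` (default 30). The cohort guard is
what separates deletions from poorly-capturing regions (cohort mean ~5x);
MQ0-dominated regions (> 0.9) are excluded outright — unmappable, not
deleted. Called regions of a gene merge into one call per sample, labelled
`whole_gene` when every region the caller could assess for that sample
(cohort supports the comparison, not MQ0) is called; assessability rather
than the raw region count is used because a region that happens to be
designated poorly-capturing carries no deletion information either way.
The caller needs ≥ 2 samples by construction and is trivially monotone in
`min_cohort_mean`; with `max_sample_reads = 0` a cohort with no zero-read
cell can produce no call at all.

## Mosaic detection

The test is a one-sided exact binomial tail against the error floor:
`p = P(X ≥ k | n, e)` with defaults `e = 0.001`, `α = 0.001`; `k = 0`
gives p = 1. The upstream pipelines' own mosaic statistics are not
described anywhere, so this test form, the α, and the zygosity bands
(mosaic < 0.30 with significance, het [0.30, 0.85), hom ≥ 0.85, hemi for
X-linked males) are this package's design; the defaults were chosen so the
hardest recorded case — 3% allele fraction at 426x, about 13 alternate
reads against a critical value of 4–5 — is detected with ≥ 95% power,
and all four numbers are configurable. Allele fraction is estimated as
k/n with an exact Clopper–Pearson interval. Power is available analytically
(binomial tail above the critical value, which is found by exact search so
it matches brute-force enumeration) or by seeded simulation; the two agree
within Monte-Carlo error, and power is monotone in depth and fraction up
to the discrete jumps of the critical value.

## Triage and classification

MAF aggregation takes the **maximum** over the three population databases,
with absence everywhere counting as 0 (novel) — the conservative reading
that matches retaining variants absent from all databases. The cascade
removes synonymous variants first, then common ones
(aggregate MAF > 0.01) unless whitelisted; the whitelist is keyed by
(gene, protein change, with an optional `p.` prefix normalised away) and
defaults to exactly the three named low-penetrance alleles. Every input
variant lands in exactly one audit category, and enabling the whitelist
can only grow the retained set.

The recessive rescue re-scan runs after the cascade: for each AR gene in
which a patient retains exactly one heterozygous variant, same-gene
non-synonymous variants are re-admitted from the unfiltered list and
flagged `rescued`. This is what recovers a commoner reduced-penetrance
second hit (the 5'UTR case at MAF 7%) and it deliberately does nothing for
AD/XL genes or for genes already biallelic.

Inheritance consistency: AR + hom, AR + ≥ 2 same-gene hets, AD + any, and
XL hemizygous males are consistent; an AR single het is `carrier_only`;
an XL heterozygous female is `flagged_for_review` (symptomatic carriers
exist); unknown inheritance is always flagged, never passed.

Classification is an ordered rule table over explicit evidence inputs
(published pathogenic report, phenotype concordance, ACMG codes VS/S/M):

| rule | condition | class |
|------|-----------|-------|
| R1 | published pathogenic report | 5 (codes from record) |
| R2 | whitelisted low-penetrance allele, concordant phenotype | 4 (S) |
| R3 | concordant phenotype and (AR-biallelic or ≥ 1 evidence code) | 4 |
| R4 | otherwise (retained rare non-synonymous) | 3 |

Synonymous/common variants never reach the classifier; they appear in the
audit trail with bookkeeping classes 1–2. This is deliberately **not** the
full ACMG 2015 combining algorithm: the expert judgement that a clinical
scientist applies is made explicit input, so replaying the same evidence
always reproduces the same classes, variant order never matters, and the
rule that fired is recorded per variant.

## Validation harnesses

The blinded preset scores truth with deletion calling off, the whitelist
off, no rescue, and every truth record in the denominator; the unblinded
preset turns all three on and restricts the denominator to mutations
inside the capture design (out-of-design variants are not detectable by
construction and are reported separately, not hidden). The rescue re-scan
belongs to the unblinded configuration because it is one of the practical
criteria learned *from* the blinded exercise. A sequence-variant truth
record is detected iff it appears in the run's variant table and survives
the active cascade; detection is therefore threshold-driven at the recorded
read depths, and the blinded count is identical across seeds (asserted over
25 replicates). `n_detected + n_missed` equals the denominator in every
configuration, and missed records carry one of three reasons:
`out_of_capture`, `deletion_no_cnv`, `maf_filtered`.

Cohort yield counts patients with ≥ 1 class-5 and ≥ 1 class-4 variant
(a patient with both would count in each tally; in the encoded cohort the
sets are disjoint). The 31 patients whose class-3-only variant lists exist
only as supplementary summaries are carried as per-patient stubs flagged
`partial` — they contribute to denominators and can never contribute a
class-4/5 finding, which is exactly what their summaries state. The
headline "firm or strongly suspected diagnosis" figure is **not**
hardcoded: patients whose best finding is a recessive single het are
flagged `carrier_only` in the summary note, and whether they count toward
yield is left to clinical judgement.

Run comparison matches retained+rescued variants on (gene, cDNA change)
per shared patient and annotates extras with the other run's coverage of
the gene, since coverage differences are the expected cause of discrepant
calls between panel versions.

## Numerical and procedural choices

* All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; there is no hidden global state, and
  identical parameters give bit-identical outputs.
* Ties and report orderings are lexicographic on (gene, position) or
  (gene, cDNA change).
* Exact binomial tails and Clopper–Pearson bounds come from
  `scipy.stats`; tests verify them against direct pmf summation to 1e-12
  at depth ≤ 30.
* Problem sizes: the synthetic runs use the full 166-gene panel
  (~940 regions × 16 samples), 500 replicates per mosaic power estimate
  and 1000 for estimator-recovery checks — the whole suite runs in a few
  seconds on one CPU.

## Known limitations

* The packaged panels and all coordinates are synthetic stand-ins; only
  gene membership of main-text genes, subgroup totals, and the two
  structural capture facts are faithful.
* The classifier reproduces recorded expert classifications from explicit
  evidence flags; it does not derive evidence from sequence or literature.
* Deletion calling is a zero-read rule, not a general read-depth CNV
  model: heterozygous deletions (reads halved, not absent) are out of
  scope.
* The mosaic test assumes independent reads and a uniform error rate;
  strand bias and UMI/duplicate structure are not modelled.
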