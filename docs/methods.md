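# Methods

This note documents the models, conventions and design choices behind
`crcevo`, in the order the pipeline runs them.

## Scope and data model

The package analyses multiregion biopsy data from colitis-associated
colorectal cancer: per-region somatic mutation calls (SNAs and small
indels with VAF and trinucleotide context), allele-specific copy-number
segments, a genome layout defining chromosome arms, and a reference
mutational-signature matrix.  Read alignment, variant calling and
segmentation are out of scope — calls and segments are inputs.

Coordinates are half-open zero-based internally and 1-based inclusive
on disk (SEG convention); conversion happens only in `crcevo.io`.
Indels carry no trinucleotide context and are excluded from 96-channel
tallies but included as phylogenetic characters.  Sex chromosomes are
flagged non-autosomal and excluded from PGA and arm statistics.
Unknown purity defaults to 1.0 with a logged warning at the call site
that needs it.

## SNA parsimony phylogenies

A mutation is *present* in a region when a call exists there with VAF
at or above the detection threshold (default 0.05).  The character
matrix carries one all-absent germline row that roots every tree.

* **Scoring.** Fitch union/intersection counting for unordered binary
  characters.  Identical columns are collapsed to unique patterns with
  multiplicity weights inside the scorer — an exact transformation
  that makes bootstrap and search cost scale with the number of
  distinct presence patterns.
* **Search.**  Exhaustive enumeration of all (2m−3)!! unrooted
  topologies for up to 7 ingroup regions; otherwise stepwise addition
  from random taxon orders followed by hill climbing over NNI moves
  augmented with leaf re-insertion (prune one leaf, try every
  attachment edge).  20 restarts by default: in randomised checks
  against the exhaustive oracle this configuration attains the global
  minimum in 100/100 instances at 6 ingroup taxa.
* **Ties.**  Among equally parsimonious trees, the lexicographically
  smallest canonical (child-sorted) newick is returned, making every
  search deterministic given its seed.
* **Branch lengths.**  One deterministic most-parsimonious
  reconstruction: downpass Fitch sets, root state forced to the
  outgroup state, uppass preferring the parent's state whenever the
  downpass set is ambiguous.  This is the classic Fitch refinement;
  branch lengths are the weighted Hamming distances between adjacent
  reconstructed states and always sum to the parsimony score.
* **Homoplasy index.**  HI = 1 − CI with CI = Σmᵢ/Σsᵢ; mᵢ = 1 for
  variable binary characters, so HI = 0 iff the matrix is compatible
  with the tree.
* **Bootstrap.**  Character columns resampled with replacement, tree
  rebuilt per replicate (smaller default restart budget, 5), support =
  percentage of replicates containing each split.  Display banding:
  blank > 95, `+` 65–95, `++` < 65.
* **Driver annotation.**  Driver-gene columns are mapped to the
  branches where the reconstruction places their gains; a column
  needing more than one gain is labelled on every gain branch with a
  homoplasy flag.

## Clonality, field and burden

Truncal = present in all carcinoma regions; shared subclonal = more
than one but not all; private = exactly one.  `in_mucosa` is
independent of the pattern; mutations confined to mucosa are
`mucosa_only` and carry no cancer pattern (mutations confined to
LGD/HGD likewise carry none).  Field overlap = fraction of truncal
mutations also in mucosa; undefined (NaN, flagged) without truncal
mutations.

Mutation burden divides the non-synonymous count by an exome footprint
in Mb.  The default footprint of 34.7 Mb is an inferred constant —
chosen so that a ~104-mutation carcinoma works out to ~3 SNAs/Mb — and
is exposed as configuration, as is the hypermutation (MSI-like) flag
threshold of 10 SNAs/Mb, a burden proxy rather than a microsatellite
assay.  CCF estimation uses multiplicity
m = clamp(round(v·(ρc_t + 2(1−ρ))/ρ), 1, max(major, 1)) and reports
both the capped (≤ 1) and raw CCF.  Convergent multi-hit detection
flags genes with ≥ 2 distinct non-synonymous mutations at CCF ≥ 0.8
("near-clonal" is not numerically defined by convention; 0.8 is this
package's documented choice).  The TP53 DNA-binding domain is codons
102–292 inclusive.

## Mutational signatures

Tallies use the fixed pyrimidine-centred channel order (C>A, C>G, C>T,
T>A, T>C, T>G × 16 flank combinations); purine-centred calls are
reverse-complemented, and a context inconsistent with the reference
base after normalisation is an error.  The same genomic mutation seen
in several regions counts once per catalogue.

Exposures solve a non-negative least-squares problem via the
Lawson–Hanson active-set method (scipy), whose pivoting is
deterministic, so fits are bit-reproducible.  R² = 1 − SS_res/SS_tot
with the total sum of squares mean-centred by default; the uncentred
convention is available (`centered=False`) since the choice is not
standardised.  Signature subsets are caller-specified; there is no
automatic model selection.  Epoch fits partition distinct mutations
into precancer (in mucosa), truncal (clonal in the carcinoma, not in
mucosa) and branch (subclonal + private) catalogues; empty epochs are
skipped with a log line.  Absolute exposures are in mutation units;
per-Mb normalisation is left to the caller via the burden footprint.

## Copy-number burden

Gain/loss/cnLOH are called against an absolute diploid-heterozygous
baseline (gain: total > 2; loss: total < 2; cnLOH: total = 2, minor
0).  The absolute baseline is deliberate: near-tetraploid genomes
should count as extensively altered.  A ploidy-relative mode (baseline
= rounded ψ) exists behind a flag for sensitivity analysis.  Ploidy
classes bin ψ as [1.6, 2.4) near-diploid, [2.6, 3.4] near-triploid,
[3.6, 4.4] near-tetraploid, else other; the edges are this package's
choice for categories that are usually reported without thresholds.
Low-pass profiles cannot resolve cnLOH; for them pga_full = pga_gl and
the result carries `cnloh_resolvable=False`.

Arm calls require ≥ 50 % (configurable) of the arm length in one
altered state, with gain/loss taking precedence over cnLOH; arms with
< 10 % segment coverage are excluded from cohort frequency tables.
Cohort arm comparisons run one Fisher 2×2 per arm × direction with BH
correction across all tests; significance at q < 0.05.

## CNA phylogenies and punctuation

Binning: fixed 500-kbp bins tiling the autosomes; a bin's state is the
length-weighted majority total CN of overlapping segments, ties broken
toward the state closer to 2, then lower; bins lacking coverage in any
sample are dropped from all samples, so binning is idempotent on
bin-aligned profiles.

Trees use ordered (Wagner) characters — cost |a−b|, so a 2→4 jump
counts two events — scored by the Sankoff dynamic programme and rooted
at a synthetic diploid reference row.  An unordered mode (any change =
1) is provided for sensitivity, since the appropriate event cost for
copy-number characters is genuinely debatable.  Search, tie-breaking
and bootstrap are identical to the SNA machinery; state reconstruction
breaks ties toward the parent state, then the lower state.  cnLOH is
invisible at total-CN resolution, matching the low-pass dialect.

The punctuation profile takes the smallest clade containing every
HGD/carcinoma sample: `trunk_changes` is the length of the branch
entering it, `mean_clade_changes` the mean branch length inside it,
and the ratio trunk / max(1, mean) separates punctuated histories
(long trunk, short branches; ratios ≫ 10 in burst simulations) from
gradual instability (ratio ≈ 1).  With a single high-grade sample the
clade degenerates to one leaf branch and the profile is flagged
low-confidence.

## Statistical machinery

Implemented in `crcevo.stats` with pinned conventions, cross-checked
in the test suite against scipy/statsmodels and direct enumeration:

* **Fisher exact 2×2**, two-sided by the point-probability (minimum-
  likelihood) rule — the dominant convention, noted because the
  doubling rule differs.  Degenerate margins give p = 1; the odds
  ratio is the sample OR with ∞/NaN handled explicitly.
* **Benjamini–Hochberg**: step-up q₍ᵢ₎ = min₍j≥i₎ p₍ⱼ₎·n/j, capped at
  1, returned in input order.
* **Mann–Whitney U**: exact by full enumeration of the C(n, n_x)
  group assignments when n_x + n_y ≤ 12 (ties handled exactly; the
  two-sided p is P(U ≤ u_min) + P(U ≥ n_x n_y − u_min)); otherwise a
  tie-corrected normal approximation with continuity correction, which
  agrees with enumeration to within 0.01 at n = 6+6.
* **Kruskal–Wallis** H with tie correction and a χ²(k−1) reference.

## The synthetic cohort generator

The source study is observational and specifies no generative model,
so every distributional choice in `crcevo.simulate` is an explicit
stand-in; its value is that all downstream truth is known exactly.

The clone tree is fixed in shape: germline root → field node (mucosa
leaves branch off) → trunk (LGD leaves) → an LGD→HGD transition branch
(HGD leaves) → a random binary subtree over carcinoma regions.
Default region counts (1 mucosa, 1 LGD, 1 HGD, 3 carcinomas) keep the
truth tree binary and the searches exhaustive.

* **SNA counts** are Poisson around per-branch means (exact when
  `noise=False`): field 21, trunk 85, shared branches 15, private
  leaves 30, mucosa-private 26 — chosen so the clonal burden (~106
  non-synonymous mutations, ~3/Mb over 34.7 Mb), the mucosa burden
  (~47) and the field overlap (field / truncal ≈ 15 %) sit at the
  magnitudes reported for this disease, with long trunks and long
  branches.  Branch event order is uniform random.
* **Contexts** are drawn from epoch-specific mixtures over three
  bundled synthetic near-orthogonal signatures (an ageing-like C>T
  profile, a flat C>A profile, and a third disjoint profile); the
  default mixture is 70/15/15 in every epoch.  These are labelled
  synthetic stand-ins — a real reference matrix loads through
  `crcevo.io.read_signature_matrix` but is never required.  Half the
  substitutions are emitted on the purine strand to exercise the
  reverse-complement normalisation.  A branch counts as truncal-epoch
  exactly when every carcinoma region descends from it, so generator
  epochs agree with the classifier's labels by construction.
* **Genome**: 22 autosomes at 10 % of human arm proportions, rounded
  to whole 500-kbp bins (~575 bins) — numerous enough for arm and bin
  statistics, small enough that a full patient simulates in about a
  second.
* **CNAs** accrue as whole-arm gain/loss/cnLOH events (Poisson rates
  per internal branch: 1/1/0.5), optional whole-genome doubling,
  per-bin drift on every branch (mean 5 bins), and an optional
  punctuated burst changing exactly `punctuated_burst_bins` bins on
  the LGD→HGD branch.  Allelic state is tracked per bin as
  (major, minor).
* **Observation model**: VAF = ρ·m/(ρ·c_t + 2(1−ρ)) with m = 1, the
  locus total clamped to ≥ 1 (mutated loci are assumed never
  homozygously deleted, which keeps the pre-noise presence matrix
  perfectly tree-compatible), binomial sampling at depth 100, and
  presence when the sampled VAF reaches the detection threshold.
  `noise=False` switches off both the count dispersion and the VAF
  sampling.

What passing tests on this generator do **not** show: robustness to
caller false positives/negatives beyond binomial VAF noise, spatial
sampling effects, subclonal copy-number mixtures within a biopsy,
selection, or realistic segment-boundary noise.  The generator's
deliberately clean architecture is what makes exact truth-recovery
assertions possible.

## Problem sizes and determinism

The bundled checks run at desk scale: exhaustive-oracle comparisons
use 4–6 ingroup taxa (≤ 945 topologies), truth-recovery sweeps use 100
seeds of the default six-region patient, signature recovery uses 200
seeds of 1000 mutations, and bootstrap defaults to 100 replicates in
the pipeline config (1000 via the CLI flag where a final figure is
wanted).  Every random step takes an explicit integer seed;
per-patient seeds in cohort simulation are derived from the master
seed and logged so any single patient can be re-simulated identically.
Pipeline reruns with the same config are byte-identical apart from
wall-clock timings in the manifest.

## Known limitations

* The heuristic search is exact-by-measurement, not by proof; beyond
  ~10 regions the restart budget, not the enumeration, is the
  guarantee.
* Binary presence/absence discards VAF information; subclonal
  deconvolution from VAF clusters is deliberately out of scope.
* The punctuation ratio presumes the high-grade samples form (nearly)
  a clade; heavily polyclonal patients need the tree inspected
  directly.
* Arm calls use a single-threshold majority rule, not a segmentation-
  aware statistical test; the cohort Fisher comparisons inherit that
  discretisation.
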