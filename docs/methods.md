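# Methods

This note documents the models, defaults, and numerical choices behind
riboscape, and what the synthetic-data generator does and does not
emulate.

## Coordinate conventions

All transcript coordinates are 0-based half-open in transcript space; the
GTF reader converts 1-based inclusive annotation exactly once. A
`TranscriptModel` is the coordinate authority: 5′UTR, CDS and 3′UTR spans
tile the sequence, the CDS is a multiple of 3 and ≥ 6 nt, and starts with
AUG unless flagged. Genes are represented by one canonical transcript;
when a GTF carries several isoforms the longest-CDS transcript is the
natural choice for gene-level work (the simulator emits one transcript
per gene).

## Footprint QC

* **Length filter**: 20–40 nt retained (inclusive), the conventional
  ribosome-protected fragment range.
* **Region assignment** anchors at the raw 5′ end by default — the way
  footprint feature distributions are usually reported — with a P-site
  mode (5′ end + per-length offset) for all frame arithmetic.
* **P-site offsets** are estimated per read length as the argmax over
  candidate offsets 10–15 nt of the meta-count of 5′ ends at
  (CDS start − offset), the initiation-peak heuristic of riboWaltz-style
  tools. Ties break toward 12 nt (the canonical mammalian offset); length
  classes with fewer than 200 reads fall back to 12 and are flagged.
* **Frame** is (P-site − CDS start) mod 3, so frame 0 is the first codon
  position; fractions are reported per length class and pooled.
* **Sample QC** computes Pearson correlations and a 2-component PCA on
  log10(FPKM + 1); the pseudocount of 1 handles zeros and matches the
  usual display convention. Zero-variance genes are dropped before PCA;
  an all-constant matrix is a hard error.

## Quantification

FPKM[g,s] = count · 10⁹ / (library size · length). Effective length is
the CDS of the canonical transcript for the footprint layer (footprints
are counted in ORFs) and the full mature transcript for RNA. TE is
computed per sample and averaged per group for binning — per-sample
ratios keep replicate information that a ratio of group means would
discard. TE is undefined (missing) where RNA FPKM is exactly zero; zeros
in the footprint layer give TE = 0, which is excluded from log₂ binning
and counted. Bin edges follow the four-group convention
log₂(TE) ≤ −1 < ··· ≤ 0 < ··· ≤ 1 < ···, right-inclusive.

## Differential testing

The NB model uses Var = μ + φμ² throughout. Size factors are
median-of-ratios over genes positive in all samples, falling back to
library-size scaling when fewer than 10 such genes exist.

Dispersion: a per-group method-of-moments estimate pooled by degrees of
freedom — per-group, so genuine group-mean shifts do not masquerade as
dispersion — left unclipped so that the mean–dispersion trend
φ(μ) = a/μ + b can be fitted without upward bias (non-negative least
squares on the raw estimates; clipping either the inputs or the fitted
coefficients was measurably biased). The reported per-gene dispersion is
the moment estimate shrunk 50/50 toward the trend. Wald standard errors,
however, use the trend itself except for dispersion outliers (moment
estimate above 3× trend, which keep their shrunk value): with three
replicates the per-gene estimate's noise is correlated with the Wald
numerator, making the plug-in test anticonservative, while flooring at
the trend is conservative. The trend-with-outlier-escape choice holds the
empirical type-I error at ~0.05 in the calibration tests while protecting
genuinely overdispersed genes.

Fitting is IRLS with the NB2 working weight μ/(1+φμ), vectorised across
genes (one batched linear solve per iteration, ridge 10⁻¹⁰, linear
predictor clipped at ±30, convergence at 10⁻⁸); estimates agree with
statsmodels' NB GLM at fixed dispersion to 10⁻⁵. The group coefficient is
tested against the standard normal, two-sided, and BH-corrected (NaN
p-values are excluded from the ranking and propagate). All-zero genes are
flagged with p = 1 and log₂FC = 0. log₂FC is group 2 over group 1 in the
sorted order of group labels.

Differential translation efficiency is the layer × group interaction in a
joint model over both layers' counts with per-layer size-factor offsets
and a four-cell pooled dispersion; log₂FC_TE is the interaction estimate
in log₂ units. This deliberately tests counts, not TE ratios.

Classification applies sig(X) := (|log₂FC| ≥ 1 and FDR < 0.05) to two
contrasts and maps (A only, B only, both-same-sign, both-opposite,
neither) to Transcription / Translation / Homodirection / Opposite /
Unchanged. The ≥ on the fold-change threshold is configurable (some
reports use a strict >). Summaries print counts with percentages rounded
to two decimals.

## Sequence features

GC content excludes ambiguous bases from the denominator. Folding prefers
the external ViennaRNA `RNAfold` binary (batched through one process);
the internal fallback is a Nussinov base-pair maximisation (−1 kcal/mol
per canonical AU/GC/GU pair, minimum hairpin loop 3) — exact for its own
objective and verified against exhaustive enumeration, but carrying no
thermodynamic parameter set; the backend tag is recorded in every result.
NMFE is MFE/length, and "higher NMFE" always means closer to zero.

Because RNAfold is cubic in sequence length (~2 s at 1500 nt), the
pipeline folds a 300-nt 5′ window of the CDS on a stratified random
subsample of 100 genes per TE bin by default; the library folds
full-length sequences up to a 3000-nt guard when asked. Truncation is
flagged per gene. Feature-vs-bin comparisons use Kruskal–Wallis followed
by pairwise Mann–Whitney with BH correction; the compact letter display
assigns letters to the maximal cliques of the non-significance graph at
α = 0.05. Bins with fewer than 3 genes are excluded and reported.

## uORFs

Detection scans 5′UTRs for AUGs with an in-frame stop entirely inside the
UTR (length including stop ≥ 9 nt by default). Nested AUGs sharing a stop
collapse to the most 5′ start; AUGs whose first in-frame stop lies in the
CDS are excluded by default (`allow_overlap` retains them, labelled).

Scores use the established literature definitions: ORFscore
log₂(1 + Σᵢ(Fᵢ−F̄)²/F̄) on P-site frame counts, negated unless frame 0 is
the strict maximum; RRS as in-ORF density over the density of the 5′UTR
gap downstream of the stop (pseudocount 1 on the gap count; undefined for
gaps < 15 nt — the mORF definition's 3′UTR denominator has no direct
uORF analog, so the downstream UTR gap is the closest structural
substitute); the Fickett TESTCODE statistic with the published lookup
tables and weights (position asymmetry max/(min+1) per codon position);
and the mean natural-log ratio of in-frame hexamer frequencies under a
coding model (in-frame CDS hexamers) versus a noncoding background
(Altschul–Erickson dinucleotide-shuffled CDS, seeded), smoothing 10⁻⁶.

A uORF is called translated when ORFscore ≥ 6, RRS ≥ 2, Fickett ≥ 0.74,
hexamer > 0, and mean footprint FPKM ≥ 1 (uORF FPKM uses footprint counts
over uORF length with total mapped footprints as library size). The
thresholds are configurable; missing scores fail the rule. Kozak contexts
are the fixed −6…+4 window (A of AUG = +1, N-padded at transcript caps);
PWMs exclude N position-wise, and two sets are compared per non-AUG
position by chi-square on base counts. Distance analyses use the most 3′
uORF per gene, with distance (CDS start − uORF end) normalised by 5′UTR
length. uORF–mORF relationships report Pearson correlation of aligned
log₂FCs, simple regressions of gene TE on uORF features, and two-sample
KS tests of TE stratified by uORF class; fewer than 10 pairs suppresses a
statistic with a warning.

## Synthetic data

The generator emulates the structure of a 2-group × 3-replicate
testis study. Defaults, chosen once as the study conditions:

* 2000 genes; 5′UTR 100–500 nt, CDS 300–3000 nt (AUG…stop, no internal
  in-frame stops), 3′UTR 100–500 nt. CDS codons are drawn from a
  position-biased codon usage (distinct base weights per codon position)
  so that coding sequence carries the positional asymmetry and hexamer
  structure real CDS has.
* RNA baseline means are lognormal around 500 counts (σ = 0.8); counts
  are gamma–Poisson (NB) with φ = 0.1 and lognormal per-sample size
  factors (σ = 0.1).
* Planted categories Transcription/Translation/Homodirection/Opposite/
  Unchanged at 15/10/15/2/58% with |log₂FC| = 2 and random signs;
  Opposite is deliberately the rarest class, as observed in this kind of
  study. Transcription-planted genes shift the RNA layer only — an equal
  shift in both layers would be indistinguishable from Homodirection, so
  only the RNA-only reading makes the category recoverable.
* Footprints: one per RIBO count unit (per-sample totals are conserved);
  90% placed in the CDS with frame-0 probability 0.9, the rest uniform
  over UTRs; lengths 20–40 nt with modes at 28 and 30; 5′ end = P-site −
  12 nt for every length.
* 30% of sufficiently long 5′UTRs carry one planted AUG uORF (51–198 nt
  incl. stop, TAA); 30% of those are translated. Translated uORFs are
  planted shorter (≤ 120 nt) and nearer the CDS, use coding-like codons,
  and receive 15× the UTR background footprint density with uORF-frame
  periodicity — i.e. they capture roughly 15–20% of their gene's
  footprints, the strong periodic occupancy a translatability screen is
  designed to detect. Untranslated uORFs get background-level uniform
  coverage and uniform-random codons. Background UTR sequence is scrubbed
  of AUGs, so the planted uORF set is exactly the detectable set.

Not emulated: alignment artifacts, rRNA contamination, multi-isoform
genes, codon-level dwell-time variation, and sequence-level determinants
of expression. Passing recovery tests therefore demonstrates that the
algorithms are correct and calibrated under the stated generative model,
not that they are robust to every artifact of real libraries.

Determinism: a single seed fans out to fixed per-stage substreams
(`default_rng([seed, stage])`), so identical configs give byte-identical
outputs on any platform; the end-to-end demo is checksum-stable across
runs.

## Problem sizes

The test suite and acceptance script run the default 2000-gene study
(≈7M footprints, ~1 minute end to end), 2000-gene calibration nulls, a
600-gene interaction-power design (300 affected genes — with 300 planted
among 2000 the BH multiplicity burden caps a calibrated interaction
test's recovery near 0.82, so the balanced design is used for the power
check), and 200-case folding-oracle comparisons at ≤ 12 nt.

## Known limitations

* The NB framework is a documented re-implementation, not DESeq2/RiboDiff;
  gene lists will not numerically match those tools (a cross-check test
  shows rank agreement with DESeq2 on strong effects).
* The internal folding backend maximises pairs, not free energy; NMFE
  comparisons across TE bins are only as thermodynamic as the backend
  used.
* uORF translatability thresholds are screen conventions, not calibrated
  probabilities; on real data they should be tuned against positive
  controls.
* Single-transcript genes only; genome-space coordinates are out of
  scope (footprints arrive in transcript space).
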