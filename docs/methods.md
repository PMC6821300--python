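# Methods

## The generative model

All recovery tests rest on one generative model of quartet gene-tree
discordance. For a quartet (P1, P2, P3, O) embedded in an eight-taxon
species tree with topology ((P1,P2),P3) on the ingroup side, each locus
draws a hidden genealogy class:

| class        | probability  | informative pattern |
|--------------|--------------|---------------------|
| concordant   | 1 − g − 3q   | BBAA                |
| ils_bbaa     | q            | BBAA                |
| ils_abba     | q            | ABBA                |
| ils_baba     | q            | BABA                |
| introgressed | g            | ABBA                |

with q = (1/3)·exp(−t_internal) the probability of each of the three
ILS resolutions of an internal branch of length `t_internal` (coalescent
units), and g = γ·(1 − 3q) the excess of (P2,P3) genealogies
attributable to gene flow at admixture proportion γ. The parametrisation
g = γ(1 − 3q) makes γ the fraction of the *non-ILS* genealogies that are
introgressed, so the class simplex is valid for every γ ∈ [0,1] and
t ≥ 0, and the D-statistic has the closed form

    E[D] = g / (g + 2q)

(the BBAA classes cancel; the two symmetric ILS classes contribute 2q to
the denominator). This closed form is the oracle for every parameter
recovery test: it is computed independently of the estimators it checks.

Three output modes share the model and one seed:

* **Pattern mode** (`simulate_locus_patterns`): each locus's informative
  site count is Poisson with mean `mut_rate · sites_per_locus`, and all
  its sites carry the class pattern. This is the exact regime for
  estimator calibration — no homoplasy, no alignment noise.
* **Alignment mode** (`simulate_cluster_alignments`): a random stop-free
  codon sequence evolves down the class's gene tree. Attempted
  single-base mutations arrive as Poisson(branch length × sites);
  mutations creating stop codons are resampled; a nonsynonymous change
  is accepted with probability min(1, ω) and a synonymous one with
  probability min(1, 1/ω), so the realised nonsynonymous/synonymous rate
  ratio equals ω in both the ω ≤ 1 and ω > 1 regimes. Each locus is
  neutral (ω = 1) or selected (ω = `omega_selected`) with probability
  `frac_selected`. Homoplasy adds a small symmetric ABBA/BABA background
  that dilutes D slightly relative to the closed form; pattern mode is
  therefore used wherever the closed form is asserted tightly.
* **Frequency mode** (`simulate_window_frequencies`): SNPs along one
  synthetic chromosome, `snps_per_window` per window. Inside planted
  tract windows (a `tract_fraction` share, default 20%) loci follow the
  full mixture at γ; elsewhere γ = 0. The class determines a base
  derived-frequency vector over (P1,P2,P3,O); the population's true
  frequency is Beta-distributed around it (concentration 20, base
  shrunk to [0.05, 0.95]) and the observed frequency is a binomial draw
  over `n_chrom_per_pop` haplotypes. At `n_chrom_per_pop = 1` all
  frequencies are 0/1 and the frequency-form D reduces exactly to the
  count form.

Defaults: `gamma = 0.1`, `t_internal = ln 2` (q = 1/6, a regime where
ILS and introgression are comparable and neither dominates),
`mut_rate = 0.02` (≈2% informative sites per locus, typical of
transcriptome divergence at this depth), `sites_per_locus = 900`
(300 codons, matching the ~1 kb mean CDS of assembled eye
transcripts), `omega_selected = 5`, `frac_selected = 0.05`,
`n_chrom_per_pop = 10`, `window_size = 50 000` bp. Taxon labels default
to the seven ingroup species plus the outgroup, with the quartet
(sara, hortense, erato | iulia).

What the simulator does **not** emulate: recombination within loci,
demographic size changes, linked selection, alignment error, assembly
artefacts, and multi-copy gene families. Passing tests therefore
demonstrate estimator correctness and calibration under the stated
mixture, not robustness to real-data nuisance processes.

## Estimators and numerics

**D-statistic.** Both forms are ratios of sums across blocks (clusters
or windows), never means of per-block ratios; the distinction matters
whenever block sizes vary (blocks [(3,0),(0,1)] give 0.5 by ratio of
sums, 0.0 by mean of ratios). The jackknife is the delete-one Tukey
form: θ₍ᵢ₎ recomputed with block i removed,
SE = sqrt(((n−1)/n)·Σ(θ₍ᵢ₎ − θ̄)²). Deletions that empty the denominator
are skipped with a warning and n adjusted; fewer than two usable
deletions is an error. Significance is z = D/SE against a standard
normal, two-tailed, with stars at 0.05/0.01/0.001. A zero SE with
nonzero D is reported as p = 0 with a `degenerate` flag rather than a
crash. In window mode, per-window SEs jackknife over SNPs within the
window, and the chromosome-level statistic jackknifes over whole
windows.

**Windows.** Non-overlapping tiles, 0-based half-open [k·w, (k+1)·w);
a SNP at position p belongs to window ⌊p/w⌋. Coordinates are 0-based
half-open everywhere internally.

**Polarization.** The outgroup allele is ancestral, always — even when
the outgroup carries the globally rarer allele. Columns with gaps,
ambiguity codes, three or more alleles, or a missing outgroup call are
excluded, with missingness judged listwise within the active quartet
only. Ambiguity codes are treated as missing because single-individual
transcriptome consensus sequences are effectively haploid calls.

**NG86 Ka/Ks.** Site counts weight each codon position by the fraction
of non-stop single-base changes that are synonymous (changes to stop
codons are excluded from numerator and denominator); substitution counts
average synonymous/nonsynonymous assignments over all k! orderings of
the k differing positions, excluding orderings that pass through a stop
codon (under the standard code every sense-codon pair retains at least
one stop-free path; the skip-and-flag branch is defensive). Rates use
the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p), flagged
`saturated` at p ≥ 3/4. Gapped codon columns are removed pairwise before
counting. The ratio is defined only for Ks > 0, unsaturated, Ks ≤ 2
(configurable cap). Per-pair ratios are upward-biased at low divergence
(noise in 1/Ks); tests that assert the neutral centre use ≥200 pairs of
≥300 codons where the bias is within a few percent.

**Screen.** A (cluster, pair) is a candidate when ratio > 1, the
ungapped aligned fragment is ≥ 100 bp and Ks passes the saturation cap.
This operationalises a manual-curation step as explicit, logged filters.
With a neutral background (ω = 1) roughly half of all pairs exceed 1 by
sampling noise, so candidate counts on synthetic data are dominated by
that false-positive rate; the meaningful statistic, and the one tested,
is the enrichment of truly selected loci among hits (odds ratio).

**Branch-test plan.** The fixed ingroup topology is
`(iulia,((erato,(sara,hortense)),(doris,(hecale,(cydno,melpomene)))))`;
foregrounds are the 8 terminal branches plus the internal clades
(sara,hortense), (erato,sara,hortense), (cydno,melpomene) and
(hecale,cydno,melpomene). Each (candidate, foreground) row carries a
newick with the foreground tagged `#1` for an external likelihood
engine; computing branch-site likelihoods is explicitly out of scope.

**BH FDR.** Step-up: largest k with p₍ₖ₎ ≤ k·q/m; everything at or below
that p₍ₖ₎ is rejected and the threshold itself is returned, since the
adjusted cut-off is often the quantity reported.

## Orthology

The similarity scorer is a k-mer-seeded (k = 11) ungapped diagonal
score, match +1 / mismatch −1, over the full overlap of every seeded
diagonal; the best diagonal wins (ties to the longer overlap, then the
smaller offset). Significance is the Karlin–Altschul-style surrogate
L_q·L_t·2^(−score) with a default acceptance threshold of 1e−6, which
admits unrelated random 500-bp pairs at well under 1% (measured 0/1000
in the test suite) while retaining 5%-diverged copies comfortably.
Reciprocal best hits require mutual uniqueness after deterministic
tie-breaking (score, then aligned length, then lexicographic id).
Clusters are cliques over all 28 species pairs, seeded from the first
species in config order; a `star` mode relaxes this to reciprocal best
hits against one hub species. Each gene joins at most one cluster;
multi-copy families that break the clique are dropped rather than
collapsed — the conservative reading when paralog resolution is not
attempted. The ortholog hit ratio (aligned length / reference CDS
length) is capped at 1 with an overhang flag.

## Pipeline

One YAML config drives simulate → cluster → dstat → kaks → plan. A
single master seed derives independent per-mode substreams
(`SeedSequence([seed, stream])`), so rerunning any stage subset with the
same config is byte-identical. Failures rename the failing stage's
outputs to `*.partial` and abort naming the stage. The run report
reconciles counts across stages (pairwise rows = clusters × 28, planned
tests = candidates × foregrounds, SNP rows = SNPs × 4 populations) and
records content digests of every artifact.

## Problem sizes

Calibration suites run at the sizes where their guarantees are stated:
null calibration at 2,000 loci × 500 seeds, parameter recovery at 5,000
loci × 100 seeds per γ ∈ {0, 0.05, 0.1, 0.2}, selection recovery at 250
loci × 300 codons, orthology recovery at 25 clusters × 8 species. These
are the package's reference experiment sizes; the NG86 oracle check is
exhaustive over all 61 × 61 sense-codon pairs.

## Known limitations

* The alignment-mode D is mildly diluted by homoplasy relative to the
  closed form; quantitative recovery claims are made in pattern mode.
* NG86 differs numerically from Li-family Ka/Ks methods, so ratios are
  not directly comparable to values computed with those estimators.
* The scorer's ungapped diagonals assume colinear, indel-free CDS pairs
  (true of the simulator's output); genes with large indels would need a
  gapped aligner plugged into the scorer interface.
* The window-mode drift model is a two-parameter Beta-binomial, not a
  coalescent; window-level D magnitudes are not calibrated to any
  particular demography.
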