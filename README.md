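# retinet

Reticulate-evolution analysis of multi-species transcriptomes: ortholog
clustering, ABBA/BABA introgression tests, and a Ka/Ks positive-selection
screen, with a synthetic-data generator that carries known ground truth.

## The problem

When a clade of closely related species — here modelled on a genus of
eight butterfly species, seven ingroup taxa plus one outgroup — shows
conflicting phylogenies between nuclear transcriptomes, mitochondria and
whole genomes, the discordance can come from incomplete lineage sorting
(ILS), from interspecific gene flow, or both. `retinet` implements the
comparative pipeline used to tell these apart from expressed-gene data:

1. **Orthology.** One CDS per gene per species (longest isoform); genes
   are clustered as cliques of reciprocal best hits (RBH) present in all
   eight species, with an "ortholog hit ratio" completeness diagnostic.
2. **Introgression.** Patterson's D over a quartet (P1, P2, P3, O):

   *count form* (per-cluster site tallies)

       D = Σᵢ [C_ABBA(i) − C_BABA(i)] / Σᵢ [C_ABBA(i) + C_BABA(i)]

   *frequency form* (per-SNP derived-allele frequencies p̂ᵢⱼ, used in
   50-kb genomic windows)

       abbaᵢ = (1−p̂ᵢ₁) p̂ᵢ₂ p̂ᵢ₃ (1−p̂ᵢ₄),   babaᵢ = p̂ᵢ₁ (1−p̂ᵢ₂) p̂ᵢ₃ (1−p̂ᵢ₄)

   Both are ratios of sums over blocks (clusters or windows). Standard
   errors come from a leave-one-out jackknife over blocks and D ≠ 0 is
   assessed with a two-tailed z-test. Under ILS alone E[D] = 0; an
   excess of ABBA over BABA indicates P2–P3 gene flow.
3. **Selection.** Pairwise Ka/Ks by the Nei–Gojobori (1986) method —
   degeneracy-weighted site counts, path-averaged substitution counts,
   Jukes–Cantor correction — over all 28 species pairs per cluster;
   pairs with Ka/Ks > 1 (quality-filtered) nominate candidate clusters,
   which are expanded into a branch-site test plan (8 terminal + 4
   internal foreground branches per cluster) for an external likelihood
   engine. Benjamini–Hochberg FDR utilities are included.

The synthetic-data generator produces all three input kinds from a
gene-tree mixture with introgression proportion γ and an internal branch
length t controlling ILS; the mixture has the closed form
E[D] = g/(g + 2q) with q = (1/3)e^(−t) and g = γ(1 − 3q), which anchors
every recovery test. See `docs/methods.md` for the model in full.

## Worked example

```python
import math
from retinet import QuartetAssignment, d_test, expected_d, kaks
from retinet.simulate import SimulationConfig, simulate_locus_patterns

cfg = SimulationConfig(n_loci=5000, gamma=0.2, seed=1)
blocks = [counts for _, counts in simulate_locus_patterns(cfg)]
res = d_test(blocks, QuartetAssignment(*cfg.quartet))
print(f"D = {res.d:.4f} +/- {res.se:.4f} (z = {res.z:.2f}, p = {res.p_two_tailed:.2e} {res.stars})")
print(f"closed-form E[D] at gamma=0.2: {expected_d(0.2, math.log(2)):.4f}")

r = kaks("TTTGCAATGGGG", "TTCGCAATGGGG")
print(f"Ka = {r.ka:.4f}, Ks = {r.ks:.4f}, Ka/Ks = {r.ratio:.4f}")
```

prints

```
D = 0.2067 +/- 0.0218 (z = 9.47, p = 2.76e-21 ***)
closed-form E[D] at gamma=0.2: 0.2308
Ka = 0.0000, Ks = 0.6355, Ka/Ks = 0.0000
```

The simulated D at γ = 0.2 sits within 1.1 jackknife SEs of the mixture
expectation and is overwhelmingly significant, as it should be for 5,000
loci with this much gene flow. The four-codon Ka/Ks pair differs by one
synonymous transition (TTT→TTC), so Ka = 0 while Ks reflects one change
over 7/3 synonymous sites after Jukes–Cantor correction.

The same analyses are available from a shell:

```sh
retinet run --config pipeline.yaml --out results/
retinet simulate clusters --out sim/ --seed 1
retinet dstat windows --snps sim/snps.tsv --pops sara,hortense,erato,iulia
retinet kaks --clusters sim/ --out kaks.tsv
```

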