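# iloci

Prioritization of SNP–SNP interactions in case/control genome-wide
association studies (GWAS).

Single-locus GWAS misses epistasis — joint effects of locus pairs on
disease risk.  Exhaustive pairwise interaction testing at genome scale
faces two problems: the sheer number of pairs (N(N−1)/2 ≈ 1.25×10¹¹ for
500k SNPs), and the flood of pairwise dependence signals that have nothing
to do with disease (linkage disequilibrium, population structure, calling
artifacts).  This package implements a contrast-based prioritization
scheme for researchers analyzing case/control SNP array data or
benchmarking epistasis-detection methods on simulated data.

## Method

Genotypes at a biallelic SNP are coded homozygous wild *w*, heterozygous
*h*, homozygous variant *v* and encoded numerically as −1, 0, +1.  For a
SNP pair (x, y), within one phenotype group, the dependence statistic is
computed from the 3×3 joint genotype probability table P(x, y):

```
ρ = (P_ww − P_wv − P_vw + P_vv) / sqrt( (P_x=w + P_x=v) · (P_y=w + P_y=v) )
```

equivalently E[xy] / √(E[x²]·E[y²]) on the encoded values.  ρ is computed
separately in cases and controls, and pairs are ranked by the contrast

```
ρ_diff = | ρ_control − ρ_case |
```

Dependence shared by both groups (LD and friends) cancels in the contrast;
disease-coupled dependence does not.  The top-K pairs (default K = 1000)
are reported with upper-tail P-values from a Weibull(k = 1, λ = 0.018)
model of the genome-wide ρ_diff distribution, plus "hub" SNPs that recur
across many top pairs.  Ranking, not a P-value cutoff, is the interface:
the ρ_diff distribution is heavy-tailed and cutoffs admit millions of
pairs.

The package also contains a penetrance-model simulator (HWE genotype
sampling + rejection to exact case/control quotas, including multi-locus
interaction networks composed from pairwise tables) and an evaluation
harness implementing the standard accuracy rules for single-pair,
multi-pair, and higher-order network detection scenarios, plus ROC curves
over ρ_diff thresholds.

## Worked example

Simulate a strong two-locus pure-epistasis dataset (800 cases, 800
controls, 100 SNPs; disease loci embedded at indices 33 and 66), scan all
4950 pairs, rank, and evaluate:

```
$ iloci simulate --model src/iloci/models/pure_epistasis_strong_maf02.txt \
      --n-case 800 --n-control 800 --n-snps 100 --seed 7 --out-prefix sim
simulated 100 SNPs x 1600 samples (800 cases, 800 controls) -> sim.geno.tsv
$ iloci scan --genotypes sim.geno.tsv --labels sim.labels.tsv --out sim.pairs.tsv
scanned 4950 pairs over 100 SNPs (0 degenerate pairs excluded from ranking) -> sim.pairs.tsv
$ iloci rank --pairs sim.pairs.tsv --top-k 10 --out sim.ranked.tsv --hubs sim.hubs.tsv
top 10 pairs: 1st rho_diff=0.55756 (P=3.5305e-14), 10th rho_diff=0.26892 (P=3.2481e-07), mean=0.30728 sd=0.088263
$ iloci evaluate --ranked sim.ranked.tsv --truth sim.truth.json
scenario=single_pair correct=yes
```

The rank-1 pair is the true disease pair (snp034, snp067): its ρ_diff of
0.558 — cases strongly enriched for concordant homozygotes, controls near
the background dependence level — stands far above the best background
pair (≈0.29, pure sampling noise at n = 800 per group).  The attached
P-value 3.5×10⁻¹⁴ is the Weibull upper tail at that score.
`sim.hubs.tsv` lists SNPs by their degree among the ranked pairs, and
every command writes a `*.manifest.json` recording parameters and seed,
sufficient to reproduce its output byte-for-byte.  The same scan output is
obtained for any `--chunk-size` and `--workers` setting: pair tallies are
accumulated in exact integer arithmetic.

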