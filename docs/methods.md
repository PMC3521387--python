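# Methods

## The dependence statistic and its contrast

Each biallelic SNP is treated as a discrete random variable over the three
genotype classes, encoded w → −1, h → 0, v → +1.  For a pair (x, y) within
one phenotype group, the statistic is the closed form on the 3×3 joint
genotype table

ρ = (P_ww − P_wv − P_vw + P_vv) / √((P_x=w + P_x=v)(P_y=w + P_y=v)),

which is E[xy]/√(E[x²]E[y²]) on the encoded values.  Two properties of
this form matter in practice and are deliberate:

* **No mean-centering.**  The encoded genotype mean is 2q − 1 (q the
  variant-allele frequency), which is zero only at q = 1/2; ρ therefore
  is *not* a Pearson correlation and is nonzero even for independent SNPs
  (under independence ρ = E[x]E[y]/√(E[x²]E[y²])).  The closed form above
  is implemented verbatim, without centering.  The method's signal is
  never ρ itself but the case/control contrast ρ_diff = |ρ_control −
  ρ_case|: any dependence level shared by the groups — including the
  nonzero independence baseline, linkage disequilibrium, structure —
  cancels in the contrast, while disease-coupled distortions of the joint
  genotype distribution in cases do not.
* **Only homozygote cells enter.**  Heterozygotes encode to 0, so ρ is
  driven by the four homozygote–homozygote joint cells and the homozygote
  marginals.  Consequently (a) ρ is undefined when a SNP has no
  homozygotes within a group (zero marginal factor) — such pairs are
  marked invalid, excluded from ranking, and counted in the scan summary,
  since no finite score is faithful and silently emitting 0 would pollute
  the ranking; and (b) penetrance patterns that only redistribute
  heterozygote mass (e.g. XOR-style checkerboards) are invisible to the
  statistic.  The shipped "strong" simulation models concentrate risk on
  concordant homozygotes, which is the kind of epistasis the statistic
  detects.

ρ ∈ [−1, 1] by Cauchy–Schwarz, so ρ_diff ∈ [0, 2].  Swapping a SNP's
wild/variant labels maps codes 0↔2, negating ρ in both groups
simultaneously and leaving ρ_diff unchanged; the major-allele = wild
convention (lexicographic tie-break) therefore affects only
reproducibility of signs, never ranking.

## The exhaustive scan

All N(N−1)/2 unordered pairs are scored.  Missing genotypes are handled
pairwise complete-case per group per pair — the least-assumption choice,
and the per-pair n_used is reported.  The SNP range is split into blocks
of at most `chunk_size` SNPs (default 10,000, a desk-scale memory bound)
and block pairs are scored independently, optionally in parallel.  All
tallies — joint counts, homozygote marginals, complete-case sizes — are
exact int64 dot products, and ρ = S_xy/√(S_xx·S_yy) is formed once per
pair from those integers, so results are bit-identical for every chunk
size and worker count; parallelism can only change wall-clock time.  The
CLI writes pairs in canonical (i, j) order, making output files
byte-reproducible too.

## Ranking and P-values

Pairs are ranked by ρ_diff descending (ties broken by ascending pair
index; ties are not otherwise meaningful), default top-K = 1000.  Tail
probabilities come from a Weibull with shape k = 1 and scale λ = 0.018 —
the published fit to the pooled genome-wide ρ_diff distribution of seven
large case/control cohorts — taken as configuration, not refitted here.
The default evaluation computes the tail as 1 − CDF with the CDF itself
formed as 1 − exp(−(x/λ)^k) in double precision.  The double rounding
quantizes extreme tails to multiples of the unit roundoff (2.2204×10⁻¹⁶
at score 0.65) and underflows to exactly 0 near 0.70 — reproducing the
published lookup table digit-for-digit, which is why it is the default.
`exact_sf` mode returns exp(−(x/λ)^k) directly (log P = −x/λ at k = 1)
and is the numerically preferable choice for downstream arithmetic.  No
multiple-testing correction is applied anywhere: the heavy tail makes
fixed cutoffs uninformative, and rank is the interface.

Hub SNPs are SNPs of high degree in the top-K pair list; degrees over all
ranked pairs sum to 2K.  The top-K summary reports the 1st and K-th
scores with their P-values and mean ± SD (sample, n−1 denominator; the
convention is not externally fixed, so it is simply stated here).

## The simulator

Individuals are independent draws: each locus samples a genotype under
Hardy–Weinberg equilibrium from its variant-allele frequency q
((1−q)², 2q(1−q), q²); background loci draw their MAFs uniformly from
(0.05, 0.5), matching the MAF > 0.05 analysis regime; disease status is
Bernoulli(penetrance at the disease-locus genotypes); and rejection
sampling runs until exactly n_case cases and n_control controls exist
(budget 10⁸ draws, guarding against near-degenerate models).  Disease
loci sit at fixed, evenly spaced indices recorded in a truth sidecar —
placement has no effect on the statistic, and fixed positions simplify
truth bookkeeping.  Default dataset sizes follow the standard validation
protocol: 800+800 samples × 100 SNPs for two-locus scenarios, 400+400 for
network scenarios.

Multi-locus network models list pairwise 3×3 tables over named loci and
are composed into a joint 3^L table by the heterogeneity rule
1 − Π_edges(1 − p_edge) — each edge an independent route to disease, the
standard composition in the multi-locus simulation literature — with a
multiplicative alternative (Π p_edge, rescaled by its maximum into
[0, 1]).  Shipped model files are synthetic reconstructions of classic
model families (concordant-homozygote pure epistasis at MAF 0.2, a
multiplicative marginal-effect model at MAF 0.5, a 4-locus heterogeneity
chain at MAF 0.25), labelled as such; they are templates, not verbatim
published tables.

What the simulator does *not* emulate: linkage disequilibrium between
background SNPs, population structure, genotyping error, missingness.
Background pairs are therefore exactly independent, so simulated power
results show detection against pure sampling noise; on real data the
contrast must additionally cancel LD structure, which these tests do not
exercise (the cancellation argument — both groups share the LD — is
structural, not empirical, here).

## Evaluation rules

Per-dataset correctness follows the standard protocol definitions:
single-pair — the true pair is rank 1 (sharing one SNP is insufficient);
multi-pair — every disease SNP appears within the top five pairs;
higher-order — the maximal ranking prefix in which every pair contains at
least one disease SNP must cover all disease SNPs.  The higher-order
phrasing ("all consecutive top pairs") admits laxer readings that allow
interleaved background pairs; the prefix form is the strictest consistent
reading and is the one implemented.  Accuracy is the percentage of
replicate datasets judged correct.  ROC curves sweep a ρ_diff threshold
t over the exact empirical grid of observed scores: sensitivity is the
fraction of true interacting pairs with ρ_diff ≥ t, specificity the
fraction of all other valid pairs with ρ_diff < t; disease-SNP ×
background-SNP pairs count as negatives.  The minimum threshold reaching
sensitivity 1 (the smallest true-pair score) is reported alongside.

## Numerical and interface choices

* Probabilities and ρ in double precision throughout; no fast path.
* Genotype codes: int8 matrix, −9 missing; biallelic only — multiallelic
  SNPs are rejected rather than recoded, since the 3×3 model is biallelic
  by construction; phenotypes must be binary case/control.
* Coordinates 0-based half-open internally; PLINK .map positions
  (1-based) converted on read; BED intervals native.  MAF filtering uses
  a strict inequality (MAF > t) on pooled allele counts.
* Test and acceptance problem sizes (100-replicate batches at 100 and 50
  SNPs) mirror the validation protocol's dataset shape while keeping the
  full suite under a minute; the scan is O(N²) and these sizes are
  representative, not limits.

## Known limitations

Heterozygote-only epistasis patterns are undetectable by construction.
ρ_diff magnitudes depend on heritability and MAF, so no universal
threshold separates signal from noise — ranking depth is the user's
choice.  P-values are descriptive (distribution-fit), not
familywise-calibrated.  The simulator's independence assumptions mean
reported accuracies are upper bounds relative to LD-dense real panels.
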