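# Methods

## Statistical model for differential expression

Counts are modelled negative-binomially: $K_{gj} \sim \mathrm{NB}(\mu_{gj},
\alpha_g)$ with $\mathrm{Var}(K) = \mu + \alpha\mu^2$ and
$\mu_{gj} = s_j q_{g,\mathrm{group}(j)}$, where $s_j$ is a per-sample size
factor and $q$ a group-level normalized mean. Only two-group contrasts are
fit — the four contrasts of the study design (knockout vs. wild type at
early and late passage under vehicle; tunicamycin vs. vehicle within wild
type; knockout vs. wild type under tunicamycin) are each tested separately,
and BH adjustment is applied per contrast. There is no GLM machinery for
covariates, no independent filtering and no fold-change shrinkage: the
point is a transparent test whose every number can be recomputed by hand.

**Size factors** are the classical median-of-ratios: for reference genes
(strictly positive in all samples), $s_j = \mathrm{median}_g\,
K_{gj}/(\prod_{j'} K_{gj'})^{1/m}$, with lower interpolation at ties and a
final rescaling to geometric mean exactly 1. A dataset with no all-positive
gene is rejected rather than silently falling back to a pseudo-reference.

**Dispersions.** The gene-wise method-of-moments estimate on normalized
counts, pooled over replicate groups with $\ge 2$ samples and clipped at
zero, is extremely noisy at typical replication (2–4 residual df), and
plugging it into a Wald test unshrunk inflates the type-I error to ~9%.
Estimates are therefore shrunk in log space toward a **Cox–Reid adjusted
pooled-likelihood common dispersion** (the estimator familiar from edgeR's
`estimateCommonDisp`): group means are profiled at their normalized sample
means and the penalty $\tfrac12 \log \sum_j w_j$ per gene and group (with
NB GLM weights $w = \mu/(1+\alpha\mu)$) removes the downward bias of plain
profiling. An earlier candidate target — the trimmed mean of
$\log\hat\alpha$ — is biased low by roughly 20% at these df (the log of a
noisy, floored estimator) and was discarded for miscalibrating the test.
The default shrinkage weight is 0.9: measured on null simulations at
dispersion 0.05 and n = 3 vs 3, this gives a p < 0.05 fraction of ~0.06 and
≤ 3 BH discoveries per 2,000 genes, while retaining some gene-wise signal
for heterogeneous dispersions. Weight 1.0 gives exact calibration at the
cost of assuming a shared dispersion; the weight is exposed. Estimates are
floored at 1e-8; genes whose raw estimate is non-positive sit at the floor
before shrinkage, so Poisson-like data yields near-floor dispersions.

**Wald test.** The log2 fold change is the log2 ratio of group means of
size-factor-normalized counts, $\hat q = \frac1n \sum_j K_{gj}/s_j$. By the
delta method, $\mathrm{Var}(\ln \hat q) = n^{-2}\sum_j (1/(q s_j) +
\alpha)$; the statistic $\ln(\hat q_A/\hat q_B)/\mathrm{SE}$ is referred to
a standard normal, two-sided. With unit size factors this reproduces a
statsmodels NB GLM Wald test exactly (verified in the test suite). Genes
with a zero count total in either group are flagged untested, carry NaN
statistics, and are excluded from the BH test count m. DEG calls use
BH q < 0.05 and |log2FC| ≥ log2 1.5 by default — thresholds are never
hard-coded downstream, and every output records them.

## Responsive-gene set logic

CARG and IARG sets are literal intersections of per-contrast DEG calls
(significance *and* direction at both passages for CARGs), mirroring how
such sets are assembled from separate per-contrast tests rather than from a
joint model. CARGs require a passage axis and are therefore derived only
for cell types carrying one (hMSC in the default design). The three-way
cross-cell-type comparison is an explicit 7-region Venn partition by
membership pattern; partitions are checked on every run for disjointness
and exhaustiveness, and all set operations are property-tested against
brute-force membership enumeration. Recovery against planted truth reports
sensitivity $|C \cap P|/|P|$, precision $|C \cap P|/|C|$ and empirical FDR
$1 - $ precision, with undefined ratios reported as missing rather than 0.

## ERSE scanning

Canonical patterns are ERSE I = `CCAAT`-N9-`CCACR` (19 nt) and ERSE II =
`ATTGG`-N1-`CCACG` (11 nt). The "CCACG/A" degeneracy is read as the final
position only (hence `CCACR`), the standard reading of the consensus.
Non-canonical mode keeps the half-sites and spacers and allows a
per-half-site mismatch budget (≤ 2; beyond that a 5-nt half-site carries no
specificity). Promoter windows span TSS-relative [−10000, +2000), realized
half-open; offsets are TSS-relative with 0 at the TSS base and a hit's
offset is the leftmost position of the match on the gene-oriented reading
for both strands. Both orientations are scanned by default since reported
ERSEs are not strand-annotated. `N` never matches a specified position;
windows over 50% `N` are skipped with a log entry. For minus-strand genes,
upstream lies at higher genomic coordinates, so the extracted window is the
reverse complement of [TSS − 1999, TSS + 10001) under BED half-open
conventions — verified against a per-base oracle. The expected background
hit count under i.i.d. bases is closed-form,
$2\,(L-\ell+1)\prod_i p_i$ with per-position match probabilities from the
GC fraction (Poisson-binomial DP when a mismatch budget applies); at
GC = 0.5 and L = 12 kb this gives ≈ 0.0457 (ERSE I) and ≈ 0.0229 (ERSE II)
hits per window, which the scanner reproduces empirically.

## ChIP normalization and promoter signal

Treat and control density tracks are combined on the union grid of their
interval breakpoints as $t_i/\Sigma t \times 10^6 - c_i/\Sigma c \times
10^6$. Totals are sums of per-interval density values **on that grid**,
which makes the normalization self-consistent: the treat per-million terms
sum to exactly $10^6$ and the normalized values to exactly 0. Negative
values are retained (no clamping). The transformation is antisymmetric
under treat/control swap and invariant to rescaling either track — both
exact identities in the tests. Promoter signal is the length-weighted mean
of the normalized track over a TSS-centered ±2 kb window (configurable) in
100-bp bins, strand-oriented, with uncovered bases counted as 0 and
zero-coverage genes flagged. Set-level summaries average replicates within
genotype per gene and compare genotypes with a paired t-test across member
genes. Replicate tracks are normalized individually and averaged
afterwards; reproducibility filtering of peak calls is out of scope (the
module consumes density tracks directly).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's *statistical design*: three cell
types × {WT, KO} × {vehicle, 12-h TM}, with an early/late-passage axis for
hMSCs and TM paired at early passage (the induced contrasts are not
passage-stratified). Replicate counts per condition are not published for
such designs; the default is n = 3, configurable but ≥ 2 (variance is
inestimable below that). Truth classes partition the gene universe with
exactly round(fraction × n) members; "both" genes carry the CARG and IARG
effects simultaneously, mirroring the small CARG∩IARG overlap. Defaults
are the study-scale conditions used throughout the tests: 5,000 genes, 4%
CARGs (log2FC −1.5 in the knockout at both passages), 2% constitutively up
(+1.5), 3% IARGs (+1.5 TM induction, −1.5 knockout blunting under TM),
0.2% both. Baseline means are log-normal (median 100, log-sd 1.2),
dispersions log-normal around 0.05 (log-sd 0.3), library-size multipliers
log-normal (log-sd 0.15) — sequencing depths of real libraries are
arbitrary, so these are chosen as typical bulk RNA-seq magnitudes.

Promoters are i.i.d. background sequence at configurable GC (default 0.5)
with motifs overwritten at stated offsets/strands — no dinucleotide
structure, CpG islands or repeats, which suffices for scanner calibration
but not for realistic motif false-positive rates on genomic DNA. ChIP
tracks are gamma noise plus a Gaussian promoter bump (sd 500 bp, peak 4) at
genes flagged enriched for the sample's genotype, binned at 100 bp. Both
tracks also carry a rest-of-genome background compartment (100,000 bins at
mean density 30): in a genome-wide library, the few hundred
genotype-differential promoters are a sub-percent fraction of total mass,
and without this compartment per-million scaling would transfer the planted
differential mass onto every other window and fabricate genotype
differences at unrelated genes. Counts have no GC or 3′ bias, no alignment
artifacts and no sample swaps — passing recovery tests therefore
demonstrates the statistical machinery, not robustness to real-data
pathologies.

Every generator is a pure function of its arguments including the seed;
pipeline stage seeds are derived from the config seed by fixed offsets, and
the run manifest (seed, thresholds, output hashes) reproduces runs
bit-identically.

## Problem sizes and numerical choices

Simulation-based checks run at: 2,000 genes for null calibration (20
seeded repeats for the FDR check), 5,000 genes for planted recovery, 1,000
12-kb promoters for scanner calibration, 200 random 2-kb sequences plus
planted fixtures for oracle equivalence, and 20 seeded repeats of a
130-gene ChIP scenario for the direction test — sizes at which Monte-Carlo
error is well inside the asserted bands. Ties in the size-factor median use
lower interpolation; the common-dispersion optimum is found by bounded
scalar minimization of the penalized likelihood on log α ∈ [log 1e-8,
log 10]; BH enforces monotonicity by a reverse cumulative minimum.

## Known limitations

Two-group contrasts only (no batch covariates or interaction terms); CARG
definitions require the passage axis; the cross-cell-type partition is
fixed at three sets; motif scanning is consensus/mismatch-based, not
PWM-scored, and co-factor context (the NF-Y CCAAT box requirement) is not
modelled; ChIP density units are whatever the input tracks carry — the
module is agnostic to per-base pileup vs. binned coverage; promoter windows
truncated at contig edges are flagged but not length-renormalized in the
background-rate expectation.
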