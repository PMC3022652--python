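# Methods

## The measure

For a protein *g* with partner set PPI_g in an undirected protein–protein
interaction (PPI) network, the **protein–protein interaction degree** is
PPID_g = |PPI_g|.  Given a panel of gene-expression datasets, ePPI_g(i)
counts the partners of *g* declared significantly positively co-expressed
with *g* in dataset *i*, and the **co-expressed PPID** is

    ePPID_g = max_i ePPI_g(i).

The maximum over datasets matters because a permanent complex is only
co-regulated under conditions in which it is actually assembled; any single
dataset underestimates the permanent partner count for complexes inactive
in it.  ePPID is an estimate of the number of partners with which a protein
interacts *permanently* (stable co-complex association), as opposed to
transiently (condition-specific contact).  The package's scientific claim,
exercised end-to-end on synthetic data, is that permanent partners impose
the selective constraint, so ePPID predicts the evolutionary rate dN
(non-synonymous substitutions per site) better than raw PPID.

## Co-expression declaration

Within one dataset with *n* samples, similarity between two gene profiles
is the Pearson correlation *r*, Fisher-transformed to

    z(r) = sqrt(n - 3) · atanh(r),

which is approximately standard normal when the profiles are independent.
A pair is declared co-expressed only if **both** of:

1. **FDR cut** — the one-sided p-value P(Z > z) for the null of no
   *positive* correlation, Benjamini–Hochberg-adjusted over all C(G, 2)
   pairs of the dataset, is ≤ `fdr` (default 0.001).  Negative
   correlations are never declared.
2. **Percentile (PER) cut** — z is at or above the (1 − `per`) quantile of
   all pairwise z values in the dataset (default `per` = 0.10, i.e. the
   top 10%).  This guards against datasets where huge sample sizes make
   biologically trivial correlations statistically significant.

Both thresholds are per dataset.  The percentile is computed by exact
enumeration by default; for very large gene sets a `sampled` mode
estimates it from ≥10⁵ uniformly drawn pairs under a recorded seed (on a
500-gene fixture the two agree to better than 1% relative error; see the
test suite).  Zero-variance profiles yield undefined correlations; their
pairs are treated as non-co-expressed rather than aborting a run.  The
pair universe defaults to all genes in the expression dataset
(`pair_universe: all`); restricting to genes present in the PPI network is
available as `ppi`.

## Expression preprocessing

Each expression matrix is preprocessed in the order: (1) remove genes
missing in strictly more than 30% of samples (exactly 30% is retained);
(2) impute remaining missing cells by K-nearest-neighbour imputation with
K = 10 over gene profiles, Euclidean distance on mutually observed samples
rescaled by the shared-sample count (scikit-learn's `KNNImputer`); if
fewer than K candidate neighbours exist, K falls back to the available
count with a logged warning; (3) average technical replicates (spot
repeats, dye swaps) given an optional sample→group sidecar.  The
procedure is idempotent and never alters observed values.

## Classification

- **Co-expressed protein**: ePPID/PPID ≥ 0.5 (boundary inclusive);
  undefined for isolated proteins.  This is a partner-counting analogue of
  the date/party-hub split that avoids the known weaknesses of APCC
  averaging (APCC is computed for comparison; in the metric table it is
  the mean of per-dataset APCC over the datasets where the gene and at
  least one partner are measured).
- **PPID bins**: the high bin ("hubs") is the top 20% of proteins by PPID
  with boundary ties included (deterministic); the remainder splits at its
  median PPID, ties to medium.  The median rule is the package's choice —
  any symmetric, reproducible split of the non-hub mass serves.
- **Interface classes** (when per-hub interface counts are supplied):
  hubs are proteins with ≥5 partners; singlish-interface means ≤2 distinct
  binding interfaces (the structural-interaction-network convention; the
  cut is a config knob), crossed with the co-expression class into
  NC-S / NC-M / C-S / C-M.

## Evolutionary-rate statistics

- Spearman rank correlations (average ranks for ties; two-sided
  t-approximation p-values) of PPID, ePPID and betweenness with dN.
- First-order **partial Spearman** correlation controlling for protein
  abundance: rho_xy·c = (rho_xy − rho_xc·rho_yc) / sqrt((1−rho_xc²)(1−rho_yc²)),
  t-test on n − 3 degrees of freedom.  Ranks are invariant to the log
  transform of abundance, so the control enters untransformed.
- **Percent variance explained**: R² × 100 from a simple linear
  regression; the abundance-controlled variant first regresses dN on
  log(protein abundance), takes the residual, and regresses the residual
  on the metric.
- **Principal component regression** of ln(dN + 0.001) on six predictors —
  mRNA abundance, protein abundance, dispensability, pleiotropy (GO-BP
  term count), ePPID, betweenness.  All predictors are natural-log
  transformed except dispensability (which may be 0 and lives on a bounded
  growth-rate scale), with +0.1 added to ePPID and betweenness to avoid
  log(0), then standardized.  The predictor correlation matrix is
  eigen-decomposed; per component the package reports the percent of
  response variance explained (squared correlation with the component
  score × 100; orthogonality makes these sum to the full-model R² × 100),
  a two-sided slope p-value (coded ***/*/# for p < 0.001 / 0.05 / 0.10),
  and per-variable percent contributions (squared loadings × 100, summing
  to 100 per component).  Natural logs are used wherever a log transform
  is stated; the base only rescales standardized predictors and leaves
  every PCR output invariant.
- **Group tests**: one-sided Wilcoxon rank-sum (exact for small tie-free
  samples, tie-corrected normal approximation otherwise) for "co-expressed
  proteins evolve more slowly" within each PPID bin and between the four
  hub classes; two-sided Fisher's exact test for 2×2 class contingencies
  (co-expression × interface class).
- Betweenness is the unnormalized shortest-path count through a node with
  endpoints excluded; tied shortest paths contribute fractionally
  (networkx's default, matching the igraph convention), computed per
  connected component.

Multi-variable tables use complete cases only; every reported *n* is the
row count actually used.

## Synthetic scenario generator

The generator produces the three pipeline inputs plus ground truth, and
its defaults define the reference study conditions:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 550 | desk-scale stand-in for a genome; keeps 20-replicate suites fast |
| n_complexes | 100, sizes 2–8, P(s) ∝ 1/s | complex catalogues are dominated by dimers/trimers with a thin tail of large assemblies; small complexes populate the low-degree end with genuinely co-expressed proteins |
| transient edges | 30% of all edges | intermediate between AP/MS-like (~14%) and Y2H-like (~46%) non-co-expressed interaction loads |
| transient hubs | 10 proteins carrying 35% of transient edges | "date hub" emulation: a uniform transient draw is Poisson with mean ≈1 and cannot produce high-degree transient proteins, which real interactomes (especially two-hybrid) plainly contain |
| expression panel | 10 datasets × 60 samples | mirrors a compendium of ten datasets each with >50 conditions |
| active_complex_frac | 0.6 | each complex is co-regulated in only some datasets, so the max in the ePPID definition is non-degenerate |
| module_signal_sd / noise_sd | 1.5 / 1.0 | within-complex correlation s²/(s²+σ²) ≈ 0.69 — strong but not trivial co-expression |
| missing_rate | 0.05 | typical spotted-array missingness; exercises the filter/impute path |
| alpha | 0.35 per permanent partner | log-scale dN decrease; sized so the constraint is detectable in every PPID bin at this sample size |
| beta | 0.2 per unit ln(abundance) | expression level as the classical confounder |
| dn_log_mean / dn_noise_sd | −3.0 / 0.4 | dN ≈ 0.05 scale with realistic scatter |

dN is generated on the log scale and exponentiated (dN > 0 always;
rank-based analyses are transform-robust).  Protein abundance is
log-normal and feeds both a baseline shift of expression profiles
(coupling 0.3) and the dN equation, making abundance a genuine confounder.
mRNA abundance, CAI, dispensability, pleiotropy and interface counts are
generated with plausible couplings to abundance and permanent-partner
count so that the PCR battery has realistic collinearity to untangle.
All randomness derives from one master seed via `SeedSequence` spawning in
fixed order (structure, attributes, one stream per dataset), so outputs
are byte-identical across runs.

**What the generator does not emulate**: dye bias, batch effects and
probe-level noise; overlapping complex membership; network false
positives/negatives beyond the transient/permanent dichotomy; any direct
structural model of binding interfaces.  Passing tests therefore show the
pipeline recovers planted structure under idealized microarray-like noise,
not that real interactomes behave this way.

## Worked example construction

`two_hub_contrast_example()` builds two hubs with ten partners each from
an orthonormal zero-mean basis (QR decomposition of centered Gaussian
vectors), so the planted Pearson correlations (seven at 0.7 and three at
−0.9 for hub A; three at 0.73 and seven at 0.0 for hub B) are exact to
machine precision.  Both hubs have APCC = 0.22, but seven versus three
significantly co-expressed partners — the case where partner counting and
correlation averaging disagree.

## Numerical choices

- Correlations are clipped to ±(1 − 1e−15) before atanh, so duplicate
  profiles yield a huge finite z rather than infinity.
- BH adjustment is an 8-line vectorized step-up implementation because the
  sampled-percentile path needs a family size m = C(G, 2) larger than the
  computed p-vector; it is cross-checked in the tests against both a
  brute-force enumeration and statsmodels.
- An abundance-controlled regression whose residual variance is below
  1e−12 of the response variance reports exactly 0% (the residual is
  float noise).
- A predictor correlation matrix with an eigenvalue below 1e−10 raises an
  error naming the collinear variables.
- Output tables are TSV with floats at 6 significant digits; expression
  round-trips are bit-identical (shortest-repr floats).

## Known limitations

- The FDR guarantee is per dataset; edges declared "co-expressed in ≥1 of
  ten datasets" carry a mildly inflated family-wise error, exactly as in
  the max-based ePPID definition itself.
- The percentile cut makes declarations depend on the whole dataset, so
  adding genes can (by design) change a pair's status.
- Partial Spearman is the first-order rank-based approximation; it is not
  a semiparametric partial rank correlation.
- With ~90 complete cases per predictor in the default scenario the PCR
  component p-values are well behaved, but the warning threshold (n < 10
  rows per predictor) is advisory only.
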