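# Methods

## Compositional geometry

Soil parts and ASV proportions are treated as Aitchison compositions:
strictly positive parts carrying only relative information, closed to unit
sum. The clr transform divides each part by the geometric mean of all parts
and takes logs; rows of a clr table sum to zero and the transform is scale
invariant. Balances come from a sequential binary partition — a strictly
bifurcating tree whose D−1 internal nodes each contrast two disjoint part
subsets:

    ilr = sqrt(r s / (r + s)) · ln( g(numerator) / g(denominator) )

with r and s the subset sizes. The coefficient makes the D−1 balances an
orthonormal basis, so Euclidean distance in full balance space equals clr
distance (tested against a brute-force oracle at 1e−8). Labels read
`[denominator | numerator]` and a balance is positive when the numerator
subset dominates. Geometric means are computed as means of logs to avoid
under/overflow on long part lists. Closure is checked at 1e−9 relative
tolerance; parts keep their input order and balances are addressed by label,
never by column position.

The soil partition contrasts organics against minerals first
(`[Clay, Silt, Sand | N, C]`), then splits texture coarse-ward
(`[Clay | Silt, Sand]`, `[Silt | Sand]`) and the organics (`[N | C]`).

### Zero replacement

Count zeros are replaced in the count-zero-multiplicative style: each zero
cell of a sample becomes δ = `delta_fraction` × (that sample's smallest
non-zero proportion), with `delta_fraction` = 0.65 by default, and the
observed parts are shrunk by the common factor 1 − n₀δ so the row re-closes
to 1. This keeps within-row ratios of observed parts exactly (tested at
1e−9) and keeps every replacement strictly below every observed proportion.
The replacement is deterministic; a Bayesian posterior-mean variant would
shift index values slightly but not the screen's ranking, since clr screens
are dominated by the observed counts. `delta_fraction` is exposed in the
pipeline configuration.

## Weather indices

From daily rainfall Rdᵢ (mm) and mean temperature Tmᵢ (°C) over a
field-season window (default: the whole series supplied per field;
restrictable by start/end date):

- `PPT = Σ Rdᵢ` (mm).
- `SDI = −Σ Pᵢ ln Pᵢ / ln n`, Pᵢ = Rdᵢ/PPT, with the 0·ln 0 = 0 convention,
  so SDI is exactly 1 for even rain and exactly 0 for single-day rain; it is
  undefined (raises) for a dry window rather than silently 0.
- `GDD` accumulates the **full** daily mean on days with Tmᵢ ≥ 7 °C and
  nothing otherwise. This full-mean accumulation is deliberate — it is the
  definition this pipeline standardizes on — and a `conventional` switch
  computing Σ(Tmᵢ − 7)⁺ is available but off by default. The two differ by a
  large additive factor, but both are monotone season-warmth summaries and
  enter the yield model standardized, where an affine difference mostly
  washes out.

All three indices are permutation invariant over days; SDI is invariant to
rescaling rainfall; PPT and GDD are additive over a partition of the window.

## Yield model

OLS of yield (t/ha) on eight standardized predictors: the four soil
balances, water-measured pH, PPT, SDI, GDD. Standardization uses the n−1
standard deviation; slopes are therefore t/ha per predictor SD and
comparable across predictors. 95 % confidence intervals use the t
distribution with n − p − 1 degrees of freedom (statsmodels OLS). Plots
within a field share weather and much of their soil, so errors are not
independent across plots of one field; no random field effect is fitted —
the model is a plain regression, and the clustering is a known limitation
that widens the true uncertainty relative to the printed intervals.
Predictors significant at a two-sided raw p < α are reported with their
sign. Residuals (residual yield) sum to zero and are orthogonal to every
predictor by construction.

## The ASV screen and the balance index

ASVs present in fewer than 2 samples are dropped (contingency filter;
a total-count variant is available). After zero replacement and clr, each
ASV is correlated with residual yield (Pearson by default, Spearman
optional); two-sided p-values come from t = r·√((n−2)/(1−r²)) with n−2 df.
Selection keeps raw p < α = 0.05 split by sign — deliberately without
multiplicity correction: the screen is a liberal, descriptive selection, not
an inference procedure, and with ~2000 ASVs roughly 5 % false positives are
expected and observed under a null simulation. Constant clr columns are
flagged neutral and excluded with a log warning.

The species balance index applies the orthonormal balance formula to the
positive set (numerator) and negative set (denominator) of the zero-imputed
closed proportions. The normalization coefficient is included by default; it
is a monotone rescaling, so correlations with yield are unaffected, and an
unnormalized ln(g⁺/g⁻) variant is selectable. The index is computed from
imputed proportions (the clr values serve only the screen), making it
invariant to per-sample sequencing depth.

**In-sample inflation, by design.** Because the sets are selected on the
same samples, the index correlates strongly with residual yield even when
nothing is planted (the null in-sample correlation is reproducibly high),
while its out-of-sample correlation on a fresh null draw is ≈ 0. Tests
assert both facts; any use of the index as a predictor requires selection on
independent data.

## Alpha diversity

Shannon entropy in nats and Pielou evenness J = H/ln S delegate to
scikit-bio. Chao1 uses the classic estimator S_obs + F1²/(2F2) when
doubletons exist and the bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when
F2 = 0. Counts are not rarefied; Shannon and Pielou are scale invariant,
Chao1 is not (it depends on absolute singleton/doubleton counts), which is
accepted and documented rather than patched.

## Redundancy analysis

RDA is computed as multivariate OLS of the column-centered clr table on the
standardized predictors, followed by SVD of the fitted values (constrained
axes) and of the residuals (unconstrained axes); eigenvalues are singular
values squared over n−1 and the two blocks sum to the total response
variance (tested at 1e−8). Scaling 1 is used: site scores U·S preserve
inter-sample distances of the fitted responses; species scores are unit
eigenvector loadings; biplot scores are correlations of predictors with site
scores. Axis signs are fixed by making the largest-magnitude species loading
on each axis positive, so runs are reproducible up to nothing.

For triplot contours the index is fitted as a second-degree polynomial trend
surface on the first two site-score axes — simple, deterministic and
adequate for a smooth low-dimensional gradient; it will under-fit genuinely
multimodal index fields.

## Synthetic survey generator

The generator emulates a potato field survey: 13 fields × 4 plots with one
plot lost (51 samples), per-field texture centroids spanning sand to loam
with logistic-normal within-field jitter, total C ~ U(1.3, 2.8) % with C:N
≈ 13, pH ~ U(4.6, 6.2) ± 0.2, one 120-day weather series per field
(Bernoulli-gamma rainfall, sinusoidal season temperature), and a ~2000-ASV
community: log-normal baseline abundances (sd 1.5 log units) multinomially
sampled at Poisson(18 000) depth, which produces realistic sampling zeros
without an explicit zero-inflation term (a Bernoulli dropout knob exists,
default 0).

The causal structure routes the planted signal through a latent per-sample
microbial component m (sd 3 t/ha, part field-level, part plot-level):
planted ASVs shift their log abundance by ±1.0 log units per SD of m
(planted baselines are drawn moderately abundant so they are observable at
the configured depth, with per-cell overdispersion sd 0.35), and yield is

    yield = 35 + Σ slopeᵦ · z(balanceᵦ) + m + N(0, 3)   [t/ha]

with planted slopes −4 on `[Clay | Silt, Sand]` and −3 on `[Silt | Sand]`
and 0 elsewhere. Detrending therefore leaves residual yield ≈ m + noise, and
the screen should — and in tests does — recover the planted sets with
sensitivity ≥ 0.8 and a ~5 % null selection rate. These defaults are the
generator's definition of a realistic survey; they are not tuned per test.

What the generator does **not** emulate: spatial autocorrelation beyond the
field level, phylogenetic correlation among ASVs, compositional interactions
(planted taxa displace others only through closure), year effects, and
sequencing artefacts (chimeras, contamination). Passing tests therefore
demonstrate internal statistical correctness of the pipeline under a
plausible generative model, not field validity.

## Problem sizes and determinism

Tests and examples run the full pipeline at the default survey size
(51 × 2000) and smaller slices (300–400 ASVs) for IO round-trips; the CI
coverage and type-I simulations use a few hundred OLS replicates at n = 51.
Every random draw flows from one integer seed through
`numpy.random.default_rng`; pipeline outputs are TSV with a config-hash +
seed provenance header and are byte-identical across reruns of the same
configuration.
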