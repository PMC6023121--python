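# Methods

This note documents the models implemented in `riparianpft`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish.

## Aridity indices

Three phytoclimatic indices are derived from the climate block:

* **UNEP aridity index** PP/PET — annual precipitation over potential
  evapotranspiration (dimensionless; < 1 indicates deficit).
* **de Martonne index** PP/(T + 10), annual form, with T the mean annual
  temperature in °C. Monthly variants are out of scope.
* **Emberger pluviothermic coefficient** Q2 = 2000·PP/(M² − m²), with M and
  m the warmest-month mean maximum and coldest-month mean minimum converted
  to Kelvin. Several Q2 variants circulate; this one was chosen because it
  reproduces the magnitudes of the published site summaries (mean inputs →
  ≈ 107 against a printed mean of 113; the printed values are means of
  per-site ratios, so only magnitude consistency can be expected).

Simpson diversity is 1 − Σp², computed from relative covers of a group's
member species within a site. The Domin–Krajina ordinal cover scale is
converted through a midpoint lookup table; published variants of the scale
differ, so the table is an explicit, overridable argument (the default
10-class midpoints are documented in `indices.py`).

## PLS engine

`pls.fit_pls` implements NIPALS PLS2 (PLS1 when m = 1) with X-deflation
only; Y-deflation changes nothing at m = 1 and is omitted for the
multivariate case as well. Predictors and responses are centered and scaled
to unit variance with the **sample SD (n − 1)** convention, recorded in the
model so the inverse transform is exact; `center_scale` exposes a `ddof`
switch for the population convention.

Numerical choices:

* The inner iteration converges on the unit-norm weight vector
  (sign-invariant drift ≤ 1e−10, max 2000 iterations). Deep components of
  deflated noise can have near-tied eigenvalues where NIPALS oscillates
  between equivalent directions; because X-deflation makes the scores
  orthogonal for *any* unit weight, a numerically stationary weight
  (drift ≤ 1e−3) is accepted at the iteration cap, while a genuinely
  drifting one raises `ConvergenceError`.
* Weight norms and score orthogonality are asserted after every fit.
* `select_components` searches at most min(n − 2, p, rank(X), 5)
  components. The rank cap lets exactly low-rank (noiseless planted)
  inputs run; the cap of 5 reflects that the entry rule never legitimately
  admits deeper components at these problem sizes.

**Q² conventions.** Cross-validation is leave-one-out with the scaling
refit inside every fold (no leakage; the fold model never sees the held-out
site). PRESS and all Q² statistics are computed on the raw response scale.
Per-component Q²_a = 1 − PRESS_a/RESS_{a−1} drives the entry rule
(threshold 0.097, strictly greater-than); cumulative Q² = 1 − PRESS_A/SS
is what reports quote as "Q²". Both are returned, since a single printed
"Q²" is ambiguous between the two.

## The protocol (`pipeline`)

* **Pruning.** A preliminary one-component PLS of all (transformed)
  responses on the full predictor table supplies VIPs. Within each block,
  while any pair exceeds |r| = 0.85, the highest-|r| pair loses its
  lower-VIP member; blocks wider than 8 then lose their lowest-VIP
  variables. The removal log records the reason for every drop. Among
  near-duplicate aridity proxies (PP, PP/PET, IDM, Q2 correlate at
  0.94–0.99 by construction) the preliminary VIPs differ by well under 1%,
  so the identity of the surviving proxy is effectively tie-broken by
  sampling noise; what is stable is that the cluster collapses to a single
  representative.
* **Cover transform.** Percent covers are arcsine-square-root transformed
  (on 0–1) wherever they enter a model — multivariate or univariate —
  and diversities never are.
* **Leave-N-out.** Sites are randomly split into 5 near-equal groups
  (34 sites → 7/7/7/7/6) from the run seed; the partition is written to the
  report metadata for exact replay, and one partition is shared by all
  models of a run. Variable selection (pruning, prescreening) is frozen
  from the full-data model and reused in every fold — refitting the
  selection per fold would change the meaning of the fold-wise VIP mean/SD
  — while scaling and component selection are refit per fold. Per-fold Q²
  is, by default, the internal leave-one-out cumulative Q² of the training
  subsample (`lno_eval="internal"`); evaluation on the held-out group is
  available as `lno_eval="holdout"`. Non-significant folds (N = 0) report
  their one-component diagnostics so the summary statistics remain defined.
* **Prescreen.** Univariate models keep predictors with VIP > 0.9 from a
  one-component screen, capped at the 15 largest; if nothing passes the
  screen the model falls back to all predictors rather than failing.
* **"Maximum Q²"** is applied within the admissible set defined by the
  entry rule, not globally.

## Leaf-trait stage (`traits`)

Traits are natural-log transformed (F statistics and Tukey results are
log-base invariant). "Tukey HSD for unequal sample sizes" is implemented as
Tukey–Kramer: q = |Δmean| / √(MSW/2 · (1/nᵢ + 1/nⱼ)) with p-values from the
studentized range distribution; the two-group case reduces analytically to
the pooled t-test. Compact letters are assigned by the insert–absorb
algorithm. K-means runs on standardized log traits (traits span four orders
of magnitude) with 50 seeded restarts; the elbow is the K maximising the
second difference of within-cluster SS, using WSS(1) = TSS so the smallest
candidate K is eligible; ties prefer the smaller K. Identical points (zero
TSS) are reported as a degenerate elbow rather than a number.

## Synthetic generator (`synthetic`)

The generator emulates the study conditions: 34 low-order Mediterranean
stream sites.

* **Environment.** One latent aridity factor z drives the loaded climate
  variables (PP −0.93, PET +0.95, DaysPP −0.75, Tmean +0.70, Tmin_jan
  +0.55, Tmax_jul +0.60, Trange +0.25) and the coupled soil variables
  (EC +0.6, pH_w +0.5, ESP +0.6, BS +0.5, OC −0.5): arid sites are saltier,
  more alkaline and poorer in organic carbon. Marginals are scaled Beta
  distributions on each variable's published [min, max] matched to its
  published mean/SD, joined by a Gaussian copula carrying z. Beta marginals
  were chosen over truncated Gaussians because several variables (ESP,
  CaCO₃, discharge, C:N) are strongly skewed — a clipped Gaussian cannot
  hit their means, whereas the Beta matches mean and SD exactly in
  expectation while respecting the bounds. The PET loading is strong so
  that PET tracks PP/PET above the 0.85 pruning threshold — the published
  collinearity that motivates the variable-reduction step. The aridity
  indices and soil C:N are computed from the sampled columns, never
  sampled.
* **Covers.** Effects are linear on the arcsine-sqrt scale:
  θ = asin√p₀ + 0.22·(η + ε), ε ~ N(0, noise_sd), clipped to [0, π/2],
  cover = 100 sin²θ. η = Σβ·x̃ over standardized predictors; the default
  signed effects encode the reported structure (aridity → GG+, DT−, with
  the associated soil syndrome EC/pH/ESP; PP and mild winters → ES+, ET+;
  altitude → DT+). Baseline covers are 25/12/15/8/35% for GG/ES/ET/DS/DT.
  The default noise SD is 0.3 on the linear-predictor scale. With
  `cover_simplex` (default on), covers are rescaled only when their sum
  exceeds 100% — canopy layers may overlap, so no strict simplex is
  imposed. Total canopy combines the woody covers as independent layers.
* **Diversity.** Per type, a Dirichlet abundance vector with concentration
  exp(0.8 + 0.7·(η + ε)) over its member species; Simpson 1 − D is computed
  from the draw, so diversity is mechanistically tied to abundance
  evenness. Total diversity pools all species weighted by group cover.
* **Leaf traits.** Species-level lognormal draws (σ_log = 0.25) around
  group medians encoding the trait syndromes: deciduous higher SLA and %N,
  lower toughness and C:N than evergreens; graminoids silicon-rich and
  lignin-poor, with toughness at evergreen levels. Medians were calibrated
  so the default table reproduces the clear three-cluster structure
  (elbow at K = 3, ~one misclassified species out of 32): medians placing
  too much variance on the deciduous/evergreen axis alone make the elbow
  rule tie between K = 2 and K = 3. %C is derived as C:N × %N for internal
  consistency. Leaf-level nesting (individuals, leaves) is collapsed to
  species means and out of scope.
* **Effect magnitudes** are free parameters: the source material states
  only signs, so defaults use |β| of 0.3–0.8 SD per predictor.

**What passing tests show — and what they do not.** The synthetic data
share the published marginal ranges, the aridity-driven collinearity and
the qualitative effect structure, but they are Gaussian-copula smooth, have
no spatial autocorrelation, no hydrological disturbance, no species-level
biogeography, and exactly one environmental latent factor. Parameter
recovery on these data validates the *machinery* (transforms, selection
rules, cross-validation bookkeeping), not the ecological conclusions that
would follow from the real, undeposited field data.

## Problem sizes

Simulation-based checks use the study's own scale (34 sites, 32 species)
with 50–100 replicates; calibration of the generator's marginals is checked
at n = 10,000 where Monte-Carlo error is well below the tolerance bands
(5% on means, 10% on SDs).

## Known limitations

* The NIPALS tie-acceptance (above) means deep noise components are
  direction-arbitrary within a degenerate subspace; retained models never
  depend on them.
* The fold-wise Q² under `lno_eval="internal"` is a stability diagnostic of
  the training subsamples, not an unbiased estimate of out-of-sample error;
  use `"holdout"` for the latter.
* Compact letter displays are greedy and may not be minimal in pathological
  significance patterns; they are always consistent with the pairwise
  flags.
* `prune_correlated` resolves VIP ties among near-duplicate predictors by
  column order; with collinear derived indices the surviving representative
  can differ between runs drawn from the same population.
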