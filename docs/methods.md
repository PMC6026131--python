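# Methods

## The count model

Vessel counts (penetrating arterioles, anastomoses, or offshoot branch
vertices) in region *r* of animal *m* are modelled as conditionally
Poisson with a log link and a known offset for region area:

    C_mr | u_m ~ Poisson(μ_mr),
    log μ_mr = x_mr'β + u_m + log A_r,      u_m ~ N(0, σ_u²)

The fixed effects x'β comprise an intercept, the deprivation group S
(treatment-coded, sham reference), centred age Y (days), the age ×
group interaction, sex G (male reference), region R (barrels
reference) and the group × region interaction.  The offset log A makes
the coefficients act on *densities* (counts per mm²), so regions of
different sizes are directly comparable.  The per-animal intercept u_m
absorbs the shared between-animal variation in overall vessel counts —
counts from five regions of the same animal are not independent
measurements — and is shared across regions on the log scale.

Interpretation of the error structure: the only stochasticity beyond
u_m is Poisson sampling variation; no extra dispersion parameter is
introduced.  Whether that suffices is *tested*, not assumed, via the
dispersion check below.

### Estimation

The marginal likelihood integrates the Poisson likelihood over each
animal's Gaussian intercept.  Because the intercept is the only random
term, each animal contributes a one-dimensional integral

    L_m(β, σ_u) = ∫ Π_r Pois(C_mr; e^{x'β + u + log A}) φ(u; 0, σ_u²) du

whose log-integrand h(u) = T_m u − A_m(β) e^u − u²/(2σ_u²) (T_m = total
count, A_m = total fitted rate at u = 0) is strictly concave.  We
locate its mode by Newton iteration, rescale to mode and curvature, and
apply Gauss–Hermite quadrature (15 nodes by default; 1 node is exactly
the Laplace approximation).  The outer maximization over (β, σ_u ≥ 0)
uses L-BFGS-B started from the σ_u = 0 Poisson regression; convergence
is declared when the relative log-likelihood change falls below 1e-8
(a vanishing projected gradient is also accepted, since a warm start at
the optimum can stall the line search).  Standard errors come from the
numerically differentiated observed information of the marginal
likelihood.  Fitted values and Pearson residuals are conditional on the
empirical-Bayes modes û_m.

Cross-validation: on simulated tables the maximized log-likelihoods
agree with R's glmmTMB (Laplace) to within the accuracy difference of
the two quadratures (<0.01), and at σ_u fixed to 0 the fit reproduces
an independently computed IRLS Poisson regression to 1e-6.

### Tests

* **Drop-one likelihood-ratio tests.**  A factor's contribution is
  2(ℓ_full − ℓ_reduced) referred to χ² with df equal to the number of
  dropped columns: 1 for S, Y or G; 4 for S×R with five regions.  Only
  the named term is dropped (testing a main effect keeps its
  interactions), matching the reported χ²(1)/χ²(4) structure.
* **Region post-hoc contrasts.**  All 10 pairwise region contrasts on
  the link (log-density) scale, with single-step family-wise adjustment
  by the max-|z| multivariate-normal reference, evaluated by seeded
  Monte-Carlo (10⁵ draws) — the z-statistic analogue of Tukey's HSD
  appropriate for a generalized mixed model.  The adjusted p is floored
  at the unadjusted p.
* **Dispersion.**  Σ Pearson residuals² referred to χ² with
  n_obs − n_fixed df (the random intercept is not counted); both
  one-sided tails are reported (variance > mean and variance < mean).
  The df is always computed from the table, never assumed.
* **LMA-vs-PA association.**  Ordinary least squares of per-animal LMA
  totals on PA totals over the somatosensory regions (barrels,
  forelimb, hindlimb), with t(n−2) inference on the slope and
  Bonferroni adjustment over the three fitted lines (pooled, deprived,
  sham).
* **Power.**  The minimal detectable Cohen's d solves
  power(d) = 1 − β for a two-sample t-test with noncentrality
  d·√(n₁n₂/(n₁+n₂)) and n₁+n₂−2 df, by bisection to 1e-6.  For the
  9-vs-10 one-tailed design at α = 0.05, power 0.8 this gives
  d = 1.191 (≈1.2); the normal-approximation shortcut gives 1.142 and
  is always smaller because it ignores SD-estimation uncertainty.

## The synthetic cohort

The generator produces the study conditions the analysis assumes, with
ground truth for everything the pipeline must recover.

**Geometry.**  A convex, ellipse-like slab of 35 mm² (per-animal aspect
jitter) holding five disjoint rectangle-like region polygons at exact
target areas — barrels 4.0, forelimb 1.5, hindlimb 1.0, visual 3.0,
auditory 1.5 mm² — in a rough flattened-cortex layout with per-animal
translation/rotation jitter.  Region areas are not tabulated in the
source anatomy; these are declared assumptions, configurable in
`GeneratorParams`.

**Counts.**  Per animal, u ~ N(0, σ_u²) with σ_u = 0.25.  PA counts per
region are Poisson(λ_PA·A_r·e^u·m_r) with λ_PA = 17.4 /mm² and
m_r = deprivation multiplier on the deprived group's barrels region
(default 1.0: the null regime); a background process at λ_PA covers the
slab outside the regions.  LMA counts are Poisson(ρ_r·A_r·e^u) with
ρ = 2.0 /mm² in hindlimb (which sits on the MCA/PCA watershed) and
1.0 elsewhere — again declared assumptions, as only the enrichment
pattern, not the rates, is known.  With u drawn mean-zero on the log
scale, the *marginal* mean density is λ_PA·e^{σ_u²/2} ≈ 1.03·λ_PA; the
generator intensity is interpreted as the typical-animal (median)
density.  A 19-animal cohort (9 deprived, 10 sham; 9 male, 10 female;
ages uniform on P45–P65) is the default.

**Graph construction.**  The trunk is a path through all PA attachment
hubs ordered by angle about the slab centroid, entered by a root node
(the MCA stem) and closed by the LMA chords: each LMA contributes one
chordal edge spanning one angular sector, consecutive chords overlap,
and hubs are kept inside the chord-covered span — so every trunk edge
lies on a cycle and the bridgeless core is exactly trunk + chords, with
precisely one independent loop per LMA.  PAs attach by short offshoot
stubs; with probability 0.25 a stub carries one bifurcation and picks
up a second nearby sampled PA as a second leaf (pairing two drawn
points rather than adding one, so PA density is untouched).  Departure
directions at every kept vertex are laid out explicitly via short
polyline elbows: LMA endpoint bifurcations send their two vessel
branches at ±75° around the chord direction (acute-angle bisector along
the chord — the morphological anastomosis criterion), while all other
bifurcations get equal-angle stars whose bisector opposes every
candidate edge.  Geometric LMA identification is therefore exactly
decidable on synthetic data.  Cross-territory labels (MCA vs ACA/PCA)
are assigned to a random half of LMAs so the watershed line is
non-trivial.

**What the generator does not emulate:** vessel diameters and
narrowness (explicitly out of scope), sinuous LMA shapes, curved
vessel paths beyond the port elbows, tissue shrinkage, tracing errors,
or flow-adaptive remodeling.  Passing tests therefore demonstrate that
the *pipeline* recovers the structures and effects it claims to
recover under the stated statistical conditions — not that those
conditions exhaust real tracings.

`sample_count_table` draws animal × region tables directly from the
count law above without building geometry; it is the unit for
large-replicate calibration studies, and is identical in law to the
counts the geometric generator realizes.

## Numerical choices

* Quadrature 15 nodes (one grouping factor makes AGQ cheap); Newton
  inner iterations to 1e-12 with step clipping; intensities clipped at
  e^{±40} to avoid overflow.
* Strict majority (>0.5) for Voronoi-cell region attribution, exact
  ties (measure zero, but code must be deterministic) to the
  lexicographically smallest region with a warning.
* LMA "near a region" = midpoint within 0.3 mm of the region boundary
  (configurable), motivated by the ~50 µm histological boundary
  accuracy plus vessel scale.
* A PA sitting directly on the backbone counts as a zero-length
  offshoot of one vertex; offshoot→region attribution uses the
  attachment node's containing region.
* Degenerate inputs fail loudly: acyclic networks have no backbone
  (error, not an empty answer), empty point processes refuse to build a
  network, coincident Voronoi seeds and rank-deficient designs raise
  with the offending elements named.
* All Monte-Carlo procedures (post-hoc adjustment, simulation) take
  explicit seeds; a single pipeline seed spawns per-stage substreams.

## Study sizes used in the test suite

Calibration and recovery experiments are scaled to run in minutes:
type-I-error calibration uses 500 replicates of 40-animal null
cohorts, effect recovery 100 replicates of 40-animal cohorts with a
0.7 multiplicative deprivation effect, σ_u recovery 15 replicates of
60 animals, and the density calibration a single 200-animal cohort.

## Known limitations

* With only ~19 animals, the ML-based likelihood-ratio test for a
  between-animal factor (deprivation, sex) is mildly liberal: its true
  type-I error is ≈0.07 at nominal 0.05, converging to nominal by ~40
  animals.  This is a small-sample property of the χ² reference with
  few groups (the motivation for Kenward–Roger-style corrections in
  linear mixed models), not an implementation artifact — the
  likelihoods match an independent mixed-model implementation.
  Borderline p-values near 0.05 at cohort scale deserve caution.
* The dispersion check uses conditional (animal-intercept-adjusted)
  Pearson residuals; overdispersion *between* animals is absorbed by
  u_m and only within-animal misfit is flagged.
* Geometric LMA identification is a convenience heuristic; all
  pipeline statistics use curated labels.  Real tracings with noisy
  bifurcation angles will not separate as cleanly as synthetic ones.
* Voronoi majority attribution loses boundary-straddling PAs whose
  cells' majority falls outside every region; with regions embedded in
  a same-intensity background this exchange is unbiased, but against an
  empty background it would undercount edge regions.
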