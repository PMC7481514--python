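# Methods

This note documents the models, conventions and numerical choices behind
`ryenue`, in the order data flows through the pipeline.

## Trial design

The generator produces a randomized complete block design: G genotypes ×
T nitrogen levels × R replicates, one pot per (genotype, treatment,
replicate). Pots are laid out in conveyor rows of fixed capacity (default
38); each replicate occupies a contiguous band of rows within which the
treatments alternate row by row, and genotypes are permuted independently
within every treatment row. The default G = 76, T = {0.5, 5} mM, R = 4
gives 608 pots in 16 rows. When the genotype count does not divide the row
capacity, rows fill left to right and the last row of a band runs short.
All randomization comes from a single seeded NumPy generator, so a design
is a pure function of its arguments.

## Growth model

Regrowth after each defoliation is logistic. With residual silhouette
area A₀ (what remains after cutting to 5 cm stubble) and pot-specific
asymptote K:

    A(t) = K·A₀ / (A₀ + (K − A₀)·e^(−r·t)),  t = days since the cut.

This is a deliberate modelling choice rather than a fitted law: its
absolute growth rate dA/dt is unimodal (rising until A = K/2, then
falling) and its relative growth rate d ln A/dt decays strictly — the
qualitative post-defoliation kinetics observed in ryegrass under both N
levels. The asymptote composes effects multiplicatively,

    K_pot = K(treatment) · g(genotype) · i(genotype, treatment),

with g and i lognormal (mean ≈ 1) and an additive per-replicate block
shift applied to observations. During the acclimation phase the treatment
effect on K is suppressed (both treatments share the low-N asymptote):
freshly transplanted plants still metabolize nitrogen reserves, so the
treatment contrast is not yet expressed — matching the purpose of an
acclimation cycle in the screening protocol.

Defaults, with reasons:

| parameter | default | rationale |
|---|---|---|
| K(0.5 mM) | 8·10⁴ px | phase-end MPPA scale consistent with reported AGR ≈ 2.5·10³ px d⁻¹ over ~28 d |
| K(5 mM) | 1.6·10⁵ px | two-fold N contrast, matching the roughly doubled growth under moderate N |
| A₀ | 6·10³ px | stubble silhouette ≈ 7% of the low-N asymptote |
| r | 0.30 d⁻¹ | AGR peak ≈ 8–11 d after a cut ("first week"); >99% of K reached by day 28 |
| genotype σ (log) | 0.28 | within-treatment CV of dry matter ≈ 0.3, the scale seen in such trials |
| interaction σ (log) | 0.08 | small but statistically detectable genotype × N structure |
| replicate σ | 800 px | mild block effects (~1% of the signal scale) |
| observation σ (log) | 0.05 | per-date imaging noise |

Cuts default to days 28/56/84 (phases AP, EP-1, EP-2); imaging occurs
twice weekly, 8 dates per phase at +3, 7, 10, 14, 17, 21, 24, 27 days
after the phase's cut. The last date is kept strictly before the next cut
so the half-open phase assignment [cut_k, cut_{k+1}) is unambiguous.

## Harvests and biomass coupling

At each cut, fresh mass is proportional to the silhouette area removed:
FM = c₁·(A(cut) − A₀)·ε_FM with c₁ = 8.5·10⁻⁵ g px⁻¹ and lognormal noise
ε; DM = FM · d(treatment) · ε_DM with dry-matter fraction d = 0.20. The
noise sigmas (FM 0.135, DM 0.04) were calibrated once by Monte-Carlo
(5 seeds, full 608-pot trials) so that the pooled Pearson correlation
between phase-end MPPA and FM across the experimental phases is ≈ 0.95
(realized mean 0.9504), the strength of the image–biomass relationship
the pipeline is designed around. With these couplings the simulated trial
lands at mean DM ≈ 1.3 g (0.5 mM) and ≈ 2.8 g (5 mM), NUE ≈ 270 and ≈ 57
g DM g⁻¹ N, and within-group CVs ≈ 0.33–0.36.

## Plant rendering

Plants are schematic: a crown at the pot surface with tillers drawn as
tapered, gently drooping blades (length, basal width, curvature, azimuth,
elevation per tiller), projected into three views — top (pot plane),
side-0° and side-90° (the same geometry rotated 90° about the vertical
axis) — and filled as polygons in painter's order. Photorealism is a
non-goal; the renderer's contract is that plant pixels are green-dominant
(G ≥ R + 30 and G ≥ B + 30 on the 0–255 scale, hence ExG ≥ 60), the
background emulates a white pot on a neutral grey cabinet (|ExG| ≤ 2), and
the returned mask is exactly the set of painted plant pixels. Two
rasterisation guards keep that contract clean: blade half-widths are
floored at 0.8 px so tips do not fragment, and any stranded component
under 8 px is unpainted from both image and mask. A projection that would
leave the frame raises an overflow error; plants are never silently
cropped. Identical spec + seed renders bit-identical images.

What the renderer does **not** emulate: specular highlights, shadows,
soil/moss in the pot, colour drift between imaging dates, lens distortion
and leaf senescence. Segmentation results on these images are therefore an
upper bound on real-world performance; the segmentation parameters exist
precisely so the thresholds and morphology can be re-tuned on real scenes.

## Segmentation

Foreground = excess green ExG = 2G − R − B above a threshold, then
optional morphological opening and closing (disk structuring elements) and
removal of connected components below a minimum size (8-connectivity).
Defaults: fixed threshold 20, no opening, no closing, minimum size 4.
The fixed threshold is the robust default here: the green-dominance margin
puts vegetation at ExG ≥ 60 and neutral backgrounds near 0, and Otsu's
method — available via `threshold: null` — is ill-posed when the
background class is nearly uniform (it can maximise between-class variance
by splitting the vegetation class instead). Closing is off by default
because it bridges adjacent thin grass blades (measured round-trip IoU
0.88 with closing radius 1 versus 1.0 without). A scene with no green
pixels yields an empty-*flagged* mask, not an exception, so missing
observations propagate as data. A configurable rectangular exclusion zone
supports masking pot carriers in real imagery.

## Shape features

The convex hull is computed over the four unit-square corner points of
every foreground pixel. This convention guarantees hull area ≥ pixel
count, so compactness = area / hull area lies in (0, 1] with equality
exactly for pixel-convex shapes (e.g. filled rectangles) — a hull over
pixel *centers* can violate that bound on thin shapes. Hull circumference
is the polygon perimeter of that corner hull; caliper length is the hull
diameter computed by a rotating-calipers antipodal scan (O(h) in hull
vertices, verified in tests against an O(n²) all-pairs oracle and a
gift-wrapped hull); width and height are whole-pixel bounding-box extents
in camera coordinates, with no principal-axis rotation. Pixel units are
never converted to millimetres (no camera calibration is modelled). One
geometric consequence worth knowing: because the corner hull exceeds the
pixel area by an O(r) rim term, a rasterised disk's compactness is ≈ 0.976
at r = 30 px and crosses 0.98 only around r = 40.

## Derived traits

MPPA is the mean of the two side-view areas; the three digital volumes
are the sum, the product, and the side-sum plus 3·ln(top area). In the
keygene variant "log of the cubed top area" is read as 3·ln A_t, natural
log, consistent with the Ln(·) convention of the RGR definition; base-10
is selectable in config (`stats.keygene_log`). Per phase, MPPA and the
volumes are reported at the phase's **last** imaging date; phase-level
AGR and RGR use the phase's first and last imaging dates as (t₁, t₂), and
per-interval rates between consecutive dates are also emitted for the
temporal profiles (both conventions, since either could be wanted).
AGR on dry mass divides the phase-end DM by the actual days between
consecutive cuts, read from the schedule, not a fixed 28.

Supplied nitrogen uses the elemental-N molar mass 14.007 g mol⁻¹ (the
treatment levels are concentrations of N, not of nitrate salt):
0.5 mM × 0.1 L × 7 applications → 4.90 mg per pot per phase; 5 mM → 49.0
mg. NUE = DM / N_s is computed for the experimental phases only — the
acclimation phase exists to exhaust residual N, so a per-phase NUE there
is not meaningful. In the worked-example arithmetic the dose is quoted at
the protocol's 0.1 mg precision (4.9 mg), so the reference mean NUE is
1.29 / 0.0049 = 263.3 g DM g⁻¹ N; using the unrounded dose instead gives
263.1.

## Statistics

Summaries are n, mean, SD (n−1 denominator), min, max and CV = SD/mean
per phase × treatment (CV flagged when the mean is zero). Because NUE is
DM divided by a group constant, CV(NUE) ≡ CV(DM) within each group — a
useful internal-consistency check that the tests enforce to machine
precision. Correlations are pairwise-complete Pearson r with two-sided
t-test p-values (cells with < 3 complete pairs flagged), with significance
stars at 0.05/0.01/0.001.

BLUEs come from the linear mixed model with genotype, N treatment and
their interaction fixed and replicate random, fitted by REML separately
per phase, in a sum-to-zero factorial parameterisation. The two variance
components are estimated with statsmodels' MixedLM; the fixed effects and
their covariance are then computed as the closed-form random-intercept
GLS at those variance estimates. This keeps the estimates exact when the
replicate variance legitimately hits the zero boundary (where the generic
optimizer's reported coefficients can be inconsistent) and makes the
balanced-design identity — cell BLUE ≡ arithmetic cell mean — hold to
~1e-14, which the tests use as an exact oracle. Wald chi-square tests of
the three fixed terms use numerator df G−1, T−1 and (G−1)(T−1). With a
single replicate the block effect is unidentifiable and the fit falls
back to ordinary least squares with a logged warning; an exactly
noise-free response short-circuits to least squares as well (there is no
variance to estimate). Recovery reports correlate estimated per-treatment
genotype BLUEs with the generator's true per-treatment effects
(g × interaction multiplier) — Pearson, Spearman and top-decile overlap;
in the noise-free limit Spearman is exactly 1.

## Pipeline scale

The growth/harvest simulation and all statistics always cover the full
configured trial. Images are rendered only for a configurable subset of
pots and dates (default 4 pots × 2 dates per phase × 3 views): rendering
all 608 × 24 × 3 views would add nothing statistically, since the full
trial's per-view areas are written by the simulator in the same
feature-table schema the image-extraction stage produces, and the derive
stage accepts either source. The rendered subset is what exercises the
image path end to end (segmentation round trips at IoU 1.0 on clean
renders, ≥ 0.95 under 1% impulse noise).

Determinism: every stage derives its sub-seed from the master seed, and a
run's manifest records a SHA-256 checksum of every artifact; identical
config + seed reproduce identical checksums.

## Known limitations

- The logistic law and multiplicative effect structure are stylised; real
  regrowth shows weather-driven day effects, tiller mortality and
  senescence the generator does not model.
- Biomass coupling is linear in projected-area gain; real canopies
  saturate projection before mass (occlusion), which would bend the
  MPPA–FM relation at high biomass.
- Passing segmentation tests on rendered scenes demonstrates the geometry
  and plumbing, not robustness to field imagery (no colour calibration,
  shadows or soil clutter).
- Tissue N concentration is not modelled, so uptake- versus
  utilization-efficiency cannot be partitioned; NUE is output-per-input
  only.
- No spatial row/column adjustment beyond the replicate block effect, and
  no heritability or variance-component reporting.
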