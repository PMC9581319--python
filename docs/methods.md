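# Methods

This note documents the models, defaults and numerical choices behind
xylograft, and what the synthetic-data generators do and do not emulate.

## Hydraulic traits

Vessel diameters are equivalent-circle diameters of segmented lumen
areas, d = 2·√(VA/π); Dh = Σd⁵/Σd⁴ is computed after normalising by
max(d) so long vessel lists cannot overflow in the fifth power. Dh is a
ratio of adjacent raw moments, hence bounded by [min d, max d], equal to
d for a homogeneous population, and monotone under appending a vessel
larger than the current maximum. Because Dh ≥ √E[d²] (power-mean
inequality), the vessel area fraction of any circular-lumen population
is bounded by VAf ≤ Vd·(π/4)·Dh².

**Poiseuille coefficient.** Kst = (π·ρ/(C·η·Aᵢ))·Σd⁴ with ρ = 998.2
kg m⁻³ and η = 1.002×10⁻⁹ MPa s. With these units the classical
Hagen–Poiseuille form requires C = 128; the package defaults to
C = 1.28, the value conventionally printed in the viticulture
literature this pipeline follows, and exposes `coefficient=128` on
`HydraulicConstants`. The two differ by an exact factor of 100; all
Kst values in this package are reported under C = 1.28. Note that even
under C = 1.28, populations with Vd ≈ 120 mm⁻² and Dh ≈ 27 µm give
Kst ≈ 150 kg MPa⁻¹ s⁻¹ m⁻¹ — literature values of ≈ 26–48 for the same
Vd and Dh are not reachable from the stated formula and constants, so
the test suite asserts a magnitude envelope (1–10⁴) that catches
unit errors (a µm-for-m slip changes Kst by 10²⁴) rather than a
literature envelope.

**Analyzed area Aᵢ.** Defaults to the summed Xy (pure xylem) area,
consistent with measuring traits on xylem that excludes phloem and ray
parenchyma; the whole image frame is selectable
(`profile_section(..., ai="image")`). Dh is pooled over all vessels of
the section by default; per-sector profiles are returned alongside.

## Section generator

A rendered section is a stem disc: pith (radius 100 µm by default),
xylem annulus, phloem ring (60 µm), on a bright background, at 1 µm/px
(making µm↔px conversions trivial in tests). Radial parenchymatic
bands split the annulus into 4–6 Xy wedges per quadrant; quadrants are
labelled DV1, L1, DV2, L2 starting at 45°. Lumens are ellipses
(aspect 0.85–1.0, random orientation) with areas matching drawn
diameters; placement is rejection sampling with a 2-pixel minimum wall
distance and a 10⁴-retry bound, after which a `PlacementError` is
raised. Lumens may abut parenchymatic bands — as real vessels abut rays
— but stay inside the annulus and never overlap; centres are sampled
inside Xy wedges so every vessel has a sector label. Ground-truth areas
are the rasterized pixel counts, so annotations are exactly recomputable
from the emitted label maps. Noise is additive Gaussian on intensity,
clipped to the 8-bit range — the simplest model that exercises
threshold robustness.

**Diameter distribution.** The literature reports only aggregate traits,
not raw diameter histograms; the default family is lognormal (standard
for conduit lumen data), with Weibull and a two-mode lognormal mixture
available. `scale=0` degenerates to a point mass, which makes
closed-form checks trivial.

**Presets and an inconsistency.** The published aggregate envelopes —
Vd ≈ 85–140 mm⁻², Dh ≈ 25–32 µm, VAf ≈ 18–24 % — are geometrically
incompatible for circular lumens: by the bound above,
VAf ≤ 140×10⁻⁶·(π/4)·32² ≈ 11 %. The `glera_like`, `teroldego_like`
and `cabernet_like` presets therefore target the density and Dh
envelopes (yielding VAf ≈ 6–8 %), while the `high_vaf` preset targets
VAf ≈ 22 % with sparser, larger vessels (Dh ≈ 60 µm). A green
generator test establishes internal consistency with these presets'
own targets, not agreement with the inconsistent published triple.

## Segmentation

Lumens are dark objects among several brighter tissue classes, so the
default threshold is the lowest cut of a 3-class multi-Otsu (plain Otsu
would merge tissue with lumens); a fixed threshold is available for
reproducible batches. Gaussian pre-smoothing (σ = 1 px) precedes
thresholding; objects under 20 µm² (tracheid scale; configurable) are
discarded and border-touching objects dropped by default. Vessels
touching an Xy boundary are included iff their centroid pixel is
labelled — the label map is authoritative, which keeps density unbiased
under random placement. Scale consistency (identical physical scene at
2× resolution changes ΣVA by <2 %) holds for the thresholding geometry
itself; fixed-pixel smoothing is excluded from that comparison since
its physical scale changes with resolution by construction.

## Necrosis measurement

The ROI rule is a horizontal band of height = sample diameter / 4
centred on the graft line, intersected with the sample disc; the exact
construction in the source protocols is ambiguous, so the geometry is
configurable and this default is documented rather than asserted as
anyone's intent. "Dark" is likewise not numeric in the protocols:
the default threshold is Otsu on the ROI histogram (appropriate when
both phases are present), with a fixed-threshold override. The
generator carves the necrotic mask from a smoothed random field so its
pixel count equals round(f·|ROI|) exactly; the measurement round-trips
within 1 percentage point at full contrast.

## Growth fitting

Ordinary least squares on y(t) = k·y₀/(y₀ + (k−y₀)e^(−rt)) via
bounded Levenberg–Marquardt (trust-region reflective), with time
re-origined to the first measurement day — a pure reparametrization
that changes only the implied y₀. Initialization: k₀ = 1.05·max(y),
y₀ from the first observation (positivity bound ε = 10⁻¹², since
fitted initial values can be vanishingly small), r₀ from the log-slope
of the central segment, plus a small multi-start grid over r; the best
SSE across starts wins, and failure of every start raises a
`FitFailureError` carrying diagnostics. Fits need ≥ 4 points and
non-constant values. Internode counts are fitted as continuous values.
On noise-free data the fit recovers parameters to 10⁻⁴ relative and
R² ≥ 0.98; with σ = 2 cm noise on the biweekly day-182–281 schedule the
median relative error of r across 15 replicates stays within 10 %.

## Graft-union ranking

The published evaluation tables never state the rule that generated
their "Ranking" column, so the package makes its own rule explicit: a
lexicographic policy — higher callogenesis, then absence of necrotized
callus, then fewer necrotic bionts (none < one < both), then higher
total tissue involvement, then higher callus differentiation — with
dense ranking (ties share the better rank: 1, 1, 2), which the printed
columns' tie patterns imply. This policy reproduces 25 of the 30
printed ranking entries (83 %); every deviation is logged with stratum,
member and both ranks. "Space between bionts" is deliberately *not* a
default criterion: including it lowers concordance to 73 %, consistent
with published observations that inter-biont space filled by callus is
not per se a defect. The policy is pluggable (`CRITERIA` registry) and
serialized into pipeline output for auditability.

## Inference layer

Balanced two-way ANOVA is closed-form (under balance the Type I/II/III
decompositions coincide); unbalanced or incomplete designs are rejected
explicitly rather than silently refit. `anova_from_summaries`
reconstructs the identical table from cell means ± SD via
MS_res = mean(s²) with df = ab(n−1) — feeding exact summaries of a raw
table reproduces `two_way_anova` to 10⁻⁹ relative. An exactly-zero
residual mean square sets an `overflow` flag with F = inf. Bonferroni
post-hoc compares all pairs within one factor at α/m using the pooled
residual MS, and letters come from the insert-and-absorb compact letter
display. The normality gate is the D'Agostino–Pearson K² omnibus
(skewness and kurtosis z-transforms; valid for n ≥ 8, enforced), the
homogeneity gate is Levene on absolute deviations from group means
(mean-centred; Brown–Forsythe via `center="median"`). The arcsine
transform asin(√p) applies to proportions p = percent/100. scipy's
`normaltest`/`levene`/`pearsonr` and statsmodels' `anova_lm` are used
only as independent oracles in the test suite, never as the
implementation.

## Demo study world

The pipeline simulates 3 "cultivars" × 3 techniques with n = 5 sections,
15 plants and 3 graft-union images per cell, mirroring the replicate
structure of the study design this package addresses. Between-plant
biological variability of K (CV 25 %) and between-replicate variability
of the true necrotic fraction (SD 3 pp) match the magnitude of published
cell SDs; without them every replicate would be near-identical and the
F statistics meaninglessly large. What the generators do **not**
emulate: stain-color fidelity, fibre/parenchyma texture, uneven
illumination, sectioning artefacts, serial-section registration, or
non-logistic growth (time lags, Gompertz/Richards shapes). A green
end-to-end test therefore establishes correctness of the measurement
and inference chain on idealized scenes, not robustness to real
histology.

## Known limitations

- Unbalanced designs are out of scope by design (no regression ANOVA).
- Percent-necrosis F statistics depend on whether published tables were
  computed on arcsine-transformed values; the pipeline transforms
  before ANOVA, but reconstruction of published necrosis F values is
  not claimed.
- The published VD–Dh correlation (−0.74) is reproduced only as a
  qualitative property (adding small vessels cannot raise Dh), since
  the sampling unit behind the printed value is unstated.
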