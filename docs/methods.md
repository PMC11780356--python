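# Methods

This note documents the models, conventions and parameter choices behind
`trioquant`, what the synthetic-data generator does and does not emulate, and
the numerical decisions a user should know before trusting or changing the
defaults.

## The measurement model

One *experiment* is one animal with one injected target HVA. Its modalities:

* a **flatmap parcellation**: named, non-overlapping polygons (V1, the five
  HVAs PM/AM/RL/AL/LM, the posterior visual areas P/POR, and the non-visual
  surround RSP/PPC/SS/AUD/TEa) in µm, x lateral, y anterior;
* an **injection site** (a point in the target polygon);
* **input cells** with flatmap position, depth below the pia, section index,
  layer and area labels;
* **starter counts** per thalamic nucleus, **brain-wide counts** per major
  region, and **SC cells** with AP position, coronal position and lamina.

### Registration

Tangential sections (a 250 µm top section, then 50 µm steps) are aligned by
full 6-parameter affine transforms fitted by least squares to ≥ 3
non-collinear landmark pairs; landmark kinds (radial vessels, surface
vessels, apical dendrites) are weighted equally since no basis for weighting
exists. Section *k*'s transform into the surface frame is the composition of
the pairwise fits k → k−1 → … → 0. A full affine (rather than a similarity)
is used so shear can absorb cutting distortion. Invertibility requires
|det| > 1e−12 of the linear part. The in-vivo border map is warped into
tissue coordinates with the surface-vessel fit, preserving area names and
order; post-warp topology is re-validated and violations warn with the
offending area names.

### Assignment

Area labels are boundary-inclusive point-in-polygon tests visited in the
parcellation's fixed order, so a point on a shared border deterministically
goes to the earlier area — determinism was preferred over geometric
tie-breaking. Layers use half-open depth intervals against the L5 marker
band: depth < top → L2/3, [top, bottom) → L5, ≥ bottom → L6; a depth exactly
at the band top is L5. The band is modeled as per-column depth intervals
(defaults 550–700 µm), not per-section image segmentation, since no pixel
data is in scope. L6 is not sublaminated. The starter-bias QC threshold
(default: pulvinar fraction ≥ 0.5) is an artifact choice — the source method
describes the exclusion qualitatively, so the threshold is configuration, not
a biological constant.

### Quantities

* Input fractions divide per-region counts by the experiment's total; HVA
  comparisons are normalized to total *visual cortical* input so outliers
  with large subcortical fractions do not distort areal comparisons.
  Zero-denominator fractions are flagged undefined and excluded from group
  medians rather than treated as 0.
* Distances are Euclidean, in µm, to the recorded injection site (the target
  polygon centroid only when no site exists). The within-radius proportion
  uses a closed 400 µm disc.
* Hexagonal densities: pointy-top hexagons, width = flat-to-flat = 180.6 µm,
  grid anchored at the map origin, membership by exact nearest-center (cube
  rounding). Any fixed convention suffices; this one is stable and
  documented.
* Kernel densities are Gaussian with Silverman's bandwidth computed on the
  *original* sample and boundary correction by reflection (at 0 for
  distances; at both 0° and 90° for θ). Computing the bandwidth on the
  mirrored sample would inflate the spread roughly threefold and oversmooth.
  Default evaluation grids refine to ≥ 4 points per bandwidth so the
  trapezoidal integral stays within 0.01 of 1 even for very concentrated
  samples. Because Silverman's factor scales as n^(−1/5), duplicating a
  sample changes the estimate slightly; pooling itself is exact
  concatenation.
* Summaries: mean ± SEM (sample SD with n−1 denominator over √n) and
  median ± MAD (unscaled). Relative-strength matrices divide each target
  column by its maximum; all-zero columns are flagged and left as zeros.

### SC polar analysis

Cells fall into four half-open 500 µm AP bins with centers −3.05, −3.55,
−4.05, −4.55 mm from bregma (the most posterior bin closed at −4.80). The
polar axis fixes θ = 0° on the ventral SC boundary and θ = 90° on the
midline; the origin per bin is their intersection at the bin center. Only the
two axis endpoints are prescribed by the method being modeled — the origin
choice is ours and makes both anchors exact; an SC-centroid origin is a noted
alternative, not implemented as a default. Superficial = {zo, sg, op},
deep = {ig, iw, dg, dw}. Per-target θ samples pool cells across animals
without weighting, so inefficiently labeled brains contribute proportionally
fewer cells instead of being reweighted.

### Statistics

The **shuffled-target null** re-draws each experiment's target uniformly and
independently from the five mapped HVAs, original included (keeping the
observed configuration inside the null support; excluding it is available as
a sensitivity option). The reference point of a shuffled target is the
centroid of that area's polygon in the animal's own map — the true injection
site exists only for the real target — except that a shuffle landing on the
experiment's own original target reuses the true site. Because a shuffle's
statistic depends on each experiment only through its assigned candidate,
the null is evaluated from a per-experiment × per-candidate table; this is
exactly equivalent to recomputing per shuffle and allows exhaustive
enumeration (all 5^k assignments) on small designs. Sampled nulls use
p = (1 + #extreme)/(N + 1), whose floor at N = 10,000 is 1/10,001 ≈ 1.0e−4,
matching the "< 1.0 × 10⁻⁴" reporting convention; exhaustive enumerations use
the plain proportion. Reciprocity is the upper tail (L6CT), antireciprocity
the lower tail (L5CT); families of per-target p-values are adjusted by
Benjamini–Hochberg.

Kruskal–Wallis (tie-corrected, χ² reference with k−1 df) gates Dunn's
pairwise rank z-tests, which are Šidák-adjusted (p_adj = 1 − (1 − p)^m);
post hoc tests run only when the omnibus test is significant at α = 0.05
(configurable). The Monte-Carlo Fisher exact test samples tables with both
margins fixed (Patefield's algorithm) and measures extremeness by
conditional table probability with a 1e−7 tie tolerance on the log scale,
reporting the binomial MC standard error; the shuffle count needed for a
target precision is N = ⌈z² · 0.25 / w²⌉ (worst case p = 0.5). Pearson χ²
uses no continuity correction. A full-enumeration Fisher oracle exists for
small tables and is used only as an independent cross-check.

## The synthetic-data generator

Defaults describe the modeled study conditions: five targets × 4–5 animals;
1,800 L6 and 200 L5 cells per experiment (the 9:1 modulator:driver ratio);
V1-dominant areal weights (L5: 0.60 V1, 0.13 RSP; L6: 0.40 V1, broader
elsewhere); brain-wide weights dominated by cortex (0.414), TRN (0.151),
SC (0.110) and pretectum (0.108); starter weights with 0.82 in the pulvinar;
reciprocal multipliers ×3 (L6) and ×0.2 (L5) inside a 400 µm disc; border
jitter 50 µm. SC θ distributions are truncated normals on [0°, 90°] with
medial (high-θ) locations for LM (75°) and PM (70°) and broader central
locations for AM/RL/AL — values chosen once to mirror the qualitative
medial-vs-distributed contrast; the source prescribes no numeric locations.
The spatial scale of the planted reciprocal effect beyond the 400 µm
analysis radius is likewise a free parameter, not an asserted biological
value.

The template flatmap is a rectilinear grid subdivision (cells of
1,000–1,200 µm) generated programmatically; border jitter displaces each
*grid vertex* once, uniformly within a disc, and applies the same
displacement wherever the vertex occurs, so shared borders move together and
jittered parcellations remain exactly disjoint (an overlap-retry path halves
the jitter and eventually raises a geometry error). Planted reciprocity is
intensity multiplication inside the disc, realized by oversampling the
area-weighted base process ~4× and subsampling with probability proportional
to the local intensity weight — totals stay exact and areal weights remain
interpretable. Each experiment owns a PRNG stream keyed by
(seed, animal id, target), so outputs are independent of generation order.
The SC cross-section is an analytic quarter-annulus with laminar shells, so
θ and lamina are exact by construction.

What the generator does *not* emulate: pixel data and fluorescence,
curvature-induced nonlinear distortion (only affine section perturbations),
per-animal retinotopy beyond polygon jitter, CCF volumetrics, spatially
correlated counting errors, and the topographic coupling between starter
position and input identity. Passing tests therefore certify the analysis
machinery — geometry, counting, estimation and inference — under the stated
generative assumptions, not the biology of any real dataset.

## Operating characteristics

`trioquant.calibration` measures the permutation test on freshly generated
studies:

* **Type-I error**: multipliers = 1 and areal weights proportional to polygon
  areas (spatially homogeneous intensity, making the shuffled-assignment
  statistic exchangeable by symmetry), 4 experiments × 800 cells, 199
  shuffles (α = 0.05 exactly attainable since (1+k)/200 ≤ 0.05 for k ≤ 9),
  200 replicates. The rejection count is checked against the exact binomial
  99% interval around 0.05.
* **Power**: multipliers ×3 (L6) / ×0.2 (L5), 4 experiments × 1,000 cells,
  1,000 shuffles, BH over the two tails, 50 replicates.

Problem sizes here (and the scaled-down defaults used in unit tests) were
chosen so the full suite and the acceptance script each complete within
minutes on a single CPU while leaving the Monte-Carlo intervals decisive.

## Published reference data

`trioquant.published` bundles the per-animal starter-count table of the
modeled study (24 animals). The printed percentages in that table are
computed on full starter totals that, for some animals, include nuclei
beyond the five tabulated; the printed pulvinar percentage is therefore
stored as data, and the pooled summary (82.0 ± 2.3%, mean ± SEM) pools those
printed values. The per-region brain-wide counts live in a supplementary
workbook that is not redistributable; `published.replicate_brainwide_summary`
implements the replication (fractions → pooled cortex mean ± SEM and
per-target SC median ± MAD) for users who supply that file, and is
unit-tested on synthetic counts with known answers.

## Known limitations

* The permutation null treats experiments as exchangeable across targets;
  systematic per-target differences in cell numbers or map geometry make the
  test approximate (the site-vs-centroid reference asymmetry contributes a
  small liberal bias, visible as empirical type-I rates of 0.06–0.07 at
  α = 0.05 in the calibration study — inside the binomial 99% band but not
  exactly nominal).
* Dunn's z-tests use the normal approximation; very small groups (< ~5 per
  group) are better served by exact rank tests.
* The Fisher MC extremeness rule compares conditional probabilities with a
  float tolerance; tables with many near-ties can be sensitive to that
  tolerance (1e−7).
* Hexbin membership at bin boundaries follows cube rounding's deterministic
  tie behavior, which may differ from other hexbin implementations by one
  bin at exact edges.
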