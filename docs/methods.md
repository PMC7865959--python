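# Methods

## Scope and model overview

`spinestereo` compares two routes to synapse density and spine-head
morphometry: 2D stereology on thin-section micrographs and direct
measurement on 3D reconstructions. Because raw microscopy datasets for
such comparisons are generally unavailable, the package supplies a
generative stand-in: a synthetic neuropil whose population statistics are
calibrated to published measurements from adult mouse CA1 stratum
radiatum, plus a virtual sectioning engine that degrades the 3D truth into
2D observations the way a TEM section does. All estimators are then
validated against known ground truth.

The geometric idealisation throughout is deliberately minimal: a spine
head is a sphere; its synaptic apposition surface (SAS) is a spherical cap
with a random orientation; a synaptic length measured on a section is the
diameter of an equivalent disc. No necks, shafts, ellipsoids or meshes.
This is the same simplification used when published 2D and 3D measures are
placed on a common scale, and it is the contract of the `geometry` module:
richer shape models are out of scope.

## Synthetic population (`synthetic`)

* **Head volume.** Lognormal truncated to [0.004, 0.300] µm³. The log-sd
  (0.8) is a free shape choice giving the strong right skew typical of
  spine-size distributions; the log-mean is solved at run time (closed-form
  truncated-moment root-finding) so the truncated mean is exactly the
  configured 0.066 µm³. With these defaults ~81% of heads fall below
  0.1 µm³, consistent with the published ">75%" quantile. A truncated
  gamma family is available (`volume_family="gamma"`) as a robustness
  check.
* **Apposition surface.** `SAS = c · V^(2/3) · exp(ε)`, `ε ~ N(0, σ²)`:
  surface area scales as volume^(2/3) with multiplicative noise. σ = 0.46
  is a fixed calibration constant chosen once, by Monte-Carlo sweep, to
  put the SAS–volume Spearman correlation at ≈ 0.73; `c` then follows in
  closed form from the configured mean SAS (0.089 µm²). Draws above the
  spherical-cap bound 4πR² are clipped (≪ 0.1% of draws; the rate is
  logged).
* **Shaft synapses.** A fraction (default 0.07) of synapses sit on
  dendritic shafts: they carry an SAS from the same marginal but no head
  (`head_volume` is NaN). The default is a modelling choice — the shaft
  contribution is reported in the literature only as "very limited" — and
  is configurable.
* **Placement.** Uniform random centres in a box, with an optional
  hard-core minimum separation (default 0: touching allowed, since no
  packing statistics are available to calibrate against). The true
  density is `count / box volume` by construction.
* **Shape classes.** `thin` / `stubby` / `mushroom` labels are assigned by
  volume thresholds (0.05, 0.10 µm³) as pure metadata; they drive no
  geometry.

All sampling is inverse-CDF under a single `numpy` Generator, so a fixed
seed reproduces tables byte-for-byte.

## Virtual sectioning (`sectioning`)

A micrograph is the projection of a slab `[z0, z0 + t)` (default
t = 0.065 µm, an ultrathin 60–70 nm section) onto the x–y plane,
restricted to a rectangular field of view.

* **Head profile.** The projection of a sphere through the slab is the
  largest circle of the sphere–slab intersection: the full equatorial disc
  when the slab contains the equator, otherwise the circle at the nearer
  slab face. Projection through finite thickness slightly overestimates an
  ideal zero-thickness cut (the Holmes effect), as real TEM projections
  do.
* **PSD length.** The SAS cap's rim circle (radius `a`, from the cap
  geometry `h = SAS/2πR`, `a² = 2Rh − h²`) is cut by the slab; the
  observed PSD length is the rim chord at the slab offset — the full
  diameter `2a` when the rim centre's z lies in the slab, else the chord
  at the in-plane offset `δ/√(1−n_z²)` for a rim tilted by axis
  z-component `n_z`. A config switch (`exact_arc`) replaces the chord by
  the in-slab rim arc length. The chord is the default because it is what
  a projected rim most closely resembles on an image.
* **SAL.** The synaptic apposition length is generated from the PSD chord
  by dividing by a per-profile ratio `PSD_L/SAL ~ Beta(7.5, 2.5)` (mean
  0.75, matching the observed ratio of mean PSD length 0.217 µm to mean
  SAL 0.291 µm; concentration 10 is a one-time choice giving a realistic
  sd of 0.13). Since the ratio is < 1 almost surely, every emitted profile
  satisfies `psd_length ≤ sal_length`. SAL is modelled this way, rather
  than as a second cap, because it is only ever measured in 2D.
* **Visibility.** A profile is emitted only when its PSD chord reaches
  0.05 µm — a geometric stand-in for the requirement that a synapse be
  unambiguously identifiable (visible cleft, vesicles); the threshold sits
  below the smallest PSD length reported on real sections (0.089 µm).
* **Shaft synapses are not sectioned** (the model has no shaft membrane to
  cut). This removes ~7% of true synapses from the 2D arm, which keeps
  the stereological estimate on the low side of the all-synapse truth —
  the direction reported for real data.
* **Fields of view** are sampled uniformly, inset 0.45 µm from the box
  faces (more than the largest possible head radius, 0.41 µm) so every
  field is surrounded by populated tissue, as on a real grid square.

## Density estimation (`stereology`)

* **Size-frequency.** `Na = (Nd/A)/d` with `d` the mean PSD length over
  the *counted* profiles, as a single global mean. The counting frame
  flags profiles touching the left or bottom edge (the standard unbiased
  two-edge frame); an `all_edges` mode reproduces the literal
  "not touching any edge" reading, which undercounts. Profiles are
  flagged by their head-profile disc.
* **3D count.** The default `brick` rule counts a head whose sphere
  intersects the subvolume and does not cross any of the three extended
  excluding planes (low-x, low-y, low-z): the classical unbiased counting
  brick, under which a tiling of space counts every object exactly once.
  A stricter `centroid` rule (SAS centroid inside the box, plus the same
  exclusion) is provided for comparison; it loses boundary-crossing heads
  without compensation and shows a measurable (~5–20%, geometry-dependent)
  negative edge bias, which is why it is not the default. The reference
  experiment counts inside an interior subvolume inset by the same 0.45 µm
  margin, so the counted brick is surrounded by tissue.

## Reference experiment (`experiment`)

One synthetic block of 190 µm³ (10 × 10 × 1.9 µm) at 2.0 synapses/µm³ —
a typical CA1 stratum radiatum figure, chosen because no published density
value exists to calibrate against — sectioned into 75 random 5 × 5 µm
fields (1875 µm² total, matching the ~1900 µm² sampling effort of the
motivating study), against brick counts on the interior subvolume. These
problem sizes make a full paired run take well under a second while
keeping per-run counting errors in the few-percent range. Across seeds the
size-frequency estimate centres near 2.07/µm³ and the 3D counts near
1.86 (heads) and 1.98 (all synapses) against a truth of 2.00.

## Statistics (`stats`)

Summaries report mean, SEM (sd with n−1 denominator over √n), min, max.
Frequency curves use fixed grids — 10 × 0.08 µm bins for lengths,
9 × 0.06 µm² for areas, 10 × 0.03 µm³ for volumes — starting at 0 (bin
origins are a convention; 0 keeps all three families aligned), as relative
frequencies so curves from different n are comparable; out-of-grid values
are clipped into the end bins and logged. Spearman uses mid-rank ties
(scipy). The two-group test is Mann–Whitney, exact by enumeration up to
n = 20 per group (without ties), normal approximation with continuity and
tie correction above; three or more groups use one-way ANOVA. No
multiple-testing correction is applied. Reported conversion values round
half-to-even at 3 decimals; internal computation is full precision.

## Numerical choices and degenerate inputs

Zero is a legal input to every geometry conversion (maps to zero);
negative inputs raise a domain error. Degenerate spines are filtered at
table validation, not inside the conversions. The area↔volume round trip
is exact to ≲1e-12 relative; tests enforce 1e-10 over a log sweep. Slabs
are half-open `[z0, z0 + t)` with z increasing into the block. A rim
circle with near-vertical axis (tilt factor < 1e-9) is treated as lying in
a horizontal plane: visible in full if its z is inside the slab, else
absent.

One known rounding artifact, kept deliberately: converting the printed
minimum head volume 0.004 µm³ gives an equivalent area of 0.030 µm² at
3 decimals, while the published minimum equivalent area is 0.031 µm² —
consistent with the true, unrounded minimum volume being ≈ 0.0042 µm³.
The package does not adjust for this; the pair is documented rather than
asserted.

## What the synthetic data does and does not show

The generator reproduces marginal size distributions, the SAS–volume rank
correlation, a shaft-synapse fraction, and spatial uniformity. It does
**not** model spine necks or shafts, membrane curvature, perforated or
horseshoe PSDs, non-spherical heads, spatial clustering along dendrites,
or segmentation error — so passing tests demonstrate that the estimators
are correct under the stated geometric model, not that real tissue obeys
that model. Two visible consequences: sectioned SAL-derived disc areas
overshoot the 3D SAS mean (the Beta-ratio model inflates SAL when PSD
chords are Holmes-inflated), and the 2D underestimation of head size is
milder than in real data (where oblique, non-maximal profiles are the
rule). The directions of the published 2D-vs-3D orderings are reproduced;
their exact magnitudes are not targets.
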