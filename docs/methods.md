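# Methods

## Problem and model

OCT angiography (OCTA) renders perfused vasculature from the temporal
decorrelation of OCT signals. Beneath large superficial (pial) vessels the
moving red blood cells distort the forward-propagating wavefront, so static
tissue below acquires spurious decorrelation — *tail artifacts* that trail
vertically under each vessel and overshadow the true capillaries of the
deeper cortex.

Both de-shadowing operators act on one A-line (depth profile) at a time.
Let `A(z)`, `z = 1..N`, be the nonnegative OCTA amplitude of one A-line.

**Mean subtraction** (the method this package exists for):

    A_ds(z) = A(z) − w · mean(A),     mean over all N depth pixels

with weight `w ≥ 0` (default 2.0, the empirical optimum for capillary SNR).
An A-line crossing a long tail has a larger mean, so the subtraction is
adaptively more aggressive exactly where the artifact is; A-lines without
shadow lose almost nothing. Negative results are clipped to zero by default
(`clip_negative`), since OCTA magnitudes are nonnegative.

**Step-down exponential filtering** (the classical baseline):

    A_ds(z) = A(z) · exp( −(1/γ) · Σ_{k<z} A_ds(k) )

a strictly top-down recursion: each pixel is attenuated by the accumulated,
already de-shadowed signal above it. `γ > 0` has units of cumulative
amplitude and is therefore scale-dependent. Strong overlying signal
suppresses everything beneath it — true vessels included, which is the
baseline's known weakness.

**γ matching.** To compare the two methods fairly, `match_gamma` finds the
γ at which step-down removes tail signal as strongly as mean subtraction at
a given w: it equates the mean residual amplitude inside a tail region of
interest. The residual is monotone increasing in γ, so the match is a
bracketed Brent root find on `E_sd(γ) − E_ms`; if the target residual is
outside the achievable range the nearer bracket endpoint is returned with a
warning (e.g. w = 0 ⇒ the upper bound, i.e. least attenuation).

**Volume processing.** Operators are applied independently to every (x, y)
column at and below `surface_index`; pixels above the surface pass through
unmodified and are excluded from the step-down attenuation sum, while the
mean in mean subtraction deliberately spans all N pixels of the A-line
(the literal per-A-line definition). Afterwards the whole volume is divided
by its global maximum — a pure rescale, no contrast adjustment. An optional
global histogram equalization (off by default) can make poorly illuminated
deep capillaries prominent; it delegates to `skimage.exposure.equalize_hist`
and preserves rank order.

## Projection and display

En face angiograms are maximum amplitude projections over half-open depth
slabs `[top, bottom)` specified in µm below the surface; µm→index
conversion floors, so a boundary falling mid-voxel assigns that voxel to
the deeper-starting slab, and tiled slabs never share a z index.
Projection operates on linear amplitudes; logarithmic scaling
(`20·log10(pixel/ref)`, clamped at a floor and mapped to [0, 1]) is a
display transform applied afterwards. The floor defaults to −30 dB, a
typical OCTA display range. `display_slab` anchors the 0 dB reference at
the parent volume's maximum so all slabs of one normalized volume share a
brightness scale — a slab dimmed by processing stays dim instead of being
auto-gained, which is essential when contrast of differently processed
volumes is compared.

## Evaluation metrics

* **RMS contrast** of a line profile is the population standard deviation
  of its pixel intensities (no mean normalization). `mean_rms_contrast`
  averages it over all horizontal lines of an angiogram. Contrast
  comparisons between processing variants are made on *display* images
  (volume-normalized, projected, volume-referenced log scaling): that is
  what an observer judges, the magnitudes match reported practice, and on
  linear images the comparison degenerates into a knife-edge race between
  clipping losses and renormalization gains.
* **Capillary SNR** of a profile crossing a small vessel:
  `(max over peak window − mean over background) / (σ over background)`,
  with disjoint half-open index windows. Zero background σ returns a +inf
  sentinel with a warning. On phantoms, `capillary_snr_windows` builds the
  windows from ground truth: the background tiles the profile line while
  skipping other resolved capillaries, so it measures shadow residue and
  diffuse speckle rather than neighboring vessels.
* **Cross-correlation similarity** between adjacent slab angiograms is the
  zero-lag Pearson correlation of the flattened pixels;
  `similarity_vs_depth` tiles 20 µm slabs every 5 µm (the reported inner
  angiogram gap) and reports each adjacent pair.

Population (not sample) standard deviations are used throughout for
determinism of tiny worked examples; the difference is immaterial at
realistic line lengths.

## The synthetic cortex phantom

No OCTA volumes are deposited with the original experiments, so evaluation
runs on a synthetic mouse-cortex phantom (`default_cortex_spec`):
256×128×128 voxels (z-x-y) at 4×16×16 µm pitch — ~1 mm deep, ~2×2 mm wide.
Construction order: noise floor, depth attenuation `exp(−z/L)` on all true
signal, vessels, tails, capillaries; ground-truth masks are recorded before
noise. Components, with defaults and rationale:

* **Pial vessels** — balls at depth < 100 µm, amplitude 1.0 (the unit of
  the amplitude scale). The first vessel is a dominant trunk of radius
  110–150 µm, the tail source the method targets; the others are 40–100 µm.
* **Tails** — beneath the deepest vessel voxel of each shadowed column, an
  exponential envelope `amplitude · strength · exp(−Δz/decay)` extending to
  the bottom, modulated voxel-wise by unit-mean Rayleigh speckle (tails are
  dynamic-scattering residues, i.e. speckle). Defaults: strength 0.5,
  decay 700 µm — tails that visibly persist through the imaged depth, as
  in real cortical OCTA.
* **Capillary bed** — Rayleigh speckle (scale 0.12) confined to the
  capillary-rich 400–500 µm band. The cortical capillary mesh is mostly
  below the 16 µm lateral pitch, so it appears as diffuse perfusion
  speckle. Because the band is thin relative to the A-line, it contributes
  little to the per-line mean and survives mean subtraction as faint
  texture — the behaviour real deep-slab angiograms show.
* **Resolved capillaries** — 24–40 balls of radius 5–10 µm at 300–700 µm,
  amplitude 1.1–1.4 (capillary decorrelation contrast saturates and is not
  weaker than large-vessel signal). Eight form a cross-section cluster at
  one (y, z ≈ 450 µm) line — two shadowed under the trunk, six in the open
  — so a single horizontal profile crosses the shadowed target plus
  reference capillaries; two more sit under mid-sized vessels, and the
  rest are rejection-sampled out of all vessel shadows so their ground
  truth is unambiguous. The amplitude range is a deliberate design
  constraint: at the operating point w = 2 the subtraction offset in a
  trunk column is ≈ 2× the column mean, and shadowed capillaries are
  placed and scaled to exceed it — the regime in which the method is
  demonstrated. Dimmer or deeper capillaries under the largest trunks are
  lost, which is the method's documented failure mode and reachable by
  lowering amplitudes or raising w.
* **Noise** — Rayleigh amplitude floor, scale 0.01 (≈ 40 dB below vessel
  amplitude; post-clutter-filter OCTA floors are low). A folded-Gaussian
  alternative is available.
* **Attenuation** — length 1500 µm, giving ≈ 0.74 remaining signal at
  450 µm, a mild cortical attenuation consistent with imaging usable to
  ~1 mm.

Randomness is a single seed fanned out into per-component substreams
(vessel placement, capillary placement, tail speckle, bed, noise), so
adding a capillary does not move vessels.

**What the phantom does not model:** wavefront physics (tails are imposed
geometrically, not simulated), B-frame ensembles and decorrelation
computation, vessel tortuosity and branching (vessels are balls, not
tubes), flow heterogeneity, bulk-motion artifacts, and curved cortical
surfaces (the surface is the z = 0 plane). Passing tests therefore show
that the operators behave as specified on data with the right structure
and statistics, not that they are validated on tissue.

## Numerical choices

* Step-down is evaluated with one sequential loop over z, vectorized
  across all columns; it matches a literal scalar recursion to ≤1e−12
  relative error (tested).
* `match_gamma` uses Brent root finding with rtol 1e−9 inside the user
  bracket (default 0.1–1e4), restricted to the columns intersecting the
  ROI for speed.
* Volume I/O stores float32 multi-page TIFF (z pages) plus a JSON sidecar
  {dtype, shape, axis_order, pitch, surface_index}; reading normalizes any
  axis permutation to (z, x, y) and rejects negative or non-finite voxels
  outright, naming the first offending index.
* Angiogram export rescales [min, max] linearly to the full uint16 range;
  a constant image maps to zeros with a warning rather than an error.
* Degenerate inputs: all-zero volumes skip normalization with a warning;
  constant volumes skip equalization; constant images make Pearson
  similarity an error (named offender) and SNR a +inf sentinel.

## Problem sizes used in the test suite

The full suite runs the complete pipeline on five default phantoms
(seeds 0–4) for the comparative properties, one phantom (seed 7) for tail
suppression, and 100 random A-lines of length 64 for the recursion oracle;
it completes in well under a minute on one CPU. `scripts/acceptance.py`
repeats the pipeline on a single seed-derived phantom.

## Known limitations

* γ is scale-dependent; matched values are meaningful only for the volume
  they were matched on.
* Mean subtraction can delete capillaries whose amplitude falls below the
  per-line offset — by design it trades a small risk of loss under the
  largest vessels for preservation elsewhere.
* The contrast ordering between methods is asserted on display-referenced
  log images; on raw linear images the ordering is not stable, and no
  claim is made there.
* `similarity_vs_depth` on near-structureless slabs can raise (constant
  image) — callers should restrict the depth range to where signal exists.
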