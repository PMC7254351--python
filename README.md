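# octa-deshadow

Removal of multiple-scattering **tail artifacts** from volumetric OCT
angiography (OCTA), for researchers quantifying cerebral microvasculature.

Beneath large superficial (pial) vessels, moving red blood cells distort
the optical wavefront and imprint spurious decorrelation on the static
tissue below. These vertical "tails" shadow the true capillaries of the
deep cortex and corrupt en face angiograms. This package implements:

* **Mean-subtraction de-shadowing** — per A-line `A(z) − w·mean(A)` with
  the mean over all N depth pixels and clipping at zero. A-lines with
  longer tails have larger means, so the subtraction is adaptively more
  aggressive exactly where the artifact is. `w ≈ 2` maximizes deep
  capillary SNR.
* **Step-down exponential filtering** — the classical baseline
  `A_ds(z) = A(z)·exp(−(1/γ)·Σ_{k<z} A_ds(k))`, plus `match_gamma` to
  calibrate γ for equal tail attenuation so the two methods can be
  compared fairly.
* **Projection** — half-open depth slabs in µm, maximum amplitude
  projection, log display scaling with a shared volume reference.
* **Metrics** — per-line RMS contrast of angiograms, capillary SNR under a
  weight sweep, and zero-lag Pearson similarity between adjacent slabs.
* **A synthetic cortex phantom** — pial vessels with speckled tails,
  depth attenuation, a diffuse capillary-bed band, resolved deep
  capillaries (some deliberately shadowed) and Rayleigh noise, with
  ground-truth masks for scoring. See `docs/methods.md` for the model and
  all defaults.

## Worked example

```python
import octa_deshadow as od

# a synthetic mouse cortex: ~1 mm deep, 2x2 mm wide, with ground truth
spec = od.default_cortex_spec(seed=1)
vol, truth = od.generate_phantom(spec)

# de-shadow with the default weight, keep absolute amplitudes
ms = od.deshadow_volume(vol, od.DeshadowParams(w=2.0, normalize_output=False))
residual = ms.data[truth.tail_mask].mean() / vol.data[truth.tail_mask].mean()
print(f"tail residual after w=2: {100 * residual:.1f}%")

# calibrate the step-down baseline to the same tail attenuation
gamma = od.match_gamma(vol, 2.0, truth.tail_mask)
print(f"matched gamma: {gamma:.3f}")

# deep-slab contrast, measured on display images (normalized, projected,
# log-scaled against the volume maximum)
for label, params in [("original", od.DeshadowParams(w=0.0)),
                      ("mean-sub", od.DeshadowParams(w=2.0)),
                      ("step-down", od.DeshadowParams(method="step_down", gamma=gamma))]:
    img = od.display_slab(od.deshadow_volume(vol, params), 440, 460)
    print(f"{label:10s} deep-slab RMS contrast: {od.mean_rms_contrast(img)['mean']:.4f}")
```

prints

```
tail residual after w=2: 1.2%
matched gamma: 0.669
original   deep-slab RMS contrast: 0.0816
mean-sub   deep-slab RMS contrast: 0.1051
step-down  deep-slab RMS contrast: 0.0549
```

Mean subtraction removes ~99% of the tail amplitude while *raising* the
deep-slab contrast above the original (hidden capillaries resurface);
step-down filtering, matched to the same tail attenuation, erodes the deep
signal and lands well below both — the characteristic ordering between the
three images.

The same workflows are scriptable from the shell:

```bash
deshadow phantom --seed 7 --out out/phantom
deshadow run --phantom-seed 7 --slab 400:420 --slab 440:460 --slab 480:500 --out out/run
deshadow sweep-w --phantom-seed 7 --grid 0,0.5,1.0,1.5,2.0,2.5,3.0,3.5 --out out/sweep
deshadow compare --phantom-seed 7 --out out/compare
```

Every run writes a manifest (config, seed, version), metrics as CSV/JSON,
and 16-bit angiogram images; identical config and seed reproduce outputs
byte for byte.

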