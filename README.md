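# menisq

Quantitative mono- and biexponential T2* relaxometry for short-T2*
fibrocartilage (meniscus, tendon), built for multi-echo gradient-echo /
variable-echo-time magnitude data. It is aimed at quantitative-MRI
researchers who need voxel-wise and ROI-averaged decay fitting with honest
model selection, plus fully synthetic phantoms so that every stage of the
pipeline is testable without scanner data.

## What it computes

Each decay curve is fitted with two nested models (TE in ms):

- monoexponential: `S(TE) = A1 e^(-TE/T2*) + eps` (3 parameters)
- biexponential: `S(TE) = B1 e^(-TE/T2*s) + B2 e^(-TE/T2*l) + eps`
  (5 parameters, short fraction `Fs = 100 B1/(B1+B2)`)

by bounded trust-region least squares (short component in [0, 20] ms, long
in [0, 200] ms), with a mono-seeded restart that guarantees
`SSE_bi <= SSE_mono`. Whether the extra two parameters are warranted is
decided per voxel and per ROI by

- the small-sample Akaike criterion
  `AICc = 2k + n ln(SSE/n) + 2k(k+1)/(n-k-1)` (lower wins), and
- the nested F-test
  `F = ((SSE_mono - SSE_bi)/SSE_bi) * (v_bi/(v_mono - v_bi))`, `v = n - k`,
  referred to F(2, n-5), biexponential when p < 0.05,

yielding binary decay-type maps, fraction maps, and per-slice/per-ROI
summary tables. Orientation dependence of T2* is modelled through the
dipolar factor `D(theta) = 3 cos^2(theta) - 1` with relaxation-rate
modulation `R2*(theta) = R2*_iso + C D(theta)^2`, which peaks T2* at the
magic angle (~54.7 deg). The phantom module synthesizes meniscus-like
multi-echo volumes (zonal geometry, mono/bi decay, Gaussian or Rician noise
at a configurable first-echo SNR, fiber-angle-dependent T2*) together with
ground-truth maps. See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

Voxel-level analysis misses biexponential decay that ROI averaging (here
100 voxels per slice, ~10x SNR gain) resolves — the central mechanism the
package demonstrates:

```python
from menisq import (BiParams, EchoSchedule, PhantomSpec, RegionSpec,
                    synthesize_echo_series, mask_foreground, fit_volume,
                    select_voxels, biexp_percentage, roi_fit_and_select)

te = EchoSchedule((0.82, 1.82, 2.82, 7.23, 9.23, 11.23, 13.39,
                   15.39, 17.39, 19.55, 21.55, 23.55))
tendon = RegionSpec(label=1, geometry="band", geometry_params={},
                    decay_kind="bi",
                    iso_params=BiParams(56.14, 43.86, 1.34, 4.50, 0.0))
spec = PhantomSpec(grid_shape=(10, 10, 10), voxel_size_mm=(0.25, 0.25, 0.4),
                   regions=(tendon,), fiber_angle_deg=0.0,
                   noise_model="gaussian", snr_first_echo=35.0, seed=7)
series, truth = synthesize_echo_series(spec, te)

mask = mask_foreground(series, threshold_factor=5.0, noise_sd=truth.noise_sd)
mono_maps, bi_maps = fit_volume(series, te, mask, model="both")
sel = select_voxels(mono_maps, bi_maps, alpha=0.05)
print(f"voxel-wise %bi (F-test): {biexp_percentage(sel.prefer_bi_ftest, sel.valid):.1f}")

summary, _ = roi_fit_and_select(series, te, mask, alpha=0.05)
print(f"ROI-averaged slices %bi (F-test): {summary['pct_bi_ftest']:.0f}")
print(f"ROI T2*s = {summary['t2s_ms_mean']:.2f} +/- {summary['t2s_ms_sd']:.2f} ms, "
      f"T2*l = {summary['t2l_ms_mean']:.2f} +/- {summary['t2l_ms_sd']:.2f} ms, "
      f"Fs = {summary['fs_percent_mean']:.1f}%")
```

prints

```
voxel-wise %bi (F-test): 29.8
ROI-averaged slices %bi (F-test): 100
ROI T2*s = 1.32 +/- 0.11 ms, T2*l = 4.47 +/- 0.18 ms, Fs = 55.4%
```

The simulated tissue is a biexponential mixture with closely spaced
components (1.34 / 4.50 ms, Fs = 56.1%). At voxel SNR 35 the F-test
resolves it in only ~30% of voxels; the ROI-averaged curves (SNR ~350)
are flagged biexponential in every slice, and their fitted parameters
recover the ground truth closely.

## Command line

```sh
menisq simulate --config phantom.yaml --out out/      # phantom + ground truth
menisq fit --in series.nii.gz --model both --out out/ # voxel-wise maps
menisq select --fit-dir out/ --alpha 0.05 --out out/  # decay-type/fraction maps
menisq roi --series series.nii.gz --labels rois.nii.gz --out out/
menisq run --config pipeline.yaml                     # all stages + provenance
```

Series are 4D NIfTI with echoes on the 4th axis; echo times (ms) live in a
JSON/YAML sidecar. ROI labels are integer NIfTI volumes with an optional
YAML role map.

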