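# whiskbroom

A whisk-broom hyperspectral imaging toolkit: the complete computational
stack for a gimbal-scanned single-point spectroradiometer — sensor
calibration, per-pixel HDR auto-exposure acquisition, scan projection,
and radiometric/visual rendering — runnable and testable against a
fully simulated instrument, no hardware required.

## What's inside

| Module | Role |
| --- | --- |
| `whiskbroom.spectral` | Core types (raw/dark frames, wavelength polynomial, spectra) and photosite math: count linearisation `c = exp(ln(r−d)·a + b)`, boxcar spectral compression, Gaussian smoothing |
| `whiskbroom.instrument` | Virtual instrument: forward sensor model (sensitivity, affine dark current, invertible nonlinearity, shot-noise-like noise, saturation), gimbal geometry, and deterministic reference scenes (`flat`, `blackbody-like`, `narrowband-set`, `hdr-night`) |
| `whiskbroom.acquisition` | Firmware decision logic: octave exposure ladders (500 µs minimum, 30 s hard cap → 1:60,000 by integration time alone), dark-frame scheduling, cosine pole-skip scan planning with per-photosite interpolation, full scan execution |
| `whiskbroom.calibration` | Linearisation-coefficient fitting from an integration-time ladder; spectral-sensitivity estimation from a white-standard scan vs. a reference radiance spectrum; `calibration_data.txt` I/O |
| `whiskbroom.radiometry` | Absolute radiance conversion, relative reflectance, sRGB / extended-range (NIR–Y–UV) / saturation / NDVI previews, quantal cone-catch channels, scene peak-ratio statistics |
| `whiskbroom.scanfile` / `whiskbroom.cli` | Documented text scan-file format (lossless round trip) and the `whiskbroom` command-line interface |

## CLI

```sh
# scan a synthetic night scene (byte-identical for a fixed seed)
whiskbroom simulate --scene hdr-night --out scan.txt --seed 1

# fit the linearisation coefficients on the simulator; print a, b, R^2
whiskbroom calibrate-linearity --seed 1 --plot-data ladder.csv

# white-standard scan + reference spectrum -> calibration file
whiskbroom calibrate-sensitivity scan.txt reference.csv \
    --lin-a 1.04 --lin-b 0.2 --out calibration_data.txt

# radiance / reflectance spectra, previews, cone catches, statistics
whiskbroom radiance scan.txt --calibration calibration_data.txt --pixel 2,3 --out spec.csv
whiskbroom export-spec scan.txt --calibration calibration_data.txt \
    --pixel 2,3 --standard-pixel 0,0 --out refl.csv
whiskbroom render scan.txt --calibration calibration_data.txt --mode srgb --out preview.png
whiskbroom cone-catch scan.txt --calibration calibration_data.txt \
    --receptors sensitivity_data.csv --outdir catches/
whiskbroom peak-ratio scan.txt --calibration calibration_data.txt
```

Every subcommand accepts `--seed`, `--config` (flat key/value YAML
overriding simulator parameters such as `noise_gain` or `peak_ratio`)
and `--verbose`.

## File formats

- **Scan file** — text; header `key<TAB>value` block, then `D`
  (dark-frame) and `P` (pixel) records with integer counts; see the
  `whiskbroom.scanfile` docstring.
- **calibration_data.txt** — `key=value` blocks per unit
  (`unit`, `wl_coeffs`, `lin_a`, `lin_b`, `sensitivity`); `#` comments
  and blank lines ignored; multiple units per file.
- **sensitivity_data.csv** — `wavelength_nm` column plus one named
  column per receptor.
- **Reference/exported spectra** — 2-column CSV
  (`wavelength_nm,radiance` or `wavelength_nm,reflectance_percent`).
- Previews are 8-bit PNG; cone catches are 32-bit float TIFFs.
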