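# dtspos

Narrow-arc digital tomosynthesis (DTS) reconstruction and translational
registration for radiotherapy patient positioning, exercisable end to end on
built-in digital phantoms — no external data required.

The pipeline mirrors the clinical workflow:

1. **Forward projection** — divergent-beam line integrals (DRRs) of a
   planning-CT-like voxel volume over a full-fan cone-beam protocol
   (200°, 375 views by default).
2. **DTS reconstruction** — filtered back-projection (log conversion,
   cosine pre-weighting, row-wise FFT ramp filtering, distance-weighted
   back-projection) of a narrow arc into coronal (arc centered at 0°) or
   sagittal (centered at 270°) plane stacks. Onboard stacks (ODTS) come
   from intensity-domain projections, reference stacks (RDTS) from DRRs.
   Half-fan pairs can be stitched with a linear cross-fade.
3. **Two-session registration** — normalized cross-correlation with
   parabolic sub-pixel refinement on the focal planes: the coronal pair
   yields (LAT, LNG), the sagittal pair (LNG, VRT), and the two LNG
   estimates are averaged into the 3D couch correction.

Every compute stage has two engines sharing one mathematical contract: a
brute-force per-ray / per-voxel **oracle** and a batched **fast** kernel
(both numba-compiled; the fast kernels factorize shared terms and run with
fastmath). Validation studies compare them via Pearson correlation and
rescaled subtraction statistics.

## Layout

- `src/dtspos/geometry.py` — cone-beam scan geometry, arc selection, rays
- `src/dtspos/phantoms.py` — voxel volumes, cube / pelvis phantoms, rigid shifts
- `src/dtspos/drr.py` — DRR engines, intensity/line-integral conversion, projection I/O
- `src/dtspos/recon.py` — ramp filtering, FDK-style back-projection, half-fan stitching
- `src/dtspos/registration.py` — NCC registration, two-session shift fusion
- `src/dtspos/metrics.py` — correlation, subtraction stats, sub-pixel edge lengths
- `src/dtspos/studies.py` — end-to-end validation studies at configurable scales
- `src/dtspos/cli.py` — command-line interface

## CLI

```bash
# forward-project a saved volume (raw + JSON) using a geometry config
dtspos drr --volume path/to/vol_dir --config geom.yaml --out proj_dir

# reconstruct a coronal stack from a 40 deg arc around 0 deg
dtspos dts --projections proj_dir --orientation coronal --center 0 --arc 40 --out dts_dir

# two-session registration of onboard vs reference stacks
dtspos register --odts-cor A --rdts-cor B --odts-sag C --rdts-sag D --report shift.json

# phantom validation studies (JSON + CSV reports)
dtspos validate geometric --out report.json
dtspos validate registration --out report.json
dtspos validate correlation --out report.json

# end-to-end workflow: phantom -> DRR -> ODTS/RDTS -> registration
dtspos simulate --phantom pelvis --shift 3 0 0 --arc 40 --out sim_dir
```

Geometry configs are YAML/JSON with keys `sad_mm`, `sdd_mm`,
`detector {nu, nv, pixel_mm}`, `scan {start_deg, range_deg, n_projections}`
and optional `arcs [{center_deg, arc_deg}]`. Validation commands accept a
config with a `scale:` section overriding any `StudyScale` field.

## Conventions

Patient axes (LAT, LNG, VRT) form a right-handed frame at the isocenter;
gantry 0° has the source anterior (coronal view), 270° lateral (sagittal
view); SAD/SDD default to 1000/1500 mm; detector pixels are 0.776 mm at
full scale (0.517 mm at the isocenter plane); DTS stacks default to 0.5 mm
in-plane pixels. Volumes and projections persist as raw float32 + JSON
metadata.
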