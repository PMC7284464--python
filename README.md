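# spindry

Intra-vial primary-drying kinetics of spin-frozen vials from
time-resolved micro-CT, as a reusable pipeline:

1. **phantom** — renders synthetic 4D-CT series of a vial with an
   annular frozen layer (axial/azimuthal thickness gradients, cracks,
   cavities, gripper spots, partial-volume boundaries, seeded noise)
   plus rotation-synchronised thermal movies, all with known ground
   truth, so every downstream stage is testable without scanner data.
2. **tomo** — converts cartesian volumes to an (r, phi, h) cylindrical
   grid, segments the frozen layer, and extracts per-(phi, h) metrics:
   frozen thickness `L_ice`, integrated radial ice length `L_ice'`
   (their relative difference diagnoses non-radial sublimation) and the
   innermost ice radius `r_p`.
3. **physics** — ice vapour pressure, sublimation enthalpy and the
   vial-level heat-balance solver for the interface temperature.
4. **resistance** — regresses local dried-product mass-transfer
   resistance profiles `R_p(L_dr)` per (phi, h) coordinate
   (Savitzky-Golay smoothing, annular segment volumes, sublimation
   rates, projected areas; 38 dried-thickness bins over 0–2.5 mm).
5. **endpoint** — predicts the per-coordinate primary-drying endpoint
   distribution by time-stepping the coupled heat/mass balance with
   spline-interpolated resistance profiles and spatial binning.
6. **thermal** — emulates the thermal-imaging verification: field-of-view
   geometry, unwrapping of rotation-synchronised movies into per-pixel
   traces, sharp-rise endpoint detection, and endpoint-distribution
   comparison (histograms, CDFs, quantiles, correlation).
7. **pipeline** — schema-validated configuration, provenance metadata
   and a CLI that runs each stage separately or end to end.

## Test

```sh
python -m pytest -q tests/
```

The suite generates all of its inputs (phantoms, movies, traces) at
test time; the full run takes a few minutes on one CPU.

## CLI

Every stage is a subcommand writing into a run directory:

```sh
spindry run-all --outdir runs/demo --seed 1          # built-in demo config
spindry phantom --config my_run.json --outdir runs/a
spindry extract --outdir runs/a
spindry rp --outdir runs/a
spindry simulate --outdir runs/a
spindry thermal --outdir runs/a
spindry compare --outdir runs/a
```

Volumes are TIFF stacks (`frame_00000.tif`, ...) with a JSON sidecar;
layer series, resistance profiles and ground truth are HDF5; maps,
histograms and step history are CSV. Identical config + seed reproduce
byte-identical tabular outputs.

A configuration file is a single JSON (or YAML) document with
`geometry`, `phantom`, `physics`, `simulate` and `thermal` blocks; see
`spindry.pipeline.demo_config()` for a complete small example
(16 x 10 surface coordinates, ~20 scans, end-to-end in ~15 s).

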