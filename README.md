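# microvns

Modeling and morphometry for **micro-magnetic vagus nerve stimulation
(µM-VNS)**: quasi-static electromagnetic simulation of sub-millimeter
stimulation coils next to the rat cervical vagus nerve, compared against
conventional cuff-electrode electrical VNS (eVNS), plus a TEM-style
cross-section morphometry pipeline (myelinated-fiber segmentation, size
classification, weighted cityblock k-means clustering, and the
diameter-versus-distance regression) driven by a synthetic image
generator with per-fiber ground truth.

## The problem

Electrical VNS passes current through electrodes in galvanic contact
with a mixed nerve, recruiting afferent and efferent fibers
indiscriminately; efferent cardiac fibers make bradyarrhythmia a known
risk. A micro-coil driven with fast current pulses instead induces a
solenoidal electric field by Faraday induction — no contact, no net
charge injection, and a much more focal field. Whether such a coil can
drive the large myelinated fibers of the vagus, and how focal its
activation volume is compared to a cuff pair, is a modeling question
this package answers quantitatively.

## Models

**Electromagnetic arm.** A coil is a discretized line current
(21-turn solenoid or 8.5-turn planar spiral on an 0402 footprint, turn
geometry calibrated so a Neumann-formula inductance estimate matches the
part's nominal value). Under the quasi-static approximation the induced
field decomposes as

    E = −(dI/dt)·A/I − ∇φ,

where `A` is the vector potential of the unit-current coil (exact
analytic per-segment expressions) and the scalar potential enforces
charge conservation `∇·(σ(E_primary − ∇φ)) = 0` with zero normal current
on the surface of the voxelized nerve (σ = 0.27 S/m), solved by
finite-volume conjugate gradients. Fields are linear in `dI/dt`, so RMS
maps come from a scalar drive factor rather than time stepping. The
activating function `AF = ∂Ex/∂x` (x = fiber axis) thresholds at
1×10⁵ V/m² to give the volume of activation (VOA) and selectivity
`S = VOA / (π r² h)`. eVNS is a Laplace solve with equipotential cuff
contacts and exact current-mode rescaling.

**Morphometry arm.** Synthetic nerve cross-sections emulate the measured
statistics of the rat cervical vagus: ~2,000 non-overlapping myelinated
fibers in a ~320 µm ellipse, a bimodal log-normal outer-diameter mixture
with population median 2.98 µm, and a linear decrease of diameter with
distance from the epineurium (slope −0.009 µm/µm). Segmentation is
threshold-based particle analysis (contrast stretch → three-level
partition → annulus hole-filling → area/circularity filters); fibers
above the size threshold are clustered with k-means under the cityblock
distance, diameter-bin weights implemented as point multiplicities and
the per-coordinate weighted median as the exact L1 centroid update.

## Worked example

```bash
microvns em --set grid_spacing_m=1e-5 --set "nerves=[block,cylinder]" \
            --set evns.enabled=false --out em_out
```

prints (10 µm grid; a few minutes on one CPU):

```
"block_spiral": {
  "e_max_rms": 13.84,
  "af_max_abs": 123025.6,
  "depth_at_6Vpm": 0.000112,
  ...
},
"cylinder_spiral": {
  "e_max_rms": 9.28,
  ...
}
```

Read: driven with 10 A exponential pulses (10 µs width), the planar
spiral 5 µm above the nerve block induces a maximum RMS field of
~13.8 V/m and a maximum activating function of ~1.2×10⁵ V/m²; the field
stays above the 6 V/m large-fiber activation level down to ~112 µm. The
comparison table in `em_out/em_report.json` shows the spiral's surface
field exceeding the solenoid's by ~1.34× on the same grid. On the
cylindrical nerve the spiral reaches ~9.3 V/m.

```bash
microvns morph --seeds 1-5 --out morph_out
```

```
{
  "n_seeds": 5,
  "mean_slope": -0.008982803107357627,
  "sd_slope": 0.0011887556667076297,
  "mean_median_diameter_um": 2.9713636005981257
}
```

Read: across five synthetic nerves, segmentation recovers the
generator's diameter–distance slope and the 2.98 µm median diameter
through the full image pipeline. Per-seed fiber tables, Table-style
summaries, regression JSONs, cluster centroids and QC overlays land in
`morph_out/`.

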