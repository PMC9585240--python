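# Methods

## Quasi-static field model

The coil is modeled as a line current on the conductor centerline.
Both the vector potential `A` and the flux density `B` of each straight
segment are evaluated with the exact finite-segment expressions
(`A ∝ û ln[(r₁+s₁)(r₂−s₂)/ρ²]`, `B ∝ (û×ρ̂)/ρ·(s₁/r₁ − s₂/r₂)`), with
the perpendicular distance clamped at the wire radius so points on the
conductor stay finite. No finite-trace-cross-section correction is
applied; at a 5 µm standoff from a 7 µm trace this is the standard line
current idealization.

The induced field is `E = −(dI/dt)·A/I − ∇φ`. Displacement currents
are dropped despite the large tissue permittivity (εr = 5,133): at the
pulse content used here (≲100 kHz), ωε/σ ≈ 0.03–0.1, so the conduction
current dominates. The correction potential solves
`∇·(σ(E_primary − ∇φ)) = 0` on the conductive voxels with zero normal
total current on the conductor surface — discretized with a
cell-centered finite-volume scheme (harmonic-mean face conductivities;
insulating boundary faces simply carry no flux). The pure-Neumann
system is singular up to a constant, so the right-hand side is
projected onto the solvable subspace and φ returned mean-free;
conjugate gradients with a Jacobi preconditioner iterate to a 1e-8
relative residual (an exception reports the residual on
non-convergence). Gradients (∇φ, the gradient tensor and the
activating function) use central differences in the interior and
one-sided differences at the conductor boundary.

Because every field is linear in the drive, RMS maps are per-unit-
current solutions scaled by a scalar drive factor instead of being
time-stepped.

### Drive convention

Exponential pulses `i(t) = I_peak e^{−t/τ}` (τ = 10 µs, truncated at
5τ; five pulses at 20 Hz; I_peak = 10 A) admit two RMS conventions,
both implemented:

* `rms_drive_factor` — time-domain RMS of dI/dt over the union of pulse
  supports: `(I/τ)·√((1−e^{−2c})/(2c))` ≈ 3.2×10⁵ A/s for cutoff c = 5.
* `harmonic_drive_factor` — the harmonic equivalent `ω·I_peak/√2` at the
  pulse's characteristic frequency ω = 2π/τ ≈ 4.4×10⁶ A/s.

The study arm defaults to the harmonic convention: the frequency-domain
quasi-static solver picture (a sinusoidal drive at 1/pulse-width) is
the natural match for how RMS field maps of a pulsed micro-coil are
produced by commercial low-frequency solvers, and the time-domain
support RMS depends on an essentially arbitrary truncation window. The
choice is a config switch (`drive.convention`).

### Coil reconstruction

Interior dimensions of the two commercial parts are not public, so
both are anchored to their 0402 package and nominal inductances using
the package's own Neumann estimator (segment-pair double sum; external
straight-wire self term `μ₀l/2π·(ln(2l/a)−1)`; near pairs refined by
8×8 sub-filament quadrature — the estimator reproduces the classical
circular-loop formula to ~1% for thin wires):

* planar spiral — 8.5 turns, 7 µm trace, rounded-rectangular profile
  (matching the SEM appearance of thin-film parts), outer extent
  0.94 × 0.44 mm, turn pitch solved so the estimate equals the nominal
  33 nH (≈24 µm);
* solenoid — 21 turns of 7 µm wire, close-wound (pitch = 1.1 wire
  diameters, as in wire-wound chip parts), winding diameter solved for
  the nominal 100 nH (≈0.26 mm).

This reconstruction is the dominant systematic uncertainty of the EM
arm. A termination-corrected spiral footprint (0.60 × 0.44 mm, end caps
excluded) also calibrates to 33 nH; it concentrates the field — better
matching gradient-structure observations at the cost of a higher
surface maximum — and is reachable through the config. Quantities that
depend on the absolute lateral field scale (the 6 V/m depth, the
solenoid-takeover depth, the cylinder activating-function maximum and
hence the selectivity) are the ones most sensitive to this choice.

### Grids and problem sizes

Default voxel spacing is 5 µm (block 1.5 × 0.3 × 0.3 mm → 300×60×60
voxels; cylinder r = 150 µm; flattened model an area-preserving 2:1
ellipse). The test suite solves at 10 µm, the acceptance script at
5 µm — single coarse solves of 10⁵–10⁶ unknowns chosen so a
configuration solves in seconds to a few minutes on one CPU. Halving
the spacing moves reported field maxima by a few percent; the
activating function converges more slowly, so `af_max_refined`
evaluates ∂E_primary,x/∂x analytically on a 1.5 µm patch around the
coarse maximum and adds the (smooth) conduction term interpolated from
the coarse grid.

### eVNS

Cuff contacts are ideal equipotential rings (no interface impedance) at
±V/2 separated by 1.5 mm; the Laplace solve uses the same finite-volume
machinery with Dirichlet rows eliminated, and current mode rescales the
unit-voltage solution exactly (fields are linear in the drive). The
drive amplitude for field maxima is a config input (default the in-vivo
0.5 mA); reported eVNS maxima therefore scale linearly with it.

## Synthetic cross-sections

The generator emulates the statistics the morphometry pipeline assumes:

* elliptical nerve, default semi-axes 160 × 160 µm (≈320 µm across,
  ≈80,400 µm² — the area scale of the measured nerves);
* 2,000 fibers by default (≈25×10³ fibers/mm², inside the measured
  21–41×10³ range);
* outer diameter from a two-component log-normal mixture — weights
  0.55/0.45, component medians in ratio ≈ 2.1, log-sd 0.32/0.22 —
  rescaled so the mixture median equals 2.98 µm. The component shapes
  are this package's choice (no published mixture parameters exist);
  they produce the observed clear bimodality of large and small fibers;
* diameters shift linearly with distance to the epineurium
  (−0.009 µm/µm by default), truncated at 0.3 µm. Packing feasibility
  couples size and position slightly, so the applied shift is corrected
  iteratively until the realized OLS slope of the truth table equals
  the requested value (≤3 packing passes);
* fibers are circles placed by dart throwing with per-fiber position
  retries (largest first), a 0.5 µm rim gap, and optional large-fiber
  hotspot disks and/or a peripheral ring for constructing clustered
  organizations;
* rendering: dark myelin annulus from the outer diameter down to the
  axon at g·d (g = 0.6), light axoplasm, mid-gray endoneurium, darker
  epineurium rim, additive Gaussian noise (σ = 6 gray levels), 0.2 µm
  pixels. Annuli are drawn at least ~1.5 px wide so thin sheaths
  rasterize as closed rings.

Same seed → bit-identical truth table and image.

**What passing on synthetic data does not show.** The generator has no
stitch seams, stain gradients, unmyelinated fibers, non-circular
profiles, or g-ratio variation; segmentation accuracy measured here
(recall/precision ≳ 0.99) is an upper bound on real-TEM performance,
and the recovery results validate the pipeline's statistics, not its
robustness to imaging artifacts.

## Segmentation and morphometry

Contrast is percentile-stretched (1–99%), the image partitioned into
three intensity classes (multi-Otsu; myelin = darkest class; a binary
Otsu fallback covers degenerate images). Oversized dark components
(the epineurium rim) are removed *before* hole-filling — otherwise the
filled rim swallows the interior — then annuli are closed with a
4-connected closing, filled, labeled, and filtered by area (≥3 px) and
circularity (≥0.3; no upper bound, because digital perimeters make
few-pixel disks measure circularity well above 1). Diameters are
area-equivalent outer diameters (myelin included — the measurement
convention is part of the column name); distance to the epineurium is
centroid-to-boundary-polygon. Size classes split strictly above the
threshold (table median by default; 2.98/2.97 µm reproduce the
reference analyses). The regression is ordinary least squares with a
t-based 95% CI on the slope.

## Clustering

Weights come from half-open diameter bins ([threshold,6)→1, [6,9)→2,
[9,12)→3, [12,15)→4, [15,∞)→5 — the contiguous resolution of the
reference bin list) and act as point multiplicities. Lloyd iterations
alternate L1 assignment (ties to the lowest cluster index) with
weighted per-coordinate medians (even multiplicity → the lower middle
value); cost is verified non-increasing each step; empty clusters are
re-seeded at the worst-served point; best of five k-means++-style
starts; points are canonically ordered first so results are independent
of input order. A cluster is peripheral when its centroid is within
0.25 area-equivalent nerve radii of the boundary.

## Known limitations

* Coil interiors are reconstructions; absolute field values carry a
  ±25% geometric uncertainty and profile-shape quantities more.
* The conduction solve omits epineurium/perineurium layers and
  frequency-dependent dispersion.
* Fiber recruitment is summarized by imported thresholds (6 V/m,
  1×10⁵ V/m²), not compartmental neuron models.
* The generator's mixture shapes are calibrated to the median and
  density only; higher moments of the diameter distribution are not
  constrained by data.
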