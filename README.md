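# cellpol

Single-cell polarity, morphology, intensity and junction quantification from
multi-channel 2-D microscopy images with instance segmentation masks — plus
the circular and estimation statistics needed to describe the *collective*
behaviour of a cell monolayer.

## Who this is for

Labs studying polarised cell collectives — e.g. endothelial monolayers under
flow-induced shear stress — that image a junction/membrane marker
(VE-cadherin), nuclei (DAPI), an organelle (Golgi) and/or an expression
marker, segment single cells, and want reproducible per-cell feature tables
and per-image collective statistics instead of hand-curated measurements.

## What it computes

**Per cell** (from label masks and channel views):

- *Morphology*: area, perimeter, circularity 4πA/P², eccentricity, axial
  shape orientation φ ∈ [0°, 180°), length-to-width ratio (LWR) of the
  intensity-equivalent ellipse, and a cue-referenced mirror-symmetry score
  (IoU of the two cell halves after reflection about the axis through the
  centroid perpendicular to the cue).
- *Directed polarity angles* α ∈ [0°, 360°): nucleus→Golgi polarity,
  nucleus displacement (cell centre → nucleus), marker polarity (cell
  centre → intensity-weighted centroid), all via
  α = σ·atan2(ȳ_f − ȳ_r, x̄_f − x̄_r), with σ = ±1 encoding the y-axis
  direction of the raster.
- *Cue directional intensity ratio* s_r = 1 − 2·I_rear/I_cell ∈ [−1, 1]:
  the front/rear asymmetry of a marker relative to a cue direction α_p.
- *Compartment intensities*: totals and means in nucleus, cytosol
  (cell \ nucleus) and a membrane band, and the nucleus/cytosol ratio.
- *Junction morphometrics* in a band of user-chosen thickness around the
  cell outline: interface area, Otsu-positive protein area, interface
  occupancy, intensity per interface area and cluster density.

**Per image** (collective statistics): resultant vector of per-cell unit
vectors r_i = (cos α_i, sin α_i) giving the polarity index R = ‖(1/N)Σr_i‖,
circular variance S = 1 − R, mean direction ᾱ with 95% CI, and the signed
polarity index V = R·cos(ᾱ − α_p) against a known reference direction.
Axial data (shape orientation, period 180°) are handled by angle doubling
θ = 2φ. Uniformity tests: Rayleigh, V-test (u = V√2n), Watson's U² and
Rao's spacing (seeded Monte-Carlo null). Circular–linear (Mardia) and
circular–circular (Jammalamadaka–SenGupta) correlations. Group differences
of per-image indices are reported as bootstrap-coupled effect sizes
(mean difference with percentile/BCa CI) rather than p-values.

A synthetic-monolayer generator (`cellpol.generate`) produces confluent
multi-channel images with full per-cell ground truth, so every feature is
validated by parameter recovery.

## Worked example

```python
import cellpol as cp

# a flow-polarised monolayer: the Golgi relocates upstream of the nucleus,
# so organelle bearings concentrate around 210 deg while the cue is at 0
spec = cp.SyntheticSpec(n_cells=50, seed=1,
                        organelle_bearing=("vonmises", 210.0, 4.0))
img = cp.generate(spec)

cfg = cp.RunConfig(channels={"junction": 0, "nucleus": 1, "organelle": 2},
                   cue_direction_deg=0.0)
df, report = cp.extract_image_features(
    img.channels, cfg,
    cell_labels=img.cell_labels, nucleus_labels=img.nucleus_labels)

angles = cp.AngleSample.from_degrees(
    df["angle_nucleus_golgi_deg"].dropna().to_numpy())
summ = cp.signed_polarity_index(angles, 180.0)  # expected: against the cue
lo, hi = cp.mean_ci(angles, seed=0)
print(f"mean direction: {summ.mean_deg:.1f} deg  (95% CI {lo:.1f}-{hi:.1f})")
print(f"polarity index R = {summ.R:.3f}, signed index V = {summ.V:.3f}")
print(f"V-test p = {cp.v_test(angles, 180.0).p_value:.2e}")
```

prints

```
mean direction: 207.3 deg  (95% CI 199.0-215.6)
polarity index R = 0.877, signed index V = 0.779
V-test p = 3.24e-15
```

i.e. the 50 measured nucleus→Golgi bearings cluster tightly around 207°
(the generative distribution was von Mises at 210°, concentration κ = 4,
whose theoretical resultant length is I₁(4)/I₀(4) ≈ 0.864), the collective
is strongly polarised (R = 0.877) and strongly aligned with the expected
upstream direction (V = 0.779 against the 180° reference), which the
V-test confirms.

The same pipeline runs from the shell — `cellpol synth` writes a synthetic
stack, `cellpol extract run.yml` produces per-cell and collective CSVs plus
a log and the resolved configuration, `cellpol stats` summarises any angle
column and `cellpol compare` computes bootstrap effect sizes between
conditions. Inputs are TIFF + YAML; outputs are CSV/YAML/SVG, each CSV
stamped with package version, seed and a configuration hash.

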