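# hvmkit

Automated, fully unattended analysis of handheld vital microscopy (HVM)
recordings of the sublingual microcirculation.

HVM devices (incident and sidestream dark field microscopes) image the
hemoglobin of flowing red blood cells: vessels appear as dark curvilinear
structures on bright tissue, and clinicians quantify microcirculatory
function from short video sequences. Manual analysis is slow and
operator-dependent. `hvmkit` implements the complete automated pipeline:

1. **Stabilization** — camera shake is estimated by sparse pyramidal
   Lucas–Kanade tracking of static-tissue corners, robust-fit as a
   per-frame similarity transform, smoothed so that intentional panning is
   preserved, and corrected; frames are cropped to the common valid region.
2. **Vessel recognition** — the temporal mean image (which fills plasma
   gaps between cells) is contrast-enhanced with contrast-limited adaptive
   histogram equalization (CLAHE) and vessels are extracted with Steger's
   principal-curvature line detector in two passes: a capillary pass at
   full resolution and a venule pass on a decimated image, superimposed
   with overlap elimination. Each vessel carries a subpixel centerline,
   per-point diameters, and a type: capillary (mean diameter ≤ 20 µm) or
   venule.
3. **Space–time velocimetry** — for every capillary, gray values along the
   straightened centerline are read out from each (histogram-equalized)
   frame and appended as columns: a kymograph in which a moving cell is a
   sloped dark streak. The same line detector traces individual
   red-blood-cell paths; each path's velocity is the magnitude of its mean
   space derivative by time. Paths are discarded as artifacts if too
   short, too curved (low curvature index), or faster than the per-vessel
   ceiling v_max = l·f/3 (vessel length l in µm, frame rate f in s⁻¹). A
   vessel is perfused when more than 95% of its paths show normal flow; if
   more than 95% are below the low-flow cutoff the vessel is non-perfused
   regardless of a fast minority (the "barcode" rule).
4. **Field metrics** — total vessel density
   TVD = Σ capillary length / field area (mm mm⁻²), functional capillary
   density FCD (perfused capillaries only), proportion of perfused vessels
   PPV = FCD/TVD, and the length-weighted field RBC velocity (µm s⁻¹).

A synthetic scene generator (`hvmkit.synthetic`) renders HVM-like
sequences — motion-blurred cells advected along spline tubes with plasma
gaps, tissue texture, flicker, jitter and sensor noise — with exact ground
truth, so every stage is testable without clinical recordings.

## Worked example

Render a synthetic scene and analyze it from the shell:

```
$ hvmkit synth --spec scene.yaml --seed 7 --out sceneout
rendered 40 frames to sceneout

$ hvmkit analyze sceneout/scene.tif --profile generic_sdf --out results --massey 5
TVD 3.29 mm/mm^2  FCD 3.29 mm/mm^2  PPV 1.000  RBCv 303 um/s  (1 capillaries, 0 venules, 10 paths)
  field: results/field.csv
  vessels: results/vessels.csv
  paths: results/paths.csv
```

where `scene.yaml` described one 10 µm capillary flowing at 300 µm/s: the
single detected capillary contributes 3.29 mm of centerline per mm² of
field, all of it perfused (PPV 1.0), and the ten tracked cell paths
average 303 µm/s — within 1% of the injected velocity. The same analysis
is available from Python:

```python
from hvmkit import AnalysisConfig, analyze, load_sequence, BUILTIN_PROFILES

seq = load_sequence("sceneout/scene.tif", BUILTIN_PROFILES["generic_sdf"])
result = analyze(seq, AnalysisConfig())
print(result.metrics.tvd, result.metrics.ppv, result.metrics.rbcv)
```

Input containers are multi-page TIFF stacks or directories of numbered
PNG/TIFF frames; device profiles supply the pixel pitch (µm/px) and frame
rate. Results are three CSV tables (per-field, per-vessel, per-path) plus
an optional losslessly written stabilized sequence.

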