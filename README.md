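# anthrobench

Forensic identification often leans on basic physical attributes — how tall
and how heavy is the person in this photograph?  Modern computer-vision
systems answer by fitting a 3D body model to the image, but a single-view
fit has no reliable absolute scale, so the model must be converted to
metric units by some population ruler, and the resulting estimates must be
compared honestly against cheap alternatives: expert photogrammetrists,
crowds of untrained viewers, and the null strategy of always guessing the
population average.

`anthrobench` implements that comparison as a reusable, fully synthetic
benchmark for researchers in forensic anthropometry and perception studies.
It provides:

* **Mesh anthropometry** — measurement of a neutral-pose, watertight,
  landmark-annotated body mesh.  The mesh (in arbitrary units) is scaled to
  centimetres with a gender-specific average inter-pupillary distance
  (IPD: 6.17 cm for women, 6.40 cm for men; the pupil centre is the
  midpoint of the eye-corner landmarks):

  $$s = \frac{\overline{\mathrm{IPD}}_{\text{gender}}}{\mathrm{IPD}_{\text{mesh}}}$$

  Height is the perpendicular distance from the head-apex landmark to the
  plane through three foot-sole landmarks.  Weight is the enclosed volume
  — the divergence-theorem sum of signed tetrahedra,
  $V = \tfrac{1}{6}\sum_f \det[a_f, b_f, c_f]$ — times an average
  whole-body density of 1023 kg/m³.
* **Synthetic study generation** — seeded cohorts (default 33 women and 25
  men, heights ~ N(161.1, 5.3²)/N(176.1, 8.3²) cm, weights
  ~ N(60.9, 11.4²)/N(78.4, 12.9²) kg), a 20-image-per-participant capture
  design (14 no-reference studio + 1 reference + 5 in-the-wild), watertight
  parametric body meshes hitting height/volume/IPD targets exactly, and
  simulated rating sessions (58 images + 4 catch trials each) with
  configurable rater bias and noise.
* **Estimator channels and filtering** — the mesh ("AI") channel, simulated
  expert and non-expert raters, a gender-specific US-average baseline
  (161/175 cm, 78.7/90.8 kg), and the catch-trial rule that voids a
  rater's entire session on any failed catch trial.
* **Error statistics** — per-image *individual* accuracy
  median<sub>j</sub>|h̃<sub>i,j</sub> − h<sub>i</sub>| and *crowd* accuracy
  |median<sub>j</sub>(h̃<sub>i,j</sub>) − h<sub>i</sub>|, medians across
  images with 1000-iteration percentile-bootstrap 95% CIs, a k-way Friedman
  omnibus test, and all-pairs two-sided Wilcoxon signed-rank tests with a
  Bonferroni-corrected threshold (0.05/10 = 0.005 for five groups).

## Worked example

```python
from anthrobench import generate_body_mesh, measure

# a male participant of 176.1 cm / 78.4 kg whose true IPD deviates from
# the population mean (anatomical jitter ~ N(0, 0.34 cm))
mesh = generate_body_mesh(176.1, 78.4, "male", seed=4, ipd_jitter_sd=0.34)
bm = measure(mesh, "male")
print(f"height = {bm.height_cm:.1f} cm, weight = {bm.weight_kg:.1f} kg")
print(f"scale = {bm.scale_factor:.3f} cm/unit, volume = {bm.volume_m3:.4f} m^3")
```

prints

```
height = 182.4 cm, weight = 87.1 kg
scale = 103.587 cm/unit, volume = 0.0852 m^3
```

The chain assumed the population-mean IPD while this individual's true IPD
is smaller, so every length is overestimated by the ratio of the two
(176.1 → 182.4 cm, +3.6%) and the volume-derived weight by its cube
(78.4 → 87.1 kg): the IPD ruler is the dominant, explainable error source
of single-image mesh anthropometry.  With `ipd_jitter_sd=0` the chain
recovers the generator's targets to better than 0.5%.

The full study pipeline runs from the command line:

```bash
anthrobench run-all --seed 1 --out study_out
```

which writes `cohort.csv`, `design.csv` (812 no-reference studio, 58
reference, 290 in-the-wild images), `estimates.csv` for all channels
(325 simulated sessions; 65 catch-failed and 24 incomplete are excluded,
leaving 236 valid), `summaries.csv`, `friedman.csv`, `pairwise.csv`, a
Markdown `report.md` (median-error table plus significance-star matrices),
and a `manifest.json` with the config echo and SHA-256 of every output —
re-running the same config is byte-identical.

## Documentation

See `docs/methods.md` for the model and procedure, the synthetic
generator's assumptions and defaults, numerical choices, and known
limitations.
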