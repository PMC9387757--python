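# ielec — headless intracranial electrode localization

Intracranial electrophysiology (sEEG depth electrodes, ECoG grids) can only
be interpreted once each recording contact has a position in the patient's
anatomy. That takes four steps, each with its own pitfalls: the
post-operative CT (where metal contacts are bright) must be aligned to the
pre-operative MR (where anatomy lives); clicked contact positions must be
refined to the true center of each metal artifact; ECoG grids must be
corrected for *brain shift* (the brain sags during craniotomy, leaving
surface grids below the pre-operative pial surface); and for group analyses
the contact positions must be carried into a template brain. `ielec`
implements this pipeline as a plain Python library plus CLI — no GUI, no
external registration engine — and verifies every stage against synthetic
head phantoms with exact ground truth.

The core algorithms:

* **CT→MR alignment** maximizes the mutual information
  $MI = \sum_{ij} p(i,j)\,\log\frac{p(i,j)}{p(i)\,p(j)}$
  of the joint intensity histogram, optimized coarse-to-fine with Powell's
  method over translation / rigid / affine parameters; a manual
  pre-alignment can seed the search when the field of view barely overlaps.
* **Snap-to-center** finds the brightest CT voxel near a seed, grows the
  26-connected region over which intensity decreases monotonically from
  that peak, and returns the intensity-weighted centroid — accurate to a
  fraction of a voxel and independent of where exactly the user clicked.
* **Brain-shift correction** projects each grid contact to the exact
  nearest point of the leptomeningeal surface (the smoothed envelope of
  the pial surface), computed by exact point-to-triangle distance over the
  whole mesh.
* **Template warping** uses a symmetric demons registration producing
  mutually inverse dense displacement fields; contact positions ride the
  field into template space, which is substantially more accurate than a
  global affine (Talairach-style) transform.
* **Anatomical labeling** samples an integer segmentation volume in a
  small ball around each contact and reports label fractions; shaft
  sequences run deep → superficial (contact 1 = tip).

## Worked example

Generate a synthetic head and run the whole pipeline on it:

```bash
ielec phantom --seed 7 --out phantom/
cat > config.json <<'JSON'
{
  "paths": {
    "ct": "phantom/ct.nii.gz",
    "mr": "phantom/mr.nii.gz",
    "seeds": "phantom/electrodes_truth_ct.tsv",
    "seg": "phantom/seg.nii.gz",
    "lut": "phantom/lut.txt",
    "lepto": "phantom/lepto.off",
    "template": "phantom/template.nii.gz",
    "out_dir": "out"
  },
  "register": {"stages": ["translation", "rigid"]},
  "snap": {"radius": 2.5},
  "project": {"channels": ["G1","G2","G3","G4","G5","G6","G7","G8",
                            "G9","G10","G11","G12","G13","G14","G15","G16"]}
}
JSON
ielec pipeline --config config.json
```

which prints

```
ct_to_mr.json: out/ct_to_mr.json
snapped.tsv: out/snapped.tsv
projected.tsv: out/projected.tsv
labels.tsv: out/labels.tsv
template_space.tsv: out/template_space.tsv
```

`ct_to_mr.json` is the recovered rigid CT→MR transform (4×4 row-major
matrix); `snapped.tsv` holds the refined contact positions in the MR frame
(mm); `projected.tsv` the grid contacts after brain-shift correction;
`labels.tsv` one row per contact-label pair, e.g.

```
name	label	fraction
LPM1	Cerebral-Cortex	1.000000
...
G1	Cerebral-Cortex	0.861111
G1	Unknown	0.138889
```

(the fraction is the share of segmentation voxels of that label in a 2 mm
ball around the contact — surface contacts graze the edge of the
segmentation, hence the Unknown remainder); `template_space.tsv` the
contact positions warped into the template brain. The same stages are
available individually (`ielec register`, `snap`, `project`, `label`,
`sdr`, `warp`); `--help` documents every flag.

The equivalent library calls are `compute_affine_registration`,
`snap_to_center`, `project_sensors_onto_brain`, `labels_at_positions`,
`compute_sdr_registration` and `apply_point_registration` — see the module
docstrings and `docs/methods.md` for the model details and parameter
choices.

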