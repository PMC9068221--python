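# nasoplan

Exhaustive, discretized search for collision-free surgical corridors in
trans-nasal endoscopic surgery, computed on segmented cranial CT label
volumes. The package is aimed at preoperative planning for skull-base
approaches to the pre-chiasmatic optic nerve in large animals: given a CT
segmentation that marks *surgical space* (the nasal / sphenoidal corridor),
*non-surgical space* (bone and soft tissue that must not be touched), a
*target* (the anterior wall of the optic canal) and surrounding *air*, it
answers whether a microdrill of a given diameter can reach the target without
collision, along which poses, and — if not — how small the drill must be.

## The model

The microdrill sweeps a straight **capsule** (cylinder with hemispherical
caps) of radius `r = d/2` along its major axis. Anchored with its tip at the
target contact point, a corridor has **five degrees of freedom**:

* `rx, ry, rz` — extrinsic rotations about the world axes (composed as
  `Rz·Ry·Rx`),
* `spin` — rotation about the corridor's own axis,
* `depth` — withdrawal of the tip along the axis, in mm.

The search grid discretizes each: rotations over a centered 180° range at 5°,
spin over 360° at 5°, travel over 15 mm at 1 mm, giving

```
(180/5)³ · (360/5) · (15/1) = 50,388,480
```

candidate poses. A pose is **feasible** iff every voxel of its corridor lies
in surgical space or air — equivalently, no non-surgical voxel center is
within `r` of the axis segment (closed `≤` convention). If no pose is
feasible the drill diameter is reduced by 0.5 mm and the search repeats, down
to a configurable floor. Feasible poses are ranked by clearance (minimal
distance from the axis to forbidden tissue, minus `r`).

Two independent routes implement the feasibility rule: a brute-force
rasterizer (the reference oracle) and an exact KD-tree / distance-transform
check that the test suite holds to 100% agreement.

## Worked example

No CT data is required: the `phantom` module generates segmented-skull
phantoms with exact analytic geometry. The narrow-channel phantom emulates a
skull whose drillable corridor is only 2.5 mm wide — too narrow for a
conventional 2.9 mm microdrill:

```bash
nasoplan phantom scene.nii.gz --preset macaque_like
nasoplan plan scene.nii.gz --rot-step 30 --spin-step 30 --travel-step 5 \
    --output-dir out/
```

prints

```
360 / 7776 poses feasible at 2.40 mm (fraction 0.046296)
adaptation trace: 2.90 -> 2.40
```

meaning: at 2.9 mm **zero** of the 7,776 poses on this coarse grid were
collision-free, the planner stepped the drill down by 0.5 mm, and at 2.4 mm
360 poses thread the channel. The JSON report in `out/plan_report.json`
contains the counts, the adaptation trace and the clearance-ranked pose list;
`--export-overlay` additionally writes the union of feasible corridors as a
volume on the input grid. On the wide-channel (13 mm, goat-like) phantom the
same 2.9 mm drill is feasible immediately with exit code 0.

`nasoplan sweep scene.nii.gz sweep.csv --diameters 1.5,2.0,2.5,2.9` tabulates
the feasible fraction against drill diameter.

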