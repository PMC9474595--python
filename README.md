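# autoplan

Automated external-beam radiotherapy planning for cervical cancer at desk
scale: 4-field-box and 3D conformal (3D-CRT) plan generation from structure
masks, field-in-field (FIF) hot-spot reduction, coverage-based plan
normalization, and EMBRACE II-style constraint evaluation — exercised on a
built-in synthetic pelvic phantom.

It is written for medical-physics researchers and students who want a fully
inspectable, scriptable model of how rule-based pelvic auto-planning works:
every stage that a clinical implementation hides inside a treatment-planning
system (landmark detection, beam's-eye-view geometry, forward FIF
optimization, normalization bookkeeping) is an ordinary, tested Python
function here. It is **not** a clinical dose engine: dose comes from a
declared surrogate model (parallel beams, percent-depth-dose falloff,
Gaussian penumbra) that preserves the properties the planning logic needs —
MU linearity, additivity, depth falloff, penumbra — and nothing more.

## The planning model

**4-field box.** The pelvis, sacrum, femurs and L4/L5 vertebral bodies are
projected to the 0°/90°/180°/270° beam's-eye views. Rectangular apertures
are shaped on bony landmarks: superior border at the L4/L5 interspace,
inferior border 10 mm below the lowest obturator-foramen pixel, AP/PA
lateral borders at the widest projected pelvic brim + 18 mm, lateral-field
anterior border 10 mm beyond the pubis and posterior border covering the
projected sacrum. Because no contoured target exists, the plan is
normalized on a *synthetic PTV*: the intersection of all beam paths (the
region of hot-spot detection, RHD) shrunk uniformly by 7 mm. The default
normalization makes **100 % of the prescription cover 97 %** of the
synthetic PTV.

**3D-CRT.** The PTV is built from contours:
`ITV = CTV_primary ⊕ (10, 10, 10, 10, 5, 5) mm ∪ CTV_nodal`, then
`PTV = ITV ⊕ 5 mm`; each aperture is the projected PTV dilated by a uniform
7 mm in-plane margin. Default normalization: **100 % of the prescription
covers 95 %** of the PTV; an alternative preset (95 %/99 %) produces cooler
plans for reviewers who prefer them.

**Field-in-field.** A hot spot is any contiguous volume larger than 2 cc
receiving more than 107 % of the prescription (105 % selectable). Per
iteration the hottest region is projected to the beam contributing most at
its maximum voxel, a subfield blocks that projection (+3 mm), and the
closed-form MU shift that brings the hot voxel to threshold moves from
parent to subfield — never leaving any segment below the 7 MU floor. The
plan is renormalized back to its recorded coverage when clean.

**Evaluation.** Cumulative DVHs, VxGy/Dmax/Dcc metrics, and a 13-rule
constraint table (hard: organ Dmax < 105 % of rx; soft: bladder V40 < 75 %,
V30 < 85 %, V45 < 50 %; rectum V40 < 85 %, V30 < 95 %, V45 < 80 %;
bowel-space V40 < 30 %; femurs V40 < 15 %).

Prescriptions are accepted only in 43.2–50.4 Gy and PTV margins only in
0.3–1.0 cm; anything else is rejected with a unit-explicit message.

## Worked example

```python
from autoplan import (PhantomSpec, generate_phantom, assemble_fourfield,
                      fif_reduce, detect_hot_spots, embrace_report)
from autoplan.evaluation import report_to_table
from autoplan.plans import build_rhd, build_synthetic_ptv, coverage

phantom = generate_phantom(PhantomSpec(random_seed=1))
plan, dose = assemble_fourfield(phantom, rx=45.0)
sptv = build_synthetic_ptv(build_rhd(plan.beams, phantom.geometry), 7.0,
                           phantom.geometry)
print(f"synthetic-PTV coverage at 45 Gy: "
      f"{100 * coverage(dose.values, sptv, 45.0):.2f} %")
print(f"hottest voxel before FIF: {dose.max_gy / 45.0:.1%} of rx")

result = fif_reduce(plan, phantom)
print(f"FIF: {result.n_subfields_added} subfields added, status {result.status}")
print(f"hottest voxel after FIF:  {result.dose.max_gy / 45.0:.1%} of rx")
print(f"remaining hot spots (>2 cc above 107 %): "
      f"{len(detect_hot_spots(result.dose, 45.0))}")
```

prints

```
synthetic-PTV coverage at 45 Gy: 97.01 %
hottest voxel before FIF: 116.4% of rx
FIF: 8 subfields added, status ok
hottest voxel after FIF:  108.2% of rx
remaining hot spots (>2 cc above 107 %): 0
```

The plan is normalized exactly to the 100 %/97 % recipe; the raw
equal-weight box plan is 16 % hot at the anterolateral entrance corners
(the classic 4-field hot spot), and eight automatic subfields bring every
region larger than 2 cc under the 107 % threshold while coverage is
restored. `report_to_table(embrace_report(result.dose, phantom, rx=45.0))`
then shows what any box technique shows: hard Dmax limits near the 105 %
line (the reason one reviewer in practice asks for a 105 % FIF threshold)
and soft bladder/rectum limits failed outright, because box fields treat the
whole central pelvis — the motivation for conformal and modulated
techniques.

The same flow is available from the shell:

```bash
autoplan phantom --out ph/ --seed 1
autoplan plan-4fbox --structures ph/ --rx 45 --out plan.json --dose dose.nii.gz
autoplan fif --plan plan.json --structures ph/ --out plan_fif.json --trace fif.csv
autoplan evaluate --dose dose.nii.gz --structures ph/ --rx 45
autoplan run --config run.yaml          # full pipeline bundle
```

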