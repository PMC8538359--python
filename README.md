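# kneeplan

Virtual 3-D planning for **customized antibiotic-loaded PMMA (ALPMMA)
femoral knee spacers** in two-stage revision of peri-prosthetic joint
infection (PJI).

Off-the-shelf articulating spacers come in a handful of sizes and cannot
adapt to the segmental femoral bone loss that revision knees typically
present. Planning a *customized* spacer requires answering, on the
patient's 3-D bone model, three questions:

1. **Joint line** — is the distal femur symmetrically short, so that the
   joint line (which should sit 40–45 mm distal to the adductor tubercle)
   has migrated proximally? → symmetric distal augmentation.
2. **Coronal alignment** — is one distal condyle deficient, tilting the
   limb into varus/valgus? → asymmetric distal augmentation on the
   deficient side.
3. **Rotational alignment** — is a posterior condyle deficient, rotating
   the component away from the surgical trans-epicondylar axis (TEA)?
   → asymmetric posterior augmentation.

`kneeplan` implements the full desk-side chain for these decisions:

- **`kneeplan.femur`** — a synthetic femur generator (sphere head, tilted
  shaft, bicondylar distal block) with named anatomical landmarks and
  injectable condylar defects, so the whole pipeline is testable without
  patient CT data.
- **`kneeplan.spacer`** — a parametric CAD kernel for the femoral
  component: five-facet bone-facing profile (amplitudes `A_AS … A_PS`,
  turning angles `ϑ_AC … ϑ_P`), facet thicknesses `D1, D2, D3`, cam-post
  profile (`HP`, `WP`), independent A–P / M–L sizing, and augment pads.
- **`kneeplan.axes`** — femoral head centre by least-squares sphere fit,
  Moreland's two-point anatomical axis, mechanical axis (head centre →
  knee centre), surgical TEA, posterior condylar angle (PCA), signed
  varus/valgus deviation.
- **`kneeplan.planning`** — component placement (perpendicular to the
  mechanical axis, rotated to the TEA, joint line at the 40–45 mm
  window), per-condyle bone-gap measurement by ray casting, the augment
  solver, restoration verification and scenario classification.
- **`kneeplan.io` / `kneeplan.cli`** — STL (binary + ASCII) and JSON
  readers/writers and the `kneeplan` command-line tool.

## The planning model in brief

With gaps `g_dist_med, g_dist_lat, g_post_med, g_post_lat` (positive =
bone deficit relative to the native condylar surface, measured along the
planned cut normals):

```
symmetric_distal     = round( max(0, min(g_dist_med, g_dist_lat)) )
asymmetric_distal    = round( |g_dist_med − g_dist_lat| )   on the deficient side
asymmetric_posterior = round( |g_post_med − g_post_lat| )   on the deficient side
```

rounded half-up to 1 mm. A residual distal imbalance of Δ over an
intercondylar span *s* tilts the joint line by `atan(Δ/s)` (varus
positive); a posterior imbalance rotates the effective condylar line by
the same trigonometry against the TEA (PCA shift). The solver drives both
below 1° and returns the joint line to the 40–45 mm window.

## Worked example

The canonical "alignment defect" scenario: a 7 mm segmental defect of the
medial femoral condyle.

```python
from kneeplan import (SpacerParams, apply_defect, generate_femur,
                      plan_spacer, preset_case)

spec, defect = preset_case("case2")          # medial distal defect, 7 mm
mesh, landmarks = generate_femur(spec)
mesh = apply_defect(mesh, landmarks, defect)
report = plan_spacer(mesh, landmarks, SpacerParams())
```

prints (via `report.gaps`, `report.plan`, `report.restoration`):

```
gaps (mm): distal med 7.00 / lat 0.00, posterior med 0.00 / lat 0.00
plan: {'symmetric_distal_mm': 0.0,
       'asymmetric_distal': {'side': 'medial', 'mm': 7.0},
       'asymmetric_posterior': {'side': None, 'mm': 0.0},
       'rounding_step_mm': 1.0}
scenario: CORONAL
post-plan coronal deviation: 0.000 deg, PCA deviation: 0.000 deg, joint line: 42.5 mm
```

Reading: the medial condyle is 7 mm short, which before augmentation
tilts the implant joint line by `atan(7/45) ≈ 8.8°` of varus; a 7 mm
medial distal augment restores perpendicularity to the mechanical axis
(coronal deviation 0°) with the joint line at 42.5 mm below the adductor
tubercle.

The same pipeline from the shell:

```bash
kneeplan --seed 0 generate-femur --preset case2 \
         --out-mesh femur.stl --out-landmarks lm.json
kneeplan plan --mesh femur.stl --landmarks lm.json --out plan.json
```

## Limitations

The synthetic femur is stylised: it reproduces correct landmark
relations, axis angles and locally flat condylar cut surfaces, not
statistical femoral shape. CT import, segmentation, tibial components,
soft-tissue balancing and 3-D printing are out of scope. See
`docs/methods.md` for the full model description and design choices.
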