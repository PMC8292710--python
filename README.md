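# ventavoid

Functional-avoidance scanned-proton treatment planning with 4DCT-derived
ventilation imaging, exercised end-to-end on a synthetic deformable lung
phantom with analytically known ground truth.

The package implements the full study chain:

1. **`phantom4d`** — synthetic 4DCT: a deformable lung phantom whose
   displacement fields have closed-form Jacobians and whose HU model
   conserves tissue exactly, so fractional ventilation has the analytic form
   `(J - 1) / f_air` on the exhale grid. Includes a heterogeneous air-fraction
   texture, vessel-like intensity-preserved strands, a regional ventilation
   defect, and a rigidly translating tumor.
2. **`registration`** — multiresolution deformable registration (SSD +
   diffusion penalty, monotone line-searched descent) estimating the
   exhale-to-inhale correspondence.
3. **`ventilation`** — per-voxel fractional ventilation
   `1000 (HU_in - HU_ex) / (HU_ex (1000 + HU_in))`, percent-of-max
   normalization, lung segmentation, regional (L/R × superior/middle/inferior)
   ventilation shares, and the ≥15-percentage-point defect eligibility screen.
4. **`structures`** — functional-lung mask (≥15% of global max), iGTV (union
   over phases) → CTV (+8 mm) → PTV (+5 mm) margin chain, optimization
   substructures.
5. **`dose_engine`** — analytic proton pencil-beam model: 97-energy machine
   (71.3–228.8 MeV, in-air sigma 5.7→2.5 mm), power-law Bragg curves with
   range straggling, depth-widening lateral Gaussians, water-equivalent depth
   accumulation, sparse influence matrices, setup-shift / range-scale
   scenarios.
6. **`planner`** — hexagonal spot placement, robust spot-weight optimization
   (expectation over the 21-scenario grid: nominal + 6 × 5 mm shifts ×
   0.95/1.00/1.05 range), worst-case V95 ≥ 95% gate with target-weight
   escalation, D99-based plan normalization, standard vs functional objective
   sets.
7. **`interplay`** — max-MU iso-layer repainting, delivery timeline,
   6 breathing scenarios (2 start phases × 3 periods), 4D dynamic dose
   accumulation on the reference anatomy, nominal-vs-dynamic metric report.
8. **`metrics_stats`** — DVH / functional-DVH metrics (Dx by the sorted-voxel
   rule, Vx by exact counting), conformity and homogeneity indices, logistic
   NTCP models on fV20/fV30/fMLD (shipped coefficients are placeholders and
   tagged as such), ANOVA + Bonferroni-corrected paired t-tests.

`pipeline.run_study` chains all stages and backs both the CLI and the
acceptance script.

## CLI

```bash
# generate a 4DCT phantom (phases, DVFs, masks, ventilation truth) as NIfTI
ventavoid generate --out phantom/ --seed 1 --size 96 --spacing 2.5

# deformable registration and ventilation on the generated files
ventavoid register --fixed phantom/phase_00.nii.gz \
    --moving phantom/phase_05.nii.gz --out dvf.nii.gz
ventavoid ventilate --exhale phantom/phase_00.nii.gz \
    --inhale phantom/phase_05.nii.gz --dvf dvf.nii.gz \
    --lung-left phantom/mask_lung_left.nii.gz \
    --lung-right phantom/mask_lung_right.nii.gz \
    --out vent.nii.gz --report eligibility.json

# full study: phantom -> ventilation -> structures -> standard + functional
# robust plans -> interplay -> metric/NTCP tables
ventavoid run --out results/ --seed 1
```

`ventavoid run` at the default 96³ / 2.5 mm grid takes roughly 8 minutes on a
single CPU; pass `--size 48 --spacing 5.0` for a quick desk-scale run.

## Conventions

- Arrays are `(z, y, x)` with index 0 at the superior end; spacing and
  displacements are in millimetres; displacement fields live on the exhale
  grid and map exhale → inhale physical coordinates.
- Doses are Gy[RBE] (RBE folded into the engine calibration); the machine
  calibration delivers 1 Gy[RBE] per 100 MU at the reference spot peak.
- Beams are axis-aligned in the axial plane (gantry multiples of 90°).
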