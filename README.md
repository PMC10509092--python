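# lgequant

Quantitative comparison of isotropic 3D late gadolinium enhancement (LGE)
cardiac MR with the standard 2D short-axis acquisition, as a tested,
reusable pipeline:

1. **Geometric reslicing** — extract 2D images from an isotropic 3D volume
   at arbitrary slice geometries, degrading resolution by symmetric
   normal-shifted plane averaging so the resliced stack matches the 2D
   reference's pixel grid and effective slice thickness (7 trilinear
   planes at 1.25 mm steps spanning 7.5 mm per 7 mm slice).
2. **Semi-automatic scar quantification** — FWHM thresholding
   (threshold = max(scar ROI) / 2) for ischemic scar and mean + 3 SD
   thresholding for inflammatory enhancement, with the nearest-slice
   fallback for slices lacking a reference ROI; myocardial mass, scar
   mass (1.05 g/ml) and LGE extent (%), plus the blood/myocardium
   contrast ratio CR = |mean(R_blood) − mean(R_myo)| / mean(R_blood).
3. **AHA 16-segment mapping** — per-segment extent and ordinal categories
   (0; 1–25; 26–50; 51–75; 76–100 %).
4. **Agreement statistics** — paired t-test, Pearson r, Bland–Altman bias
   with 95 % limits of agreement (bias ± 1.96 SD), Wilcoxon signed-rank,
   exact McNemar.
5. **Synthetic LV phantom** — a seeded truncated half-ellipsoid shell with
   subendocardial-infarct or outer-wall-myocarditis enhancement, papillary
   lesions, partial-volume acquisition at both study geometries and Rician
   noise, with fine-lattice ground truth — so the whole chain is testable
   without patient data.

Who it is for: image-analysis researchers who need a transparent,
scriptable reference implementation of LGE reslicing + quantification, and
anyone validating scar-quantification software against known ground truth.

## Worked example

```python
from lgequant.phantom import PhantomSpec
from lgequant.study import (
    simulate_patient, reslice_stack, quantify_patient,
)

patient = simulate_patient(PhantomSpec.ischemic(seed=7))   # ~30 s
resliced = reslice_stack(patient.volume3d, patient.geometries)
q2d = quantify_patient(patient, patient.sax_native)        # native 2D
q3d = quantify_patient(patient, resliced)                  # resliced 3D
truth = patient.truth_in_covered_slab()
print(f"2D: {q2d.myocardial_mass:.1f} g myocardium, "
      f"{q2d.scar_mass:.1f} g scar, extent {q2d.lge_extent:.1f}%")
print(f"3D: {q3d.myocardial_mass:.1f} g myocardium, "
      f"{q3d.scar_mass:.1f} g scar, extent {q3d.lge_extent:.1f}%")
print(f"truth: extent {truth['extent_pct']:.1f}%")
```

prints

```
2D: 95.9 g myocardium, 11.8 g scar, extent 12.3%
3D: 95.9 g myocardium, 11.9 g scar, extent 12.4%
truth: extent 10.6%
```

i.e. the two sequences agree with each other to 0.1 percentage points of
extent and sit within 2 points of the fine-lattice truth; the myocardial
mass (same contours on both stacks) recovers the covered-slab truth
(95.4 g) to within 0.5 %.

The numbered scripts under `analysis/` run the full study chain and write
their tables to `results/`:

```bash
python analysis/01_simulate_phantoms.py     # phantoms + ground truth
python analysis/02_reslice_3d_to_sax.py     # multiplanar reslicing report
python analysis/03_quantify_scar.py         # FWHM / 3-SD quantification
python analysis/04_aha_segments.py          # 16-segment extents/categories
python analysis/05_agreement_2d_vs_3d.py    # cohort Bland–Altman battery
```

A `lgequant` console command exposes the same stages
(`phantom`, `reslice`, `quantify`, `segments`, `agree`, `run`) for
file-based use; `lgequant run --pattern ischemic --seed 7 --out out/`
executes the whole chain on one synthetic patient and writes per-stage
outputs with provenance.

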