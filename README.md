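# atriflow

Semi-automated left-atrium (LA) segmentation transfer for 4D-flow MRI.

4D-flow MRI measures time-resolved, three-directional blood velocity, but
its ~3 mm resolution and washed-out contrast make chamber segmentation the
bottleneck of every atrial-flow study. A contrast-enhanced MR angiogram
(CE-MRA) of the same patient shows the atrium and its appendage at ~1.2 mm
with excellent contrast — in a different patient pose. `atriflow`
transfers a CE-MRA segmentation into 4D-flow coordinates:

1. **PC-MRA derivation** — an angiogram-like volume computed from the
   4D-flow series itself,
   `PCMRA(r) = (1/N) Σᵢ Iᵢᴹᵃᵍ(r) · √(v²ₓ,ᵢ + v²ᵧ,ᵢ + v²_z,ᵢ)`.
2. **Segmentation** — seeded region growing on the CE-MRA with median +
   closing refinement (3 mm kernel) and an orifice-plane cut to separate
   the appendage; homomorphic bias correction for the PC-MRA.
3. **Rigid registration** — the CE-MRA (moving) is aligned onto the PC-MRA
   (fixed) by maximising joint-histogram mutual information over the six
   rigid parameters (Powell's method, 20% voxel sampling, 32 bins, 1500
   iteration cap). If the global round locks onto the aortic arch — whose
   position relative to the chambers differs between a time-averaged
   PC-MRA and a single-phase CE-MRA — a second round re-runs with full
   sampling inside a cuboid ROI around the upper chambers.
4. **Resampling** — nearest-neighbour transfer of the binary masks into
   the 4D-flow grid.
5. **Quantification** — Dice similarity coefficient (DSC), average
   symmetric surface distance (ASSD, mm), volumes (ml), and hemodynamics:
   pooled mean velocity (cm/s) and stasis (% of the cycle below 0.1 m/s),
   plus Bland–Altman / Pearson agreement statistics.

Because no patient data ship with the package, a first-class synthetic
phantom (`atriflow.phantom`) generates paired CE-MRA / 4D-flow datasets of
an ellipsoidal atrium with appendage, four irregular pulmonary veins, an
aortic arch (optionally displaced, to reproduce the registration failure
mode) and a ventricle — with a known posing transform and closed-form
hemodynamics, so every pipeline stage can be validated against ground
truth.

## Worked example

```python
import atriflow as af

# a synthetic patient: 1.2 mm CE-MRA + 3 mm, 25-phase 4D-flow,
# posed 6/-4/8 mm and 5/-3/2 degrees apart
ce, flow, truth = af.generate_phantom(af.PhantomSpec(seed=1))

fixed = af.bias_correct(af.compute_pcmra(flow))
result = af.two_round_register(
    fixed, ce, [truth.la_mask_ce, truth.pv_mask_ce],
    af.RegistrationConfig(sample_fraction=0.2, seed=11),
)
la = af.resample_mask(truth.la_mask_ce, result.transform, flow.grid)

print(f"dice      {af.dice(truth.la_mask_flow, la):.3f}")
print(f"assd_mm   {af.assd(truth.la_mask_flow, la):.3f}")
print(f"volume_ml {af.volume_ml(la):.1f}")
print(f"mean_vel  {af.mean_velocity(flow, la):.2f} cm/s")
print(f"stasis    {af.stasis(flow, la):.1f} %")
```

Output:

```
dice      0.997
assd_mm   0.063
volume_ml 82.7
mean_vel  9.91 cm/s
stasis    53.4 %
```

A Dice of 0.997 against the generator truth means the recovered transform
is within a small fraction of a 3 mm flow voxel; volume, mean velocity and
stasis land at clinically typical atrial values (the phantom's swirl field
is calibrated to produce them).

The same workflow runs from the shell on NIfTI/DICOM data:

```bash
atriflow phantom --seed 1 --out-dir demo/
atriflow pcmra --in demo/flow --out demo/pcmra.nii.gz
atriflow pipeline --config my_case.yaml --out-dir results/
```

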