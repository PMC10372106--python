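# lvpet

Left-ventricular volumes and ejection fraction from first-pass gated
blood-pool ¹⁵O-water PET.

¹⁵O-water is the reference tracer for quantitative myocardial blood flow,
but because it diffuses freely there is no late-uptake contrast between
myocardium and blood pool — the gated-uptake segmentation used for ⁸²Rb or
¹³N-ammonia cannot be applied. `lvpet` instead analyses the **first pass**
of the bolus: the 10–50 s post-injection window, reconstructed as 8
ECG-gated blood-pool bins, in which activity is confined to the cardiac
blood pools. The analysis chain is:

1. **Steepest-path seeding** — every foreground voxel follows its steepest
   spacing-normalised ascent to a local maximum; voxels reaching the same
   maximum form a *seed*. The sub-resolution valves depress local activity,
   so chambers separate into different seeds.
2. **Chamber assignment** — each seed is labelled LEFT or RIGHT from the
   arterial (V_A) and venous (V_V) spill-over fractions of the
   single-tissue-compartment kinetic analysis, sampled at the seed maximum
   (`V_A > V_V` and above threshold ⇒ LEFT).
3. **Mitral valve plane** — activity indentations (width minima of the
   blood pool) are found at many rotations about the LV long axis and a
   robust 3D plane is fitted through them; the user may fine-tune it
   (offset/tilt).
4. **Count-based volumetrics** — per gate bin, the LV is the union of LEFT
   seeds apical of the plane, and its volume is
   `V = v_vox · Σ C_i / C_ref` over voxels above a low threshold, with
   C_ref a pure-blood reference concentration: partial-volume counts are
   recovered rather than thresholded away. Then
   `EDV = max_b V_b`, `ESV = min_b V_b`, `SV = EDV − ESV`,
   `EF = 100 · SV / EDV`.

The package also contains the supporting pieces: a basis-function
single-tissue-compartment fitter producing the MBF/V_T/V_A/V_V parametric
maps from the 22-frame dynamic series, input-function extraction by TAC
clustering, Bland–Altman / RPC / ICC(2,1) / Pearson / Wilcoxon agreement
statistics for validation studies, and a synthetic gated cardiac phantom
with analytic ground truth so the whole chain is testable without patient
data.

## Worked example

```python
from lvpet import phantom, pipeline

cfg = phantom.PhantomConfig(edv_ml=150, ef=0.60, seed=1)   # default phantom
gated, truth = phantom.make_gated_phantom(cfg)
result = pipeline.analyze(gated, maps=truth.maps)
print(result.function.to_dict())
```

prints

```
{'edv_ml': 156.5217232670743, 'esv_ml': 68.28134332376075, 'sv_ml': 88.24037994331354, 'ef_percent': 56.37580401076231, 'ed_bin': 0, 'es_bin': 4}
```

i.e. the pipeline recovers EDV within ~4% and EF within ~4 absolute points
of the generating truth (EDV 150 mL, EF 60%) on a noisy 8-bin phantom; the
residual EF deficit is dominated by the gating attenuation — each gate
averages its phase window, washing the volume extremes toward the mean —
which is the same reason few-gate protocols overestimate ESV clinically.

The same analysis is available from the shell:

```bash
lvpet phantom --edv 150 --ef 0.6 --seed 1 --out ph/
lvpet analyze --gated ph/gated.nii.gz --gated-sidecar ph/gated.json \
      --va-map ph/va_map.nii.gz --vv-map ph/vv_map.nii.gz --out out/
lvpet agree a.csv b.csv     # paired agreement report (bias, RPC, ICC, r, p)
```

`analyze` accepts either precomputed V_A/V_V maps or the non-gated dynamic
series (`--dynamic`/`--dynamic-sidecar`), from which it fits the maps
itself.

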