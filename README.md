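# tractrr

Test–retest reliability of corticospinal-tract (CST) diffusion-tensor metrics,
rebuilt as a fully synthetic, end-to-end testable pipeline.

## The problem

Diffusion tensor imaging (DTI) indexes white-matter integrity of the CST after
stroke through fractional anisotropy (FA) and the mean/axial/radial
diffusivities (MD, AD, RD). Before such measures can track recovery or serve
as biomarkers, two psychometric questions must be answered per extraction
approach:

* **test–retest reliability** — how well do measurements agree across two
  scan sessions on unchanged subjects? Quantified by the intraclass
  correlation for absolute agreement, single measurement:

  $$\mathrm{ICC}(A,1) = \frac{MS_R - MS_E}{MS_R + (k-1)MS_E + \frac{k}{n}(MS_C - MS_E)}$$

  from the two-way ANOVA mean squares of the $n \times k$ subject-by-session
  matrix (rated poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.9 < excellent);

* **minimal detectable change** — the smallest change exceeding measurement
  noise at 95% confidence:

  $$\mathrm{SEM} = \mathrm{SD}_{day1}\sqrt{1-\mathrm{ICC}}, \qquad
    \mathrm{MDC}_{95} = 1.959964 \cdot \mathrm{SEM} \cdot \sqrt{2}.$$

Because the answers depend on *how* the tract is extracted, the pipeline
implements three standard approaches: a **cerebral-peduncle slice ROI** (the
three contiguous inferior axial slices of largest cross-section), a
**probabilistic tract** (streamlines seeded in six cortical patches, kept only
if they traverse waypoint masks in the internal capsule and peduncle and avoid
exclusion masks, normalised by the *waytotal* and thresholded at 1%), and a
**tract template** (a canonical mask resampled into subject space). All masks
are restricted to FA > 0.2 and lesion voxels are removed.

Real subject data for such studies are typically not shareable, so the package
generates its own: a synthetic two-session cohort (default 18 subjects, b =
1000 s/mm², 56 directions, 1.8 mm isotropic) with bilateral tracts, a lesion
on the ipsilesional side, and a controlled variance structure whose true ICC
is known — every stage can therefore be validated by parameter recovery.

## Worked example

```python
from tractrr import sem_mdc
for sd, icc in [(0.052, 0.844), (0.033, 0.973), (0.025, 0.984)]:
    sem, mdc = sem_mdc(sd, icc)
    print(f"SD={sd:.3f} ICC={icc:.3f} -> MDC95={mdc:.3f}")
```

prints

```
SD=0.052 ICC=0.844 -> MDC95=0.057
SD=0.033 ICC=0.973 -> MDC95=0.015
SD=0.025 ICC=0.984 -> MDC95=0.009
```

i.e. with those day-1 SDs and ICCs, ipsilesional CST FA must change by 0.057
(peduncle), 0.015 (probabilistic) or 0.009 (template) before the change
exceeds measurement noise — the more automated the approach, the smaller the
detectable change.

A full synthetic study (`tractrr run-all --seed 1 --out out/`, ~6 min) prints
a reliability table; the FA block for the probabilistic approach at seed 1:

```
metric        hemisphere          mean_d1 (sd)    mean_d4 (sd)    ICC          95% CI     rating   MDC95
[probabilistic]
FA            ipsilesional        0.543 (0.032)    0.547 (0.029)  0.972   0.914-0.990  excellent   0.015
FA            contralesional      0.577 (0.028)    0.576 (0.029)  0.924   0.809-0.971  excellent   0.021
```

The generator's true ICC is 0.970 (σ_between = 0.04, σ_session = 0.007 FA
units); the pipeline recovers 0.972 for ipsilesional FA — the whole chain
(simulation → tensor fit → tracking → ICC) preserves the reliability
structure. Ipsilesional FA is lower than contralesional (paired t, p < 0.01),
and the across-subject FA range is widest for the peduncle ROI and narrowest
for the template mask.

The CLI exposes each stage separately (`simulate`, `fit`, `extract`,
`reliability`, `report`, `verify-reference`, `run-all`) with NIfTI/bval/bvec
and CSV interfaces; `tractrr verify-reference` recomputes MDC95 from the SD
and ICC of every row of a published reference table shipped with the package
and reports the closure error.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package's SEM/MDC machinery on the reference
table's printed day-1 SD and ICC inputs, the minimal detectable change of
ipsilesional CST FA for each of the three extraction approaches, and writes
them as JSON.
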