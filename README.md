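# rtctqa — automated QA for radiotherapy planning CT

Planning CTs anchor the whole radiotherapy chain: they define target and
organ-at-risk geometry and the electron densities used for dose
calculation. Errors at this stage — wrong scan range, a metal prosthesis
reconstructed without artifact reduction, a full bladder on a protocol
that requires an empty one — propagate silently into treatment planning.
`rtctqa` is a retrospective quality-assurance toolkit for medical
physicists and RTT teams that audits large planning-CT cohorts for:

* **imaging dose**: CTDIvol (mGy), scan length, DLP (mGy·cm) and the
  effective-dose estimate *E = DLP · k*, with body-region-specific
  conversion coefficients *k* (mSv per mGy·cm);
* **anatomical scan range**: per body-region SOP, the signed deviations
  Δtop (cranial) and Δbot (caudal) of the actual scan boundaries from
  the SOP-required anatomical field of view, measured from organ
  segmentations (TotalSegmentator-style label maps). Positive Δ means
  over-coverage, negative means under-coverage; |Δ| > 50 mm raises a
  guideline flag. When a landmark is cut off by a truncated scan, the
  boundary is estimated by bridging the missing vertebral levels with a
  vertebral-body lookup table (VB-LUT: skull 210 mm, C1–C2 25 mm,
  C3–C7 20 mm, T1–T12 25 mm, L1–L5 30 mm per segment);
* **protocol adherence**: metal (HU > 4000) without iMAR reconstruction,
  topograms shorter than the volumetric scan, the 399-slice limit,
  breathing-phase plausibility via lung volumes, bladder filling classes
  (empty < 200 mL / partially filled 200–400 mL / full > 400 mL) against
  protocol expectations, thorax-protocol misapplication (cranial end
  > 10 cm too low **and** caudal end > 10 cm too long), and
  field-of-view truncation at the reconstruction-circle edge;
* **temporal trends**: per-protocol summaries (mean ± SD, quartiles)
  after a 25-case minimum-occurrence filter, and moving averages with
  running SD over centred date windows (e.g. 12 weeks → ±42 days).

Because clinical DICOM data cannot ship with the package, a synthetic
phantom generator produces stylized label maps, HU volumes, metadata and
dose reports with *exact* ground truth for every audited quantity, so
the entire pipeline is testable end to end.

## Worked example

```bash
rtctqa simulate --n 30 --seed 42 --out demo/cohort \
    --defect-rates '{"metal_no_imar": 0.1, "short_topogram": 0.1, "truncation": 0.1}'
rtctqa audit --cohort demo/cohort --out demo/audit
rtctqa report --audit-dir demo/audit
```

prints

```
audited 30 scans; 9 flagged findings
scans audited: 30
  contrast: 0 flagged
  metal_imar: 2 flagged
  topogram: 7 flagged
  slice_count: 0 flagged
  bladder_filling: 0 flagged
  misapplied_thorax: 0 flagged
  fov_truncation: 0 flagged
  delta_top_mm: mean +24.9 mm, sd 12.3 mm, n 30
  delta_bot_mm: mean +19.0 mm, sd 25.7 mm, n 30
```

Every flag is a planted defect recovered by the audit: the 7 topogram
flags are exactly the 7 scans generated with topograms shorter than the
volumetric scan (`demo/cohort/ground_truth.csv` holds the plants), and
the mean Δtop/Δbot reflect the generated over-coverage distribution.
The per-scan table (`demo/audit/per_scan.csv`) joins dose descriptors,
deltas with their estimation method (`direct` vs `lut-estimated`) and
all QA statuses; `rtctqa trends` aggregates it into group summaries and
moving-average CSVs.

The same machinery is available as a library:

```python
from rtctqa import default_registry, generate_phantom, PhantomSpec
from rtctqa import extract_extents, ScanExtent, compute_deltas

reg = default_registry()
data = generate_phantom(PhantomSpec(group="Brain", seed=1,
                                    intended_overcoverage=(15.0, -40.0)), reg)
landmarks = extract_extents(data.label_map, reg.aliases)
scan = ScanExtent.from_label_map(data.label_map)
res = compute_deltas(scan, reg.sop("Brain"), landmarks, reg.vblut)
# res.delta_bot == -40.0, res.bot_method == "lut-estimated"
```

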