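# Methods

## Scope and data model

`rtctqa` audits planning-CT acquisitions retrospectively. Its inputs
are (a) per-scan metadata records in a JSON dialect whose field names
mirror DICOM radiation-dose structured-report concepts (`CTDIvol`,
`DLP`, `ScanningLength`), (b) organ label maps in NIfTI with a
label-ID → structure-name mapping using the TotalSegmentator "total"
vocabulary, and (c) optionally the reconstructed HU volume. The package
does not run a segmentation network and does not parse binary DICOM; it
consumes segmentations and metadata as inputs.

## SOP registry

Each body-region group (Brain, H&N, Thorax, 4D, Upper abdomen, Abdomen,
Pelvis, Spine) carries a cranial and a caudal landmark: a structure
extent (cranial or caudal end), a signed offset in mm (positive =
cranial; e.g. Brain cranial boundary = cranial start of skull + 10 mm,
Pelvis caudal boundary = 100 mm caudal of the trochanter-minor level),
and, where the landmark itself is not segmentable (mastoid, diaphragm,
tracheal bifurcation, iliac crest, trochanter minor), an equivalent
height-level organ. The equivalent may use a different extent side than
the landmark (the iliac crest maps to the *cranial* end of the hip even
though it bounds the scan caudally), which is why landmark specs carry
an explicit `equivalent_side`.

Each boundary also has an ordered fallback chain of vertebral levels,
starting at the level equivalent to the landmark and proceeding toward
the scan interior. The VB-LUT assigns each skull/vertebral segment a
reference length: skull 210 mm, C1–C2 25 mm each, C3–C7 20 mm each,
T1–T12 25 mm each, L1–L5 30 mm each. The per-vertebra reading (rather
than per-block) is the only one consistent with a 12-segment thoracic
spine. The 4D cranial chain is encoded as C7, T1, T2, … — the cervical
column ends at C7, so the chain continues thoracically; every chain
element must have a VB-LUT entry, which is validated at load time.

Protocol names resolve to groups by case-insensitive substring rules,
first match wins. k-factors default to AAPM Report 96 adult body-region
values (Brain 0.0021, H&N 0.0059, chest 0.014, abdomen/pelvis 0.015
mSv per mGy·cm); they are institution-configurable, not ground truth.
Organ-characteristic (tube-current-modulation) settings, including the
2024 head→neck / head→abdomen switchovers for H&N and spine, are
carried as metadata only — no dose physics is modelled on them.

## Geometry conventions

All measurements are in patient-space mm from the NIfTI affine after
reorientation to a canonical RAS-like frame, so cranial is +z.
Structure extents and scan boundaries both use **outer slice faces**
(voxel centre ± half the slice thickness): an organ filling 11 slices
of 3 mm has a 33 mm extent. With a single convention on both sides,
boundary errors are pure sub-slice quantization — at most half a slice
per boundary — and vanish entirely when anatomy boundaries align with
slice faces. The scanned range is taken from image geometry; the
dose-report scan length is kept as an independent cross-check.

Δtop = scan_top − SOP_top and Δbot = SOP_bot − scan_bot, so
over-coverage is positive at both ends. A boundary that cannot be
located is reported as missing, never as 0. Guideline flags mark
|Δ| > 50 mm (configurable).

A structure whose relevant extent touches the scan border is treated as
truncated there and is not used as a landmark or chain anchor (its
extent on that side is unreliable). The "relevant side" is the side of
the extent actually used: a hip that runs off the caudal scan edge still
anchors the iliac-crest boundary through its cranial end. When the
landmark and its equivalent are unusable, the first usable chain element
anchors the estimate and the VB-LUT lengths of all skipped levels are
added (cranial end) or subtracted (caudal end); the SOP offset is
applied after the chain arithmetic. Partial truncation of the anchor
itself is not corrected — estimation accuracy degrades with truncation
depth, which is inherent to reference-length bridging.

## Dose descriptors

Effective dose is E = DLP × k(region). Per-report DLP sums volumetric
events only; topograms are carried but excluded from summaries. A
consistency rule cross-checks DLP against CTDIvol × length/10 with a
10% default relative tolerance — with tube-current modulation the
reported CTDIvol is a scan mean, so exact equality is not expected.
Phantom diameter (16/32 cm) is recorded but never used to rescale dose.

## QA rules

All checks are pure functions emitting pass / flag / not-applicable
findings with machine-readable details. Boundary conventions: metal is
strictly HU > 4000; slice count is compliant iff ≤ 399; bladder classes
are empty < 200 mL, partially filled 200–400 mL (closed interval), full
> 400 mL, with volumes from labelled voxel count × voxel volume; thorax
misapplication requires Δtop < −100 mm **and** Δbot > +100 mm, both
strict; breathing plausibility requires ≥ 2 scans in distinct modes and
expects inspiration/DIBH > free > expiration lung volumes with zero
default tolerance. iMAR use is detected by the case-insensitive token
"imar" in the reconstruction description. FOV truncation samples a ring
one voxel inside the reconstruction circle over the upper half of every
slice against a −500 HU air threshold; HDFoV reconstructions are
recognized by non-padding values (> −1024 HU sentinel) in the four
corner regions outside the standard circle. Pelvic protocols accept a
partially filled bladder as non-empty; expectation tables are
configurable.

## Trend statistics

Group summaries use the sample SD (n−1) and linearly interpolated
quartiles. Protocols with fewer than 25 scans are excluded before
aggregation. Moving statistics are evaluated on the observed scan dates
(no calendar grid, no interpolation): at each date, mean/SD/n over all
rows within window/2 days on either side, inclusive — a 12-week window
is ±42 days; edge dates use whatever falls inside the window. The
running SD is the sample SD of raw in-window values, not the SD of the
mean. Reference-level comparison reports whether each group median
exceeds configured proposed/achievable levels; no reference values are
shipped as authoritative.

## Synthetic phantoms

Phantoms are stylized: a circular soft-tissue body (radius 110 mm in a
64 × 64 × n grid at 4 mm in-plane, 3 mm slices by default), a central
bone column stacking skull and C1–L5 with per-segment lengths, and
simple solids for lungs (four lobes), liver, bladder (sphere of the
requested volume) and hips. Soft organs are anchored at the vertebral
levels their SOP chains assume (lung C7-cranial…T12-caudal, liver
T10-cranial…L2-caudal, hip cranial end at L3-caudal), so chain
estimates converge to direct measurements as truncation → 0. The hip
*caudal* chains (Abdomen/Pelvis) deliberately keep the crude
L5-anchored approximation — the phantom's trochanter level sits 120 mm
below L5 — reproducing the known bias of reference-length bridging for
fully missing hips.

Vertebral lengths default to the VB-LUT values; a ±10% uniform jitter
(the default in cohort generation) emulates anatomical variability and
exercises the estimation error the lookup table incurs on real
patients. The caudal scan face is placed exactly at the requested
boundary, so the planted Δbot is exact and Δtop absorbs the ≤ one-slice
grid quantization; ground truth records the achieved values. HU values
are piecewise constant (soft 40, lung −800, bone 700, air −1000, metal
8000, pad −1024); there is no noise, texture or tube-current-modulation
simulation. Consequently, passing tests demonstrate the correctness of
the audit logic and its quantization behaviour — not robustness to
segmentation errors, image noise, or anatomies far from the reference
proportions, all of which affect real cohorts.

Cohort generation plants defects independently per scan at configured
rates: caudal truncation, metal without iMAR, short topograms,
inverted breathing pairs (4D cases emit an inspiration/expiration pair
sharing a pseudo-id) and thorax misapplication (cranial end 11.5 cm too
low, caudal end 11–15 cm too long, placed so a chain anchor always
survives under jitter). All randomness derives from one seed;
regeneration is byte-identical (gzip timestamps pinned).

## Validation studies and problem sizes

The self-validation studies (also used by `scripts/acceptance.py`) use
100 phantoms at 3 mm slices for delta recovery — errors are bounded by
half a slice per boundary, observed max ≈ 1.5 mm — and 200 thorax scans
with a 10% misapplication rate for planted-defect recovery, where the
deterministic rule recovers every plant and the flagged count is checked
against the central 95% binomial interval. The truncation-exactness
check uses 5 mm slices because all VB-LUT lengths are multiples of
5 mm, making segment boundaries coincide with slice faces; under ±10%
jitter the estimation error is asserted within the summed
|true − reference| deviation of the bridged segments plus one slice.
These sizes keep the full suite and the acceptance script in the
seconds-to-minutes range on a single CPU.

## Known limitations

* No DICOM/RDSR binary parsing, PACS retrieval, or segmentation network
  — upstream systems must supply the JSON dialect and label maps.
* VB-LUT estimation assumes reference anatomy; tall/short patients bias
  truncation estimates, and the bias grows with truncation depth.
* Brachytherapy and axilla/extremity protocols are resolvable and
  dose-audited but their Δ evaluation is not claimed meaningful (ad hoc
  clinical FOV choices).
* The FOV edge check samples a discrete ring; pathologies thinner than
  the angular sampling (4°) could be missed.
* Size-specific dose estimates (SSDE) and tube-current-modulation
  physics are out of scope.
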