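# implantkinetics

Geometric analysis of temporary (pulsed-dose-rate) prostate brachytherapy
implants across serial CT timepoints — for medical physicists and
researchers who want to quantify oedema-driven volume change and implant
stability during a 48-hour treatment without relying on prostate contour
delineations.

During a PDR boost, 11–12 flexible catheters stay implanted for two days
while the source steps through dwell positions spaced 5 mm apart.  Because
the planning software defines the same dwell grid on every scan, the dwell
coordinates reconstructed on the planning CT (CT1) and on repeat CTs at 24
and 48 hours (CT2, CT3) form point clouds with guaranteed one-to-one
correspondence — a delineation-free probe of prostate geometry.

## Methods implemented

**Volume change from the dwell spread.**  For each scan the mean radial
distance of the n in-target dwells to their centre of mass, computed in the
transverse (L-R / D-V) plane only,

    MRD = (1/n) Σᵢ √((xᵢ − x_COM)² + (zᵢ − z_COM)²),

tracks the linear size of the implant; the caudo-cranial direction is
excluded because motion along a catheter reflects slippage, not volume
change.  The relative volume change between scans follows the cube law
ΔV(%) = 100·(MRD₂³ − MRD₁³)/MRD₁³, with σ_MRD = σ/√n for an assumed
per-dwell uncertainty σ (default 1 mm).

**Inter-marker distances.**  Three implanted fiducial markers (two base,
one apex) give three pairwise 3-D distances per scan; their changes are an
independent, catheter-free oedema indicator.

**Rigid registration, two ways.**  Catheter-based: iterative closest point
(ICP) on the full dwell clouds — whole-implant shifts are absorbed by the
fitted transform, so residuals measure implant *deformation*.
Marker-based: closed-form quaternion (Horn) least-squares fit on the three
markers applied to the dwells — whole-implant motion relative to the
markers stays visible.  A Monte-Carlo analysis perturbs the marker
coordinates (0.5 mm SD in L-R/D-V, 1 mm in C-C) to quantify how marker
uncertainty propagates into marker-based dwell displacements.

**Cohort statistics.**  Per-patient mean δ and SD σ_pat of each
displacement component; cohort Δ (mean of δ), Σ (SD of δ) and RMS of the
σ_pat; Wilcoxon signed-rank tests (exact null distribution up to 25
effective pairs, midrank ties handled); Tukey box summaries.

**Synthetic cohorts.**  A generator produces three-timepoint series with
known ground truth — ellipsoidal prostates of 21–56 cm³, 12 peripheral
gently-bowed catheters, ~80 in-target dwells, prescribed (an)isotropic
expansion, whole-implant rigid shifts, per-catheter craniocaudal slip and
reconstruction noise — so every estimator is testable end to end.

## Worked example

A patient's MRD grows from 15.0 mm to 15.7 mm between the planning CT and
a repeat CT, and the delineated planning volume was 42 cm³:

```python
>>> from implantkinetics import relative_volume_change, apply_relative_change
>>> r = relative_volume_change(15.0, 15.7, sigma_1=0.1118, sigma_2=0.1118)
>>> print(f"{r.dv_percent:.1f} +/- {r.sigma_dv_percent:.1f} %")
14.7 +/- 1.8 %
>>> print(f"{apply_relative_change(42.0, r.dv_percent):.1f} cm3")
48.2 cm3
```

The 0.7 mm MRD increase corresponds to a +14.7 % volume change, carrying
the 42 cm³ gland to 48.2 cm³; with σ = 1 mm per dwell and n = 80 dwells,
σ_MRD = 1/√80 ≈ 0.1 mm per scan.

A full cohort run over a simulated 23-patient study:

```sh
implantkinetics report --simulate-config cohort.json --seed 1 --out-dir run1
```

prints (excerpt):

```
Volume change from MRD (per interval):
  CT1-CT2: dV = +4.4% ± 1.2% (range +2.3% to +6.5%, n=23, Wilcoxon p=2.38e-07)
  CT1-CT3: dV = +4.8% ± 1.0% (range +2.6% to +6.9%, n=19, Wilcoxon p=3.81e-06)
  CT2-CT3: dV = +0.5% ± 1.7% (range -2.5% to +4.1%, n=19, Wilcoxon p=0.332)
...
Marker-noise uncertainty of marker-based dwell displacement (100 reps,
SDs [0.5, 1.0, 0.5] mm L-R/C-C/D-V):
  mean ± SD per axis: +0.02 ± 0.84 mm, -0.02 ± 0.93 mm, -0.01 ± 0.87 mm
```

The mean recovered ΔV matches the generator's prescribed +4.3 % / +4.4 %
oedema within the cohort's Monte-Carlo spread, and the marker-noise means
are compatible with zero: marker uncertainty adds random, not systematic,
displacement error on the ~1 mm scale.  `run1/` also contains per-stage
CSVs (`volume_changes.csv`, `marker_changes.csv`, `displacements.csv`),
a `cohort.json` with all pooled statistics and a `manifest.json`.

Other subcommands — `simulate`, `volume-change`, `marker-analysis`,
`register`, `uncertainty` — run the individual stages over the CSV
dialects documented in `implantkinetics.implant_model`.

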