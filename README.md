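# emdamage

Electron-beam damage analysis for cryo-EM dose-series density maps.

## The problem

Single-particle cryo-EM routinely collects 40–80 e⁻ Å⁻² per movie.
Converted with the standard 300 kV factor of 3.7 MGy per e⁻ Å⁻², a
typical 83 e⁻ Å⁻² exposure deposits ~307 MGy — more than fifteen times
the Henderson limit (~20 MGy), the dose at which a cryo-cooled crystal's
diffraction halves.  For redox-active metalloproteins the consequences
are concrete: disulfide bonds cleave, metal centers are photo-reduced,
metal–metal and metal–oxygen distances stretch by tenths of an Ångström,
and refined occupancies drop below 1.  Because exposures are
dose-fractionated into movie frames, maps reconstructed from only the
initial frames trade a little resolution for much less damage, and the
damage itself can be charted against accumulated dose.

`emdamage` packages that analysis for anyone studying beam sensitivity
of metal clusters (the Mn₄CaO₅ oxygen-evolving cluster of photosystem II
is the motivating case): map algebra and difference maps, peak-based
metal/ligand assignment, distance-restrained real-space refinement, FSC
resolution estimation, Rosenthal–Henderson B-factor fits, and a
synthetic dose-series generator so the entire chain is testable against
planted ground truth without any downloads.

## The model in brief

* **Dose bookkeeping.** Fluence *F* (e⁻ Å⁻²) → absorbed dose
  *D* = 3.7 *F* MGy; the initial *k* of *n* frames of a *F*-total
  exposure carry *k/n · F*.
* **Forward model.** An atom at **r₀** with occupancy *q*, displacement
  parameter *B* (Å²) and element weight *w* ∝ *Z* contributes
  *q·w·(2πσ²)^(−3/2)·exp(−|**r**−**r₀**|²/2σ²)* with
  *σ² = (B + B_global)/8π²* — the crystallographic B-to-width convention.
* **Damage process (synthetic).** Occupancy decays as exp(−*D*/*D_c*);
  ADPs inflate linearly; damage-prone atoms drift along fixed directions
  with saturating kinetics Δ(*D*) = Δ_max(1 − e^(−D/D_d)); a disulfide
  partner vanishes beyond its break dose; frames carry independent
  Gaussian noise.
* **Resolution.** Gold-standard FSC between half-maps,
  FSC(s) = Re⟨F₁F₂*⟩/√(⟨|F₁|²⟩⟨|F₂|²⟩) per shell, reported at the 0.143
  crossing.
* **Rosenthal–Henderson B.** 1/d² = (2/B)·ln N + const; *B* is twice the
  inverse slope of inverse squared resolution against log particle
  count.
* **Cluster geometry.** Metals are assigned to the highest map peaks;
  oxygens/waters to ≥7σ peaks of the metal-subtracted (carved) map
  within a 1.7–3.0 Å bonding window; positions are refined against the
  map under metal–ligand distance restraints tightened from σ = 0.1 to
  0.05, targets refreshed each macrocycle, until distances converge;
  contacts refining below 1.7 Å are fixed at 1.8 Å and flagged.
  Reported distances are the mean of the final four macrocycles, rounded
  half-up to one decimal, with deltas against a damage-free reference
  geometry.

## Worked example

```python
from emdamage import dose_to_gray, PipelineConfig, run_pipeline

info = dose_to_gray(83.0)
print(f"83 e-/A^2 = {info['dose_mgy']:.1f} MGy "
      f"({info['henderson_ratio']:.1f}x the Henderson limit)")

report = run_pipeline(PipelineConfig(seed=1, dose_list=(3.3, 83.0)))
print(report.table[["fluence", "dose_mgy", "frames", "bond_intact"]]
      .to_string(index=False))
for fluence in (3.3, 83.0):
    deltas = report.distance_tables[fluence]["deltas"]["deltas"]
    print(f"dose {fluence:>4} e-/A^2: Mn2-Mn3 delta vs damage-free "
          f"reference = {deltas['Mn2-Mn3']:+.1f} A")
```

prints

```
83 e-/A^2 = 307.1 MGy (15.4x the Henderson limit)
 fluence  dose_mgy  frames  bond_intact
    3.32    12.284       2         True
   83.00   307.100      50        False
dose  3.3 e-/A^2: Mn2-Mn3 delta vs damage-free reference = +0.1 A
dose 83.0 e-/A^2: Mn2-Mn3 delta vs damage-free reference = +0.3 A
```

Reading it: the two-frame (3.3 e⁻ Å⁻², 12.3 MGy) map keeps the
disulfide probe intact at a 4σ contour and its Mn2–Mn3 distance within
0.1 Å of the damage-free reference, while the full 50-frame
(307 MGy) map has a cleaved disulfide and a +0.3 Å dose-averaged
Mn2–Mn3 elongation; the metal peak-height occupancy proxy drops from
1.00 to 0.82.  `report.distance_tables` also holds the per-macrocycle
distance tables and the clamped-pair flags.

The same stages are available from the shell — `emdamage simulate`,
`sum-frames`, `subtract`, `lowpass`, `transform`, `carve`, `peaks`,
`assign`, `bond`, `superpose`, `fsc`, `rh-fit`, `dose-report`,
`refine`, and `run` for the whole pipeline.

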