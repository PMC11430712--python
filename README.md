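# poreblock

Trajectory-level analysis of ion-channel pore block, built around the question
of whether a peptide lodged in a cation channel's outer pore actually stops
ions from getting through. The package implements, as one tested pipeline,
the analyses used to characterise a channel–blocker complex from molecular
dynamics trajectories — plus the electrophysiology-side concentration–response
stage — and a synthetic pseudo-channel generator that plants known ground
truth so every stage is verifiable without large production trajectories.

It is aimed at computational biophysicists and ion-channel modellers who have
a topology (PDB), frames (multi-model PDB or DCD) and a vdW-radius/charge
table, and want the standard battery of pore-block descriptors with explicit,
testable definitions.

## What it computes

**Interface contacts.** Hydrogen bonds use a donor–acceptor distance < 3.5 Å
and a D–H–A angle criterion; the ambiguous "180°–70°" angle window is read by
default as ≤ 70° deviation from linearity (D–H–A ∈ [110°, 180°]), with the
literal [70°, 180°] reading selectable. Van der Waals contacts between heavy
atoms A and B require |AB| < R_vdw(A) + R_vdw(B) + 0.5 Å. Per-frame counts,
residue-pair frequencies and flare-plot edge lists are exported.

**Buried surface.** Shrake–Rupley SASA with a deterministic golden-spiral
point set, and the ligand–receptor contact area in two conventions:
`buried_interface` = SASA_lig + SASA_rec − SASA_complex (default) and
`as_printed` = 2·SASA_lig − SASA_complex.

**Pore geometry.** A HOLE-style radius profile: at each z-slice the largest
sphere centred at (x, y, z) that overlaps no lining atom's vdW sphere,
maximised over (x, y) near the axis by deterministic grid refinement.

**Ion permeation.** Per-ion visits to a filter region (default z ∈ [0, 20] Å)
with residence times and outcome classification, up/down translocation
counts, per-ion z-traces, and total plus local/total density profiles.

**Pore electrostatics.** The applied-field relation V = E·L_z, and the 1-D
potential φ(z) from double integration of the binned charge density,
φ(z) = −(1/ε₀)∫∫ ρ, gauged to φ(z_min) = 0.

**Ensemble similarity.** Cartesian covariance PCA after iterative mean
superposition, and the root-mean-square inner product of two n-mode
subspaces, RMSIP = sqrt((1/n) Σᵢⱼ (ηᵢ·νⱼ)²) ∈ [0, 1].

**Concentration–response.** `HillModel` / `HillResults` fit
response(c) = bottom + (top − bottom)/(1 + (c/IC50)^h) by multi-start least
squares on log-concentration, with standard errors, t-based confidence
intervals and a `summary()` table.

## Worked example

The default configuration generates a blocked/unblocked pseudo-channel pair
(240 frames, 10 K⁺ ions, −300 mV applied) and runs every stage:

```python
from poreblock.pipeline import load_config, run_pipeline

summary = run_pipeline(load_config(), output_dir="poreblock_out")
for name, s in summary["systems"].items():
    print(name, s["min_pore_radius_A"], s["translocations_total"], s["n_visits"])
print("V =", summary["applied_voltage_V"], "V   IC50 =", summary["ic50_uM"], "uM")
```

prints (seed 1):

```
without_blocker 4.393850251214243 6 8
with_blocker 1.2968367049962022 0 0
V = -0.3 V   IC50 = 18.619999999999997 uM
```

The open channel passes 6 ions through the filter while 8 visits are logged;
placing the blocker peptide in the constriction narrows the minimum pore
radius from 4.39 Å to 1.30 Å and suppresses every crossing — the direction of
effect expected of a pore plug. The IC50 is recovered from the noiseless
4-point dose–response table at its generating value. The same run is
available from the shell:

```bash
poreblock report --config examples/demo_config.yaml
```

Artifacts (CSV profiles, visit tables, flare JSON, `summary.json`) land in
the output directory, each stamped with the config hash, seed and package
version.

Fitting your own dose–response table:

```python
import pandas as pd
from poreblock.dose import HillModel

df = pd.read_csv("doses.csv")          # columns: concentration, response
res = HillModel.from_dataframe(df).fit()
print(res.summary())
```

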