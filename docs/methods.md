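# Methods

This note records what each stage of the pipeline computes, the assumptions
behind it, the defaults and why they were chosen, and what the synthetic
test systems do and do not establish about real trajectories.

## System model and I/O

A system is a static atom table (element, residue, partial charge, vdW
radius, hydrogen-bond role, bonds, named groups) plus ordered coordinate
frames with an orthorhombic box. Lengths are Å, times ns, charges elementary
units; z is the membrane normal and pore axis, with an affine z-offset
available at load so the pore centre can define z = 0. Triclinic boxes are
rejected: every analysis here assumes rectangular membrane boxes, and the
minimum-image convention is implemented for that case only.

File I/O goes through MDAnalysis (PDB v3.3 topology with CONECT bonds;
multi-model PDB or CHARMM/NAMD DCD frames). vdW radii and default charges
come from a plain-text per-element table whose defaults are the Bondi radii
(no radii source being canonical for the contact criterion, Bondi is the
conventional element set); atoms whose element is absent from the table must
carry per-atom overrides in the PDB B-factor (radius) and occupancy (charge)
columns, and loading fails loudly otherwise. Donor/acceptor/hydrogen roles
are not representable in plain PDB, so they are derived deterministically
from chemistry: an H bonded to N/O/S is a polar hydrogen, an N/O/S carrying
one is a donor, any other N/O/S is an acceptor. The synthetic generator
encodes planted roles by choosing those elements, which makes write→read
round trips role-preserving by construction.

RMSD uses closed-form Kabsch superposition (proper rotation enforced via the
determinant correction); with fewer than three non-collinear atoms the
rotation is undetermined, so the fit degrades to translation-only with a
warning rather than failing. The radius of gyration is unweighted by default
— the choice is exposed (`mass_weighted=True`) because conventions differ
and nothing in the analyses downstream depends on it.

## Synthetic pseudo-channel generator

The generator emulates exactly the features the analyses consume: a
cylindrical pore of stacked atom rings with a piecewise-constant radius (a
narrower band models the selectivity filter), an optional 12-bead blocker
peptide whose first bead sits on-axis inside the constriction, monovalent
cations, and donor/hydrogen/acceptor triplets placeable at exact (distance,
angle) geometry. Ions move by overdamped Langevin dynamics — drift μqE with
Einstein mobility μ = D/k_BT at 310 K, plus Gaussian diffusion — with hard
reflecting walls at the box, the membrane slab, the pore lining and the
blocker beads (hard-sphere admissibility of the ion centre). Channel and
blocker atoms are static apart from optional Gaussian jitter. All randomness
derives from one integer seed and runs are bitwise reproducible.

Demo defaults: 240 frames at 1 ns spacing, 10 ions started near the axis
above the extracellular mouth, E = −0.003 V/Å in a 100 Å box (V = −300 mV),
axial diffusion 10 Å²/ns with slower lateral diffusion (0.5 Å²/ns) so ions
funnel into the pore rather than wander the leaflet plane; ring radius 8 Å
(filter band 6.2 Å) with 1.7 Å lining atoms, giving a 4.5 Å open filter that
admits a 2.75 Å cation, and a 2.0 Å blocker bead whose hard-sphere annulus
leaves no admissible passage. These numbers are chosen so the planted
physics is unambiguous: the blocked system structurally cannot pass ions,
and the open system passes several per run at any seed.

What the generator does **not** model: water, lipids, thermodynamic realism,
channel gating, ion–ion interactions. Passing tests on these systems
establishes that the *bookkeeping and geometry* of every analysis is exact —
planted events are recovered, profiles match closed forms — not that the
analyses characterise any particular real channel.

## Contact criteria

Van der Waals: heavy-atom pairs from two disjoint groups with
|AB| < R_vdw(A) + R_vdw(B) + 0.5 Å, strict inequality, minimum image.
Hydrogens are excluded by default (flag to include). Detection uses a
periodic cKD-tree for candidates and re-applies the exact criterion per
pair, so it is guaranteed identical to the brute-force all-pairs scan (and
tested to be, on hundreds of random frames).

Hydrogen bonds: donor–acceptor distance < 3.5 Å (strict) and a D–H–A angle
test with the hydrogen at the vertex; when a donor carries several
hydrogens, the most linear one decides. The printed angle window "180°–70°"
admits two readings; the default is ≤ 70° deviation from linearity (angle ∈
[110°, 180°]), the convention of the contact-analysis tools this criterion
descends from, with the literal [70°, 180°] window behind
`angle_mode="literal"`. Both scan directions (donor in either group) are
covered. Counts are reported at both atom-pair and residue-pair granularity,
since "n hydrogen bonds" is ambiguous between the two; frequency tables give
the fraction of frames in which a residue pair shows at least one contact of
each kind, which is what flare-plot edge weights encode.

## Surface area and contact area

SASA is the Shrake–Rupley estimate: each atom's expanded sphere
(r_vdw + probe, probe 1.4 Å — the conventional water radius) is sampled with
a deterministic golden-section spiral (default 960 points; fewer than 32 is
refused), a point is accessible when outside every neighbour's expanded
sphere, and the accessible fraction scales 4π(r_vdw + probe)². Because the
point set is fixed in space rather than co-rotating with the molecule, SASA
is exactly translation-invariant but rotation-invariant only to
discretization accuracy (≲ 0.5% at 960 points); no seed is involved. A
degenerate tie — a test point exactly on a neighbour's sphere, as with
coincident identical atoms — is assigned to the lower-index atom, so exact
duplicates contribute exactly one sphere's surface.

Contact area per frame uses in-complex coordinates with the partner deleted
(no relaxation). Two conventions are implemented and never silently merged:
`buried_interface` = SASA_lig + SASA_rec − SASA_complex, the standard buried
interface, non-negative up to discretization; and `as_printed` =
2·SASA_lig − SASA_complex, an alternative in circulation that can go
negative for small ligands on large receptors. The default is
`buried_interface`; the choice is a config key, and outputs record which
formula produced them.

## Pore radius

The profile follows the HOLE objective: at each z-slice, maximise over the
slice point (x, y) the clearance min_i(|c − x_i| − r_i) over lining atoms.
The maximisation is a three-level deterministic grid refinement (0.5 →
0.05 → 0.005 Å steps) confined to a disc around the pore axis — the
objective is unbounded outside the lining, so the search domain is part of
the definition. Against an exhaustive 0.01 Å grid the refinement agrees to
well under 0.05 Å on irregular linings. Slices with no atoms in reach
report +inf rather than a fabricated radius.

## Ion occupancy, visits, translocations

The filter region is a z-slab (default z ∈ [0, 20] Å) with an optional
cylindrical radial cutoff; the demo uses a fixed 8 Å cylinder, and a
local-radius-based cutoff can be emulated by passing a different region. A
visit is a maximal run of consecutive frames with the ion inside the region;
no smoothing or gap-merging is applied (a one-frame excursion ends the
visit) — determinism is preferred over heuristics, and residence statistics
at the frame spacing used here are insensitive to the choice. Outcomes
partition visits: entry and exit z-sides differing makes a translocation
(up/down counted separately, re-crossings independently), matching sides or
a radial exit is a return, and a visit still open at the last frame is
censored. Density profiles report time-averaged ions/Å (so the profile
integral equals the mean in-cylinder ion count exactly) alongside the
local/total fraction per bin.

## Electrostatics

The 1-D potential uses the standard applied-field membrane protocol: bin the
time-averaged charge density inside an averaging cylinder (or the whole
cross-section), then double-integrate Poisson's equation with ε = ε₀ and the
gauge φ(z_min) = 0, E(z_min) = 0. The integration is exact for
piecewise-constant bin densities (field piecewise linear, potential
piecewise quadratic, both accumulated bin by bin), so the uniform-slab
closed form is reproduced to machine precision at matching bin edges. No
implicit dielectric is applied; on a non-neutral synthetic system the
absolute values are accordingly large, and only differences/shapes are
meaningful. The applied-field voltage is V = E·L_z.

## Essential dynamics

PCA superposes all frames onto the trajectory mean (two iterations: align to
frame 0, re-align to the resulting mean), eigen-decomposes the 3M×3M
Cartesian covariance and keeps the leading modes. The superposition
reference being the mean (not frame 0) is recorded in the mode-set metadata.
Requesting more modes than the covariance rank is an error, except for the
strictly rigid case where all-zero eigenvalues are returned as such. RMSIP
uses n = 10 modes by default (the common essential-dynamics convention; the
analysis that motivated it reports no n) and is asserted into [0, 1] on
every call.

## Hill fit

The inhibition curve bottom + (top − bottom)/(1 + (c/IC50)^h) is fitted by
Levenberg–Marquardt least squares on log10 concentration (for conditioning),
multi-started over a grid of log-IC50 initial values spanning the design.
With fewer than five distinct concentrations the bottom/top are constrained
to 0/1 — with four points a four-parameter fit is not identifiable — and the
free fit requires ≥ 5. Flat data, wrong-signed slopes and failed starts
yield an explicit non-converged result, never a silent number. Standard
errors come from the Jacobian at the optimum; confidence intervals are
t-based with df = n_points − n_params on the log10-IC50 scale (standard
nonlinear-regression practice), which the seeded recovery study shows gives
~95% empirical coverage at σ = 0.05 noise on the 4-point design.

## Orchestration

`run_pipeline` runs any subset of stages on a with-blocker/without-blocker
pair — user-supplied files or the generated demo — writing CSV/JSON
artifacts plus a machine-readable summary; every output embeds the config
hash, seed and package version, and equal configs produce byte-identical
summaries. The `poreblock` CLI is a thin wrapper over this; logs go to
stderr only.

## Problem sizes

The shipped demo uses 240 frames of ~160–180 atoms with 10 ions, SASA at 480
points with a stride of 10 frames, and a 1000-replicate IC50 recovery study;
the full pipeline and the recovery study each complete in seconds on one
CPU. These sizes are the package's test conditions, chosen so planted
effects are unambiguous while the whole suite stays interactive.

## Known limitations

- No analytic (arc-based) SASA; accuracy is bounded by the point density.
- The pore-radius search assumes a single, roughly axis-aligned channel;
  branched or strongly tilted pores would need a moving axis.
- The 1-D Poisson treatment ignores lateral structure and dielectric
  screening by construction.
- The Langevin generator's ions do not interact with each other, so
  knock-on permeation statistics are out of reach.
- MM-GBSA-style binding energetics are out of scope entirely.
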