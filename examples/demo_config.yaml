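# Demo run configuration for the synthetic blocked/unblocked channel pair.
# Every key shown here has the same built-in default; override as needed.
# User-supplied systems replace the generator via a `systems:` block, e.g.
#
# systems:
#   with_blocker:    {topology: sys_a.pdb, trajectory: sys_a_traj.pdb, radii: radii.dat}
#   without_blocker: {topology: sys_b.pdb, trajectory: sys_b_traj.pdb, radii: radii.dat}

seed: 1
output_dir: poreblock_out
dt: 1.0          # ns between frames

generate:
  n_frames: 240
  n_ions: 10
  field_E: -0.003       # V/Angstrom along z; with Lz = 100 A this applies -300 mV
  diffusion: 10.0       # axial ion diffusion coefficient, A^2/ns
  lateral_diffusion: 0.5
  jitter: 0.05          # Gaussian jitter of channel/blocker atoms, A
  open_radius: 8.0      # lining ring radius outside the filter, A
  filter_radius: 6.2    # lining ring radius inside the filter band, A
  filter_z: [0.0, 20.0]
  n_rings: 11
  atoms_per_ring: 14
  atom_vdw: 1.7
  slab_z: [-20.0, 20.0]
  box: [40.0, 40.0, 100.0]
  blocker_radius: 2.0

region:                 # the "selectivity filter" analysis window
  zmin: 0.0
  zmax: 20.0
  radial_cutoff: 8.0

contacts:
  fudge: 0.5            # vdW criterion: |AB| < R(A) + R(B) + fudge
  d_max: 3.5            # H-bond donor-acceptor cutoff, A
  angle_mode: deviation # 'deviation' (D-H-A in [110, 180]) or 'literal' ([70, 180])

sasa:
  probe: 1.4            # A
  n_points: 480

contact_area:
  formula: buried_interface   # or 'as_printed' (2*SASA_lig - SASA_complex)
  stride: 10

pore_radius: {step: 0.5, zmin: -20.0, zmax: 20.0}
density:     {zmin: -45.0, zmax: 45.0, width: 1.0}
potential:   {zmin: -45.0, zmax: 45.0, width: 1.0, radial_cutoff: null}
rmsip:       {n_modes: 10}

dose:
  csv: null             # path to a (concentration, response) CSV; else synthesized
  ic50_true: 18.62      # uM, ground truth for the synthesized table
  hill_slope_true: 1.0
  concentrations: [1.0, 10.0, 20.0, 50.0]
  noise_sd: 0.0
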