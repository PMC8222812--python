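# kirgate

Normal-mode-driven gating analysis for tetrameric inward-rectifier
(Kir-type) potassium channels.

Kir channels conduct K⁺ through a pore gated at a few constriction
residues whose side chains narrow the conduction pathway.  Whether such
a channel is open is, at the geometric level, a distance question: a
gate is open when the shortest atomic distance between the constriction
residues on diametrically opposed chains exceeds the unhydrated K⁺
ionic diameter, 3.5275 Å.  `kirgate` turns that criterion — together
with the normal-mode-based conformational exploration used to generate
the ensembles it is applied to — into a reusable, testable pipeline:

1. **Elastic-network normal modes** (`enm_modes`): anisotropic network
   Hessian, lowest-frequency eigenpairs, and a selection protocol that
   keeps the modes driving channel opening (scored by diametric
   distance changes at a probe residue, classified as spherical or
   elliptical openings, de-duplicated, lowest frequencies kept).
2. **MDeNM** (`mdenm_engine`): replica Langevin dynamics with periodic
   kinetic-energy injections along unit combinations of the selected
   modes — each injection carries exactly (3/2)·N·k_B·ΔT (default
   ΔT = 4 K, 10 excitations, 1 ps relaxation time between them).
3. **Clustering and relaxation** (`cluster_relax`): greedy leader
   clustering on channel-region RMSD (residues 121–133, 0.9 Å),
   closest-to-mean representatives, free-dynamics relaxation keeping
   the last three quarters of each trajectory.
4. **Gating analysis** (`gating_analysis`): the six shortest gate
   distances (124/129/132 × A–C/B–D), a five-state classifier (fully
   open, fully closed, two partially open states, and a middle-gate
   129-closed state), population tables and distance distributions.
5. **Geometry** (`geometry_analysis`): TM1 kink angle (segment axes
   46–56 / 56–80), cytoplasmic-domain rotation pseudo-dihedral
   (CA 108 / axis projections / CA 266), per-residue ensemble RMSD
   (RMSD_i = √(1/N Σ|r_i(n) − r_i^ref|²)), and a simplified
   pore-radius profile.
6. **Synthetic channels** (`synthetic_data`): idealized C4 tetramers
   with analytically known gate distances, kink, rotation and state
   populations — ground truth for every stage.

Intended users: structural bioinformaticians and simulators who want
the gating-analysis operators on their own ensembles (multi-model PDB
in, CSV/JSON out), or a fully controlled synthetic test bed for
method work on channel-gating classification.

## Worked example

```python
from kirgate import (ChannelSpec, SyntheticParams, make_ensemble,
                     make_channel, population_table, kink_angle,
                     ctd_rotation)

spec = ChannelSpec()                      # 121-133, gates 124/129/132, 3.5275 Å
params = SyntheticParams(n_frames=2000, seed=7)
ensemble = make_ensemble(params, spec)    # labeled synthetic frames
table = population_table(ensemble, spec)  # classify every frame
print(table.to_dataframe().to_string(index=False))

open_state = make_channel(SyntheticParams(kink_angle_deg=13.0,
                                          ctd_rotation_deg=33.0), spec)
closed_ref = make_channel(SyntheticParams(kink_angle_deg=13.0), spec)
print("TM1 kink (chain A):", round(kink_angle(open_state, "A"), 1), "deg")
print("CTD rotation offset:",
      round(ctd_rotation(open_state, "A") - ctd_rotation(closed_ref, "A"), 1),
      "deg")
```

prints

```
                      state  percent
                 fully_open     53.9
               fully_closed      0.0
partial_124_open_132_closed      0.0
partial_132_open_124_closed      0.0
             gate129_closed     46.1
TM1 kink (chain A): 13.0 deg
CTD rotation offset: 33.0 deg
```

The ensemble was generated from an engineered-open scenario (52.8 %
fully open, 47.2 % closed only at the middle 129 gate); the classifier
recovers that split within binomial sampling error at n = 2000.  The
two geometry calls verify that a built-in 13° TM1 kink and a 33°
cytoplasmic-domain rotation are measured back exactly from the
constructed coordinates.

## Command line

The same pipeline is scriptable via the `kirgate` CLI
(`make-fixtures`, `simulate`, `cluster`, `relax`, `analyze`,
`report`), driven by one YAML config that holds every protocol
constant and is hashed into all artifacts:

```sh
kirgate make-fixtures --config run.yaml
kirgate analyze out/ensemble.pdb --labels out/labels.csv --config run.yaml
kirgate report out/analysis_run_populations.json --out summary.json --md summary.md
```

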