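# pdzkit

Analysis pipeline for PDZ-domain/peptide recognition studies: salt-bridge
occupancy statistics over molecular trajectories (with a docked/undocked
classifier for the C-terminal α3 helix), one-set-of-identical-sites ITC
binding thermodynamics, and NMR chemical-shift-perturbation mapping — plus
synthetic-data generators so the whole pipeline is testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `pdzkit.structure` | PDB structure/trajectory I/O, residue numbering conventions (protein 302–403, ligand −5…0), charged-group chemistry (anchor carbons, mass-weighted charge centers), succinimide water-loss mass |
| `pdzkit.saltbridge` | Per-frame contact detection under two criteria (anchor-carbon minimum < 5 Å, charged-center < 4 Å), occupancy/any-of aggregates, helix undocked fraction, distance time series, occupancy tables |
| `pdzkit.itc` | One-site heat model with displaced-volume correction, dilution subtraction, (n, K_d, ΔH) least-squares fitting, ΔG = RT·ln K_d, −TΔS = ΔG − ΔH, condition comparisons |
| `pdzkit.csp` | Combined amide perturbation √(ΔδH² + (ΔδN/5)²), three-bin colour classes ([0,0.2), [0.2,0.5), ≥0.5 ppm), per-region summaries |
| `pdzkit.synth` | Generators: Markov contact trajectories with competition groups and exact truth records, noisy ITC titrations, fast-exchange titration peak lists |
| `pdzkit.workflow` / `pdzkit.cli` | YAML config validation, a deterministic simulate→analyse→report pipeline, and the `pdzkit` CLI |

## CLI

```sh
pdzkit show-defaults                       # full default config as YAML
pdzkit run --config run.yaml --seed 1      # full pipeline into out_dir
pdzkit simulate traj|itc|peaks --out DIR   # individual generators
pdzkit saltbridge --traj t.pdb --pairs pairs.yaml --criterion anchor --out DIR
pdzkit helixstate --traj t.pdb
pdzkit distances --traj t.pdb --a A:334 --b B:-5 --out dist.tsv
pdzkit itc-fit --isotherm iso.tsv --blank blank.tsv --out thermo.tsv
pdzkit csp --free peaks_00.tsv --bound peaks_05.tsv --out DIR
```

Trajectories are multi-model PDB (chain `A` protein, chain `B` ligand by
convention); isotherms and peak lists are tab-delimited; configs are YAML.
Identical config + seed reproduce byte-identical analysis tables.

## Notes

* "Closer than 5 Å" is implemented as the *minimum* over the 2×2 anchor-carbon
  cross pairs, strict at the cutoff.
* The helix-anchoring bridges are Glu334–**Arg**399 and Lys355–Glu401; the
  alternative "Asp399" spelling that appears in some table headers is a known
  inconsistency and is not supported.
* The ¹⁵N scale factor of the combined shift (default 1/5) and the
  phospho-Tyr anchor-carbon choice are configurable, since neither is fixed
  by a published convention.
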