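# nucdyn

Comparative nucleosome trajectory analysis: local (Cα RMSF) and global
(center-of-mass distance) fluctuation measures, fractional residue contact
maps and salt-bridge tracking, Cα principal component analysis with 2D
free-energy-landscape basin/barrier quantification, and DNA-detachment
event-coincidence analysis. A synthetic-data module generates toy
nucleosome-like systems and trajectories with planted ground truth so the
entire pipeline is testable without running MD.

## Layout

| module | contents |
|---|---|
| `nucdyn.core` | PDB/trajectory ingestion, nucleosome annotation (roles, regions, basepair↔dyad coordinates), site selection |
| `nucdyn.geometry` | Kabsch superposition, trajectory fitting, average structures, COM distance series |
| `nucdyn.fluctuations` | per-site RMSF, trajectory-thirds significance thresholds, two-system comparison, basepair RMSF |
| `nucdyn.contacts` | fraction-of-time contact maps (3.6 Å heavy-atom cutoff, strict `<`), interface contact counts, minimum-distance and salt-bridge series (4.0 Å; head-group or Arg CZ↔Glu CD charge centers) |
| `nucdyn.pca_fel` | Cα PCA, projections, representative frames, ±5·√λ mode animations, −kT ln(density) landscapes, watershed basins and bottleneck barriers |
| `nucdyn.events` | DNA-segment detachment episodes (threshold + hysteresis), residue-swing series, start-to-start event coincidence |
| `nucdyn.synthetic` | toy nucleosome builder (Cα protein cylinder + DNA superhelix), Gaussian / planted-mode / two-state / scripted-detachment trajectory generators |
| `nucdyn.crystal` | sequence-guided residue matching, matched-Cα RMSD, basepair counting, insertion detection between crystal structures |
| `nucdyn.report`, `nucdyn.cli` | two-system comparison orchestration and the `nucdyn` command line |

Conventions: Å and ns everywhere, 0-based frames, half-open windows, default
analysis window = final 40% of frames (override per config).

## CLI

Every system is described by one JSON/TOML config
(`structure`, `trajectory`, `chain_roles`, optional `regions`,
`dyad_bp_offset`, `window_fraction`, `events`):

```sh
nucdyn synth --out demo --seed 1            # toy system + trajectory + config
nucdyn annotate --config demo/config.json --out ann.json
nucdyn rmsf     --config demo/config.json --out rmsf.tsv --role H3-like
nucdyn com      --config demo/config.json --out com.tsv \
                --dimer-a homodimer-1 --dimer-b homodimer-2
nucdyn contacts --config demo/config.json --out contacts.tsv
nucdyn pca      --config demo/config.json --out pca.json
nucdyn fel      --config demo/config.json --out fel.tsv
nucdyn compare  --config-a a.json --config-b b.json --out report/
```

`compare` writes `report.json`, `report.md`, and a manifest; stage subsets via
`--stages rmsf,com,contacts,pca,fel,events`.

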