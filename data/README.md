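# Crystal-structure inputs

The crystal checks (tests `test_crystal_superposition_under_2A`,
`test_cenpa_crystal_resolves_121_bp`, `test_h3_crystal_resolves_147_bp`,
`test_loop1_two_residue_insertion` and acceptance targets t1–t3) read:

- `data/1kx5.pdb` — canonical H3 nucleosome, PDB entry 1KX5
- `data/3an2.pdb` — CENP-A nucleosome, PDB entry 3AN2

Download them from https://files.rcsb.org/download/1KX5.pdb and
https://files.rcsb.org/download/3AN2.pdb and place them here (lower-case
names). This build environment has no route to the PDB, so the files are not
bundled.
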