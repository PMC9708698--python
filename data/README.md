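# data/

External inputs that cannot be redistributed with the repository.

The structure-ensemble control (`analysis/06_structure_screen.py` and
the corresponding acceptance test) expects the deposited 12-model NMR
ensemble of the human telomeric quadruplex at `data/2GKU.pdb`
(multi-model PDB with hydrogens, available from the Protein Data Bank,
accession 2GKU). Place the file here to run the screen against the
deposited coordinates; all other tests and scripts generate their
inputs programmatically.
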