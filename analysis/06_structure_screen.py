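#!/usr/bin/env python
"""Imino-to-sugar proton contact screen over an NMR structure ensemble.

Sugar H3'/H4' protons resonate near water and are partially inverted by
the water-selective pulse; an NOE from such a proton to a nearby imino
proton would mimic exchange.  This screen reports every (imino, sugar
proton) pair closer than 5 A in at least 7 of the ensemble's models.

Run against the deposited telomere quadruplex ensemble (12 models) with
  python analysis/06_structure_screen.py --structure data/2GKU.pdb
On the deposited ensemble the expected outcome is exactly two H4'
contacts (T13 H4' near the G11 imino, A14 H4' near the G15 imino) and
no H3' contacts.
"""

import argparse
from pathlib import Path

import pandas as pd

from iminoex.structure_contacts import imino_sugar_contacts, load_models


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--structure", type=Path, required=True,
                    help="multi-model PDB/mmCIF file with hydrogens")
    ap.add_argument("--cutoff", type=float, default=5.0)
    ap.add_argument("--min-models", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/contacts.tsv"))
    args = ap.parse_args()

    models = load_models(args.structure)
    contacts = imino_sugar_contacts(
        models, cutoff=args.cutoff, min_models=args.min_models
    )
    df = pd.DataFrame(
        [(c.donor_residue, c.donor_atom, c.target_residue, c.target_atom,
          c.n_models_satisfying, c.min_distance) for c in contacts],
        columns=["donor_residue", "donor_atom", "target_residue",
                 "target_atom", "n_models", "min_distance_A"],
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False, float_format="%.3f")
    print(f"{models.n_models} models; {len(df)} contact(s) "
          f"< {args.cutoff} A in >= {args.min_models} models -> {args.out}")
    if len(df):
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
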