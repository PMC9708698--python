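#!/usr/bin/env python
"""In-vitro opening rates from the catalyst titration plateau.

At saturating base catalyst every opening event exchanges, so the
maximum k_ex over the titration equals the opening rate k_open.  Writes
kopen.tsv with a plateau flag (False when k_ex was still rising at the
top concentration).
"""

import argparse
from pathlib import Path

import pandas as pd

from iminoex.interface import read_config
from iminoex.pipeline import titrate_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = read_config(args.bundle / "config.json")
    kex_df = pd.read_csv(args.bundle / "kex.tsv", sep="\t")
    df = titrate_table(kex_df, cfg)
    out = args.bundle / "kopen.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.17g")
    print(f"k_open (in vitro, plateau rule) -> {out}")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
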