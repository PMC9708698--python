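#!/usr/bin/env python
"""Classify in-cell base-pair opening against the in-vitro rates.

Because k_open >= k_ex always, the in-cell k_ex is a lower bound on the
in-cell opening rate: a base pair is called "increased_in_cell" when
that bound clears the in-vitro k_open beyond the 1-sd error bars, and
"indeterminate" otherwise (the bound is one-sided).  Writes
comparison.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from iminoex.interface import write_comparison_report
from iminoex.pipeline import compare_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/study"))
    ap.add_argument("--sd-multiplier", type=float, default=1.0)
    args = ap.parse_args()

    kopen_df = pd.read_csv(args.bundle / "kopen.tsv", sep="\t")
    kex_df = pd.read_csv(args.bundle / "kex.tsv", sep="\t")
    comparisons = compare_table(kopen_df, kex_df, sd_multiplier=args.sd_multiplier)
    out = args.bundle / "comparison.tsv"
    write_comparison_report(out, comparisons)
    print(f"comparison report -> {out}")
    for c in comparisons:
        print(f"  {c.residue:>4s}: k_open(vitro)={c.k_open_invitro:.1f}"
              f"+/-{c.k_open_invitro_sd:.1f}  k_ex(cell)={c.k_ex_incell:.1f}"
              f"+/-{c.k_ex_incell_sd:.1f}  -> {c.verdict}")


if __name__ == "__main__":
    main()
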