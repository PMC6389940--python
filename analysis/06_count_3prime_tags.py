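#!/usr/bin/env python
"""Count 3'-tag reads per gene with the window-extension algorithm.

Plants known read counts as jittered 3'-end footprints over 500 synthetic
genes, runs the initial-window + valley-rule extension counter, and
reports how many genes are recovered exactly.
"""

import pandas as pd

from hybridpaint import experiments as ex

SEED = 1
OUT = "results"


def main() -> None:
    res = ex.quantseq_recovery(SEED, n_genes=500)
    rate = res["n_exact"] / res["n_genes"]
    print(f"exact planted-count recovery: {res['n_exact']}/{res['n_genes']} "
          f"genes ({rate:.1%})")
    pd.DataFrame([res]).to_csv(f"{OUT}/quantseq_recovery.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
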