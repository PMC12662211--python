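#!/usr/bin/env python
"""Build maximum-parsimony haplotype trees for each simulated clade and
screen internal nodes under the new-haplogroup rule (>=5 samples, >=2
haplotypes, not defined by a control-region mutation alone).

Requires analysis/02_profiles.py.
"""

from pathlib import Path

import pandas as pd

from mitofounder.haplotree import build_mp_tree, edge_table, propose_haplogroups, to_newick
from mitofounder.mito_io import read_profiles_tsv

RESULTS = Path("results")


def main():
    rows = []
    for scenario in ("star", "constant"):
        profiles = read_profiles_tsv(RESULTS / f"02_profiles_{scenario}.tsv")
        tree = build_mp_tree(profiles)
        (RESULTS / f"03_tree_{scenario}.nwk").write_text(to_newick(tree) + "\n")
        edge_table(tree).to_csv(RESULTS / f"03_edges_{scenario}.tsv",
                                sep="\t", index=False)
        proposals = propose_haplogroups(tree)
        rows.append({
            "scenario": scenario,
            "n_haplotypes": len(tree.tips()),
            "parsimony_score": tree.score,
            "candidates_screened": len(proposals),
            "candidates_accepted": sum(ok for _, ok, _ in proposals),
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "03_tree_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nIn the star clade nearly every sample is its own haplotype and "
          "internal structure is sparse, so few candidate haplogroups pass "
          "the five-sample/two-haplotype screen; the nested constant-size "
          "clade shows deeper shared branches.")


if __name__ == "__main__":
    main()
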