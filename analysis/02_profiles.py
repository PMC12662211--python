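#!/usr/bin/env python
"""Call variant profiles against the reference and apply the standard site
mask; summarise how many calls the mask removes per scenario.

Requires analysis/01_simulate.py to have been run.
"""

from pathlib import Path

import pandas as pd

from mitofounder.mito_io import (
    apply_mask, call_variants, load_fasta, load_reference, write_profiles_tsv,
)

FIX = Path("scratch/fixtures")
RESULTS = Path("results")


def main():
    ref = load_reference(FIX / "reference.fasta")
    rows = []
    for scenario in ("star", "constant"):
        seqs = load_fasta(FIX / scenario / "sequences.fasta")
        raw = [call_variants(s, ref, sample_id=n) for n, s in seqs.items()]
        masked = [apply_mask(p) for p in raw]
        write_profiles_tsv(RESULTS / f"02_profiles_{scenario}.tsv", masked)
        rows.append({
            "scenario": scenario,
            "n_samples": len(raw),
            "variants_raw": sum(len(p) for p in raw),
            "variants_masked_out": sum(p.masked_removed for p in masked),
            "variants_kept": sum(len(p) for p in masked),
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "02_masking_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nMasked-out calls sit at the hypervariable hotspots "
          "(16182/16183/16519), which the simulator deliberately upweights; "
          "keeping them would inflate rho and bias clade ages upward.")


if __name__ == "__main__":
    main()
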