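"""05 - SSR and low-complexity survey.

Scans the 96-clone survey for perfect 2-4 bp tandem arrays (>= 6/5/5
units for di-/tri-/tetramers) and AT-rich low-complexity tracts, and
tabulates motif frequencies by canonical (rotation/strand) class.

Run after 01: python analysis/05_ssr_lowcomplexity.py
"""

from pathlib import Path

import pandas as pd

from repeatscape import ssr
from repeatscape.io import read_fasta

SCRATCH = Path("scratch/data/survey")
RESULTS = Path("results")


def main() -> None:
    clones = read_fasta(SCRATCH / "clones.fasta")

    all_loci, lc_rows = [], []
    for clone in clones:
        all_loci.extend(ssr.find_ssrs(clone))
        for region in ssr.find_low_complexity(clone):
            lc_rows.append(
                {
                    "clone_id": region.interval.scaffold_id,
                    "length": len(region.interval),
                    "at_fraction": round(region.at_fraction, 4),
                }
            )

    motifs = ssr.ssr_summary(all_loci)
    motifs.to_csv(RESULTS / "05_ssr_motifs.tsv", sep="\t", index=False)

    lc = pd.DataFrame(lc_rows, columns=["clone_id", "length", "at_fraction"])
    lc_summary = pd.DataFrame(
        [
            {
                "n_tracts": len(lc),
                "total_bp": int(lc.length.sum()) if len(lc) else 0,
                "mean_length": round(float(lc.length.mean()), 1) if len(lc) else 0.0,
                "mean_at_fraction": (
                    round(float(lc.at_fraction.mean()), 4) if len(lc) else 0.0
                ),
            }
        ]
    )
    lc_summary.to_csv(RESULTS / "05_low_complexity.tsv", sep="\t", index=False)

    total_bp = sum(len(c.seq) for c in clones)
    ssr_bp = sum(len(L) for L in all_loci)
    print(
        f"{len(all_loci)} SSR loci ({ssr_bp:,} bp, "
        f"{100 * ssr_bp / total_bp:.3f}% of dataset), "
        f"{len(lc)} low-complexity tracts"
    )
    print(motifs.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
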