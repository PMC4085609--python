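"""02 - K-mer repeat landscape and clone classification.

Builds the shared 20-mer index over the simulated survey, measures each
clone's repetitive fraction (bases spanned by a 20-mer occurring >= 4
times in the dataset), classifies clones low/mid/high at the 40%/70%
thresholds, and tabulates the confusion against the planted classes.

Run after 01: python analysis/02_repeat_landscape.py
"""

from pathlib import Path

import pandas as pd

from repeatscape import kmers
from repeatscape.io import read_fasta

SCRATCH = Path("scratch/data/survey")
RESULTS = Path("results")


def main() -> None:
    clones = read_fasta(SCRATCH / "clones.fasta")
    index = kmers.build_kmer_index(clones, kmers.DEFAULT_K)
    profiles = kmers.profile_clones(clones, index)

    table = pd.DataFrame(
        {
            "clone_id": [p.clone_id for p in profiles],
            "length": [len(c.seq) for c in clones],
            "repetitive_fraction": [round(p.repetitive_fraction, 4) for p in profiles],
            "clone_class": [p.clone_class for p in profiles],
        }
    )
    table.to_csv(RESULTS / "02_clone_classes.tsv", sep="\t", index=False)

    truth = pd.read_csv(SCRATCH / "truth_clones.tsv", sep="\t")
    merged = table.merge(
        truth[["clone_id", "clone_class"]].rename(columns={"clone_class": "planted"}),
        on="clone_id",
    )
    confusion = (
        pd.crosstab(merged.planted, merged.clone_class)
        .reindex(index=["high", "mid", "low"], columns=["high", "mid", "low"])
        .fillna(0)
        .astype(int)
    )
    confusion.to_csv(RESULTS / "02_class_confusion.tsv", sep="\t")

    n_high = (table.clone_class == "high").sum()
    print(f"{len(clones)} clones; {100 * n_high / len(clones):.1f}% highly repetitive")
    print(confusion)


if __name__ == "__main__":
    main()
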