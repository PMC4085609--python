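"""04 - Homology annotation and repeat composition.

Masks the sparse survey clones with the de novo consensus library from
03 (seed-and-extend homology search at >= 80% identity, >= 50 bp),
resolves overlapping hits to a disjoint annotation set, and summarizes
the repeat composition (bp, % of dataset, % of repetitive fraction,
genome-wide extrapolation).

Run after 03: python analysis/04_annotation_composition.py
"""

from pathlib import Path

from repeatscape import annotation as ann
from repeatscape.io import read_fasta, write_annotations

SCRATCH = Path("scratch/data/sparse")
RESULTS = Path("results")


def main() -> None:
    clones = read_fasta(SCRATCH / "clones.fasta")
    library = read_fasta(SCRATCH / "family_consensi.fasta")

    hits = ann.mask_with_library(clones, library)
    resolved = ann.resolve_overlaps(hits)
    write_annotations(resolved, SCRATCH / "annotations.gff3", "GFF3")

    dataset_bp = sum(len(c.seq) for c in clones)
    summary = ann.summarize_composition(resolved, dataset_bp=dataset_bp)
    summary.table.round(2).to_csv(RESULTS / "04_composition.tsv", sep="\t", index=False)

    print(f"{len(hits)} hits -> {len(resolved)} disjoint annotations")
    print(
        f"repetitive: {summary.total_repetitive_bp:,} of {dataset_bp:,} bp "
        f"({summary.pct_repetitive_of_dataset:.2f}%)"
    )
    print(summary.table.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
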