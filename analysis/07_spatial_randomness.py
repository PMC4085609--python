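"""07 - Spatial randomness of the repeat landscape.

Bins each sufficiently contiguous survey clone (>= 50 kb ungapped) into
5-kb windows, binarizes repeat occupancy at 50%, and applies the
Wald-Wolfowitz runs test per clone to ask whether repetitive and
repeat-poor windows are interleaved at random or spatially clustered.
Occupancy comes from the planted (ground-truth) annotations, resolved
to a disjoint set.

Run after 01: python analysis/07_spatial_randomness.py
"""

from pathlib import Path

from repeatscape import annotation as ann
from repeatscape import spatial
from repeatscape.io import read_annotations, read_fasta

SCRATCH = Path("scratch/data/survey")
RESULTS = Path("results")


def main() -> None:
    clones = read_fasta(SCRATCH / "clones.fasta")
    truth = read_annotations(SCRATCH / "truth.gff3")
    resolved = ann.resolve_overlaps(truth)

    keep = set(spatial.select_scaffolds(clones))
    series = [spatial.binarize(c, resolved) for c in clones if c.id in keep]
    report = spatial.randomness_report(series)
    report.round(4).to_csv(RESULTS / "07_runs_tests.tsv", sep="\t", index=False)

    n_nonrandom = int(report.nonrandom.sum())
    n_bonf = int((report.p_bonferroni < 0.05).sum())
    print(
        f"{len(series)} of {len(clones)} clones tested; "
        f"{n_nonrandom} non-random at alpha=0.05 "
        f"({n_bonf} after Bonferroni)"
    )
    print(report.head(10).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
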