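"""03 - De novo repeat discovery and clustering.

Interval-level discovery followed by single-linkage clustering assumes
each called interval is one repeat copy.  That holds when copies are
well separated, so this survey uses a sparser 12-clone simulation
(~30% planted density, 5 families) rather than the dense landscape
library from 01, where abutting copies concatenate into mixed intervals
(see docs/methods.md).

Writes the blastclust-style cluster report and family abundance curve
to results/, and the family consensi plus per-family member sequences
to scratch/ for the annotation (04) and dating (06) steps.

Run from the repository root: python analysis/03_repeat_discovery.py
"""

from pathlib import Path

from repeatscape import discovery, kmers
from repeatscape import simulate as sim
from repeatscape.io import SequenceRecord, write_fasta

SCRATCH = Path("scratch/data/sparse")
RESULTS = Path("results")


def sparse_config() -> sim.SimulationConfig:
    families = [
        sim.FamilySpec("LTRfamA", "Ty1-Copia", 3000, 25, 1.5e6, True, 500, 2000, 1.0),
        sim.FamilySpec("LTRfamB", "Ty3-Gypsy", 2600, 25, 0.8e6, True, 400, 1800, 1.0),
        sim.FamilySpec("RTfam", "ClassI-unclassified", 2200, 25, 2.0e6, weight=1.0),
        sim.FamilySpec("NOVfam", "novel", 1600, 25, 1.2e6, weight=1.0),
        sim.FamilySpec("DNAfam", "DNA-nonMITE", 1000, 25, 0.6e6, weight=1.0),
    ]
    return sim.SimulationConfig(
        n_clones=12,
        clone_length_range=(60_000, 90_000),
        class_targets=[sim.ClassTarget("low", 0.25, 0.35, 12)],
        families=families,
        nesting_probability=0.0,
        seed=777,
    )


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = sparse_config()
    clones, _truth = sim.build_synthetic_clones(config, outdir=SCRATCH)

    index = kmers.build_kmer_index(clones, kmers.DEFAULT_K)
    copies = discovery.find_repeat_intervals(
        clones, index, kmers.DEFAULT_FREQ_THRESHOLD
    )
    families, report = discovery.cluster_copies(copies, build_consensi=True)

    report.to_frame().to_csv(RESULTS / "03_cluster_report.tsv", sep="\t", index=False)
    curve = discovery.family_abundance_curve(families)
    curve.table.round(4).to_csv(
        RESULTS / "03_family_abundance.tsv", sep="\t", index=False
    )

    write_fasta(
        [
            SequenceRecord(
                f.family_id,
                f.consensus,
                description=f"class=novel family={f.family_id}",
            )
            for f in families
        ],
        SCRATCH / "family_consensi.fasta",
    )
    members_dir = SCRATCH / "families"
    members_dir.mkdir(exist_ok=True)
    for f in families:
        write_fasta(
            [SequenceRecord(m.copy_id, m.seq) for m in f.members],
            members_dir / f"{f.family_id}.fasta",
        )

    print(f"{len(copies)} repeat intervals -> {len(families)} families")
    print(report.to_frame().to_string(index=False))
    print(
        f"families covering 50% of repeat bp: {curve.families_for_50pct_bp}; "
        f"of copies: {curve.families_for_50pct_copies}"
    )


if __name__ == "__main__":
    main()
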