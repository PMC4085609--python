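"""End-to-end orchestration: simulate -> landscape -> discovery ->
annotation -> SSR -> dating -> spatial stats, plus ground-truth recovery
metrics.

The pipeline is deterministic under its configuration seed: one
top-level seed drives the simulator, and every analysis stage is
deterministic given its inputs.  All stage outputs are written as TSV /
GFF3 / FASTA into the chosen output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from repeatscape import annotation as ann
from repeatscape import dating, discovery, kmers, spatial, ssr
from repeatscape import simulate as sim
from repeatscape.io import (
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
    write_annotations,
    write_fasta,
)

logger = logging.getLogger("repeatscape")


@dataclass
class PipelineConfig:
    """Every tunable of the full analysis in one place."""

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    k: int = kmers.DEFAULT_K
    freq_threshold: int = kmers.DEFAULT_FREQ_THRESHOLD
    min_len: int = discovery.DEFAULT_MIN_LEN
    merge_gap: int = discovery.DEFAULT_MERGE_GAP
    min_copies: int = discovery.DEFAULT_MIN_COPIES
    identity_threshold: float = discovery.DEFAULT_IDENTITY
    coverage_threshold: float = discovery.DEFAULT_COVERAGE
    mask_min_identity: float = 0.80
    bin_size: int = spatial.DEFAULT_BIN_SIZE
    min_contiguous: int = spatial.DEFAULT_MIN_CONTIGUOUS
    binarize_threshold: float = spatial.DEFAULT_BINARIZE_THRESHOLD
    alpha: float = 0.05
    genome_size: float = ann.DEFAULT_GENOME_SIZE
    # overlap-contest scores for non-homology annotations: SSRs outrank
    # homology hits and low-complexity tracts on contested bases
    ssr_score: float = 1.10
    low_complexity_score: float = 1.05


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's outputs."""

    clones: list[SequenceRecord]
    truth: sim.GroundTruth
    index: kmers.KmerIndex
    profiles: list[kmers.CloneProfile]
    copies: list[discovery.RepeatCopy]
    families: list[discovery.RepeatFamily]
    cluster_report: discovery.ClusterReport
    annotations: list[RepeatAnnotation]
    resolved: list[RepeatAnnotation]
    composition: ann.CompositionSummary
    density: ann.DensityReport
    ssr_loci: list[ssr.SSRLocus]
    ssr_table: pd.DataFrame
    family_ages: list[dating.FamilyAge]
    runs_report: pd.DataFrame
    family_labels: dict[str, tuple[str, str]]  # family_id -> (class, truth family)


def _label_families(
    families: list[discovery.RepeatFamily],
    reference: dict[str, tuple[str, str]],
    min_identity: float,
) -> dict[str, tuple[str, str]]:
    """Assign a repeat class to each de novo family by homology.

    ``reference`` maps reference sequence -> (class, reference family
    id); consensi with no qualifying hit are labeled "novel" (the de
    novo repeat is repetitive but matches nothing known).
    """
    labels: dict[str, tuple[str, str]] = {}
    for fam in families:
        best = None
        for ref_seq, (klass, ref_id) in reference.items():
            q, t = (
                (fam.consensus, ref_seq)
                if len(fam.consensus) <= len(ref_seq)
                else (ref_seq, fam.consensus)
            )
            max_dist = int(len(q) * (1 - min_identity))
            res = edlib.align(q, t, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] == -1:
                continue
            ident = 1.0 - res["editDistance"] / len(q)
            if ident >= min_identity and (best is None or ident > best[0]):
                best = (ident, klass, ref_id)
        labels[fam.family_id] = (best[1], best[2]) if best else ("novel", "")
    return labels


def run_full(
    config: PipelineConfig,
    outdir: str | Path,
    reference_library: dict[str, tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run every stage on a freshly simulated clone set.

    ``reference_library`` (sequence -> (class, family id)) plays the role
    of the external labeled repeat database used to annotate de novo
    repeats; by default the simulator's ancestral consensi are used,
    which emulates annotating against a curated repeat library.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage simulate: %d clones", config.simulation.n_clones)
    clones, truth = sim.build_synthetic_clones(config.simulation, outdir / "truth")

    logger.info("stage kmer landscape: k=%d", config.k)
    index = kmers.build_kmer_index(clones, config.k)
    profiles = kmers.profile_clones(clones, index, config.freq_threshold)
    pd.DataFrame(
        {
            "clone_id": [p.clone_id for p in profiles],
            "repetitive_fraction": [p.repetitive_fraction for p in profiles],
            "clone_class": [p.clone_class for p in profiles],
        }
    ).to_csv(outdir / "clone_classes.tsv", sep="\t", index=False)

    logger.info("stage discovery")
    copies = discovery.find_repeat_intervals(
        clones, index, config.freq_threshold, config.min_len, config.merge_gap
    )
    families, report = discovery.cluster_copies(
        copies,
        config.identity_threshold,
        config.coverage_threshold,
        config.min_copies,
    )
    report.to_frame().to_csv(outdir / "cluster_report.tsv", sep="\t", index=False)

    if reference_library is None:
        reference_library = {
            seq: (next(f.repeat_class for f in config.simulation.families if f.family_id == fid), fid)
            for fid, seq in truth.family_ancestors.items()
        }
    family_labels = _label_families(families, reference_library, config.mask_min_identity)
    write_fasta(
        [
            SequenceRecord(
                f.family_id,
                f.consensus,
                description=(
                    f"class={family_labels[f.family_id][0]} "
                    f"copy_number={f.copy_number} total_bp={f.total_bp}"
                ),
            )
            for f in families
        ],
        outdir / "family_consensi.fasta",
    )

    logger.info("stage homology masking")
    library = [
        SequenceRecord(
            f.family_id,
            f.consensus,
            description=f"class={family_labels[f.family_id][0]} family={f.family_id}",
        )
        for f in families
    ]
    annotations = ann.mask_with_library(
        clones, library, config.mask_min_identity, config.min_len
    )

    logger.info("stage SSR / low-complexity")
    ssr_loci: list[ssr.SSRLocus] = []
    lc_regions = []
    for c in clones:
        ssr_loci.extend(ssr.find_ssrs(c))
        lc_regions.extend(ssr.find_low_complexity(c))
    ssr_table = ssr.ssr_summary(ssr_loci)
    ssr_table.to_csv(outdir / "ssr_motifs.tsv", sep="\t", index=False)
    for locus in ssr_loci:
        annotations.append(
            RepeatAnnotation(
                locus.interval, "SSR", f"SSR_{locus.canonical_motif}", config.ssr_score
            )
        )
    for region in lc_regions:
        annotations.append(
            RepeatAnnotation(
                region.interval, "low_complexity", "LC", config.low_complexity_score
            )
        )

    logger.info("stage overlap resolution + composition")
    resolved = ann.resolve_overlaps(annotations)
    dataset_bp = sum(len(c.seq) for c in clones)
    composition = ann.summarize_composition(resolved, dataset_bp, config.genome_size)
    composition.table.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    write_annotations(resolved, outdir / "annotations.gff3", "GFF3")

    # dense/poor windows from the k-mer landscape for the density report
    regions: list[tuple[GenomicInterval, str]] = []
    for c in clones:
        mask = kmers.repetitive_coverage_mask(c.seq, index, config.freq_threshold)
        for s in range(0, len(c.seq), config.bin_size):
            e = min(s + config.bin_size, len(c.seq))
            label = "dense" if mask[s:e].mean() >= 0.5 else "poor"
            regions.append((GenomicInterval(c.id, s, e), label))
    density = ann.repeat_density(resolved, regions)

    logger.info("stage dating")
    family_ages = []
    for f in families:
        if f.copy_number >= 2:
            try:
                family_ages.append(
                    dating.family_consensus_age(
                        [m.seq for m in f.members],
                        f.consensus,
                        config.simulation.rate,
                        f.family_id,
                    )
                )
            except (dating.SaturationError, ValueError):
                continue
    pd.DataFrame(
        {
            "family_id": [fa.family_id for fa in family_ages],
            "k": [fa.k for fa in family_ages],
            "age_years": [fa.age_years for fa in family_ages],
            "n_members": [fa.n_members for fa in family_ages],
        }
    ).to_csv(outdir / "family_ages.tsv", sep="\t", index=False)

    logger.info("stage spatial statistics")
    selected = spatial.select_scaffolds(clones, config.min_contiguous)
    series = [
        spatial.binarize(c, resolved, config.bin_size, config.binarize_threshold)
        for c in clones
        if c.id in selected
    ]
    runs_report = spatial.randomness_report(series, config.alpha)
    runs_report.to_csv(outdir / "runs_tests.tsv", sep="\t", index=False)

    return PipelineResult(
        clones=clones,
        truth=truth,
        index=index,
        profiles=profiles,
        copies=copies,
        families=families,
        cluster_report=report,
        annotations=annotations,
        resolved=resolved,
        composition=composition,
        density=density,
        ssr_loci=ssr_loci,
        ssr_table=ssr_table,
        family_ages=family_ages,
        runs_report=runs_report,
        family_labels=family_labels,
    )


def recovery_report(result: PipelineResult, config: PipelineConfig) -> dict:
    """Compare every recovered quantity with the planted ground truth.

    Returns a dict with: the clone-class confusion matrix, planted vs
    recovered family counts and family recall, base-level
    precision/recall of discovered repeat intervals, per-family age bias
    against the planted ages, and SSR recall/precision (evaluated at the
    planted minimum unit counts, below which chance arrays in background
    sequence are expected).
    """
    truth = result.truth

    # clone-class confusion
    measured = {p.clone_id: p.clone_class for p in result.profiles}
    conf = (
        truth.clones.assign(measured=truth.clones["clone_id"].map(measured))
        .groupby(["clone_class", "measured"])
        .size()
        .unstack(fill_value=0)
    )

    # family recovery: planted family matched when a de novo family labels to it
    matched_truth = {
        ref_id for (_k, ref_id) in result.family_labels.values() if ref_id
    }
    planted_counts = truth.copies.groupby("family_id").size()
    datable = set(planted_counts[planted_counts >= config.min_copies].index)
    family_recall = (
        len(matched_truth & datable) / len(datable) if datable else float("nan")
    )

    # base-level precision/recall of discovered repeat intervals vs planted TEs
    def base_masks() -> tuple[int, int, int]:
        tp = fp = fn = 0
        lengths = {c.id: len(c.seq) for c in result.clones}
        truth_by_clone: dict[str, list[tuple[int, int]]] = {}
        for a in truth.annotations:
            if a.repeat_class not in ("SSR", "low_complexity"):
                truth_by_clone.setdefault(a.interval.scaffold_id, []).append(
                    (a.interval.start, a.interval.end)
                )
        found_by_clone: dict[str, list[tuple[int, int]]] = {}
        for c in result.copies:
            found_by_clone.setdefault(c.interval.scaffold_id, []).append(
                (c.interval.start, c.interval.end)
            )
        for cid, L in lengths.items():
            t = np.zeros(L, dtype=bool)
            f = np.zeros(L, dtype=bool)
            for s, e in truth_by_clone.get(cid, []):
                t[s:e] = True
            for s, e in found_by_clone.get(cid, []):
                f[s:e] = True
            tp += int((t & f).sum())
            fp += int((~t & f).sum())
            fn += int((t & ~f).sum())
        return tp, fp, fn

    tp, fp, fn = base_masks()
    base_precision = tp / (tp + fp) if tp + fp else float("nan")
    base_recall = tp / (tp + fn) if tp + fn else float("nan")

    # age recovery for de novo families matched to planted families
    rows = []
    for fa in result.family_ages:
        _klass, ref = result.family_labels.get(fa.family_id, ("", ""))
        if ref and ref in truth.family_ages:
            rows.append(
                {
                    "family_id": fa.family_id,
                    "ref_family": ref,
                    "age_est": fa.age_years,
                    "age_true": truth.family_ages[ref],
                }
            )
    ages = pd.DataFrame(rows)
    if not ages.empty:
        err = ages["age_est"] - ages["age_true"]
        age_bias = float(err.mean())
        age_rmse = float(np.sqrt((err**2).mean()))
        rel = err / ages["age_true"].replace(0, np.nan)
        age_rel_rmse = float(np.sqrt((rel.dropna() ** 2).mean()))
    else:
        age_bias = age_rmse = age_rel_rmse = float("nan")

    # SSR recovery at the planted minimum unit counts
    min_planted = {
        s.motif: s.min_units for s in config.simulation.ssr_specs
    }
    truth_ssrs = [
        a
        for a in truth.annotations
        if a.repeat_class == "SSR"
    ]
    found = [
        L
        for L in result.ssr_loci
        if L.n_units >= min_planted.get(L.motif, min(min_planted.values(), default=8))
    ]
    t_hit = 0
    for a in truth_ssrs:
        if any(
            L.interval.overlaps(a.interval)
            and min(L.interval.end, a.interval.end)
            - max(L.interval.start, a.interval.start)
            >= 0.9 * len(a.interval)
            for L in found
        ):
            t_hit += 1
    f_hit = sum(
        1
        for L in found
        if any(L.interval.overlaps(a.interval) for a in truth_ssrs)
    )
    ssr_recall = t_hit / len(truth_ssrs) if truth_ssrs else float("nan")
    ssr_precision = f_hit / len(found) if found else float("nan")

    return {
        "clone_class_confusion": conf,
        "n_planted_families": int(len(datable)),
        "n_recovered_families": len(result.families),
        "family_recall": family_recall,
        "base_precision": base_precision,
        "base_recall": base_recall,
        "age_bias_years": age_bias,
        "age_rmse_years": age_rmse,
        "age_relative_rmse": age_rel_rmse,
        "ssr_recall": ssr_recall,
        "ssr_precision": ssr_precision,
    }
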