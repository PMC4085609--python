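"""Clone-scale sequence simulator with planted repeat structure.

Generates 50-200 kb "clone" sequences consisting of unique background
sequence into which transposable-element copies, microsatellites and
AT-rich low-complexity tracts are planted, with full ground truth for
every planted feature.  TE copies are amplified from a random ancestral
consensus and diverged under a forward Kimura 2-parameter (K2P)
substitution process at a configurable rate (default r = 2.0e-8
substitutions/site/year), so the dating estimators downstream can be
checked against the planted ages.  LTR retrotransposon elements carry two
long terminal repeats that are identical at "insertion" and diverge
independently, giving an expected pairwise LTR divergence of 2*r*T.

No indels are simulated: the dating formulas address substitutions only,
and substitution-only copies keep alignments trivial and the estimators
exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from repeatscape.io import (
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
    write_annotations,
    write_fasta,
)

#: Default substitution rate for LTR retrotransposons, subs/site/year.
DEFAULT_RATE = 2.0e-8

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i


class SimulationError(ValueError):
    """Raised for invalid simulation configurations or inputs."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as a uint8 array (A=0,C=1,G=2,T=3,N=4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise SimulationError(f"invalid alphabet symbols {bad}")
    return arr


def decode_sequence(arr: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return _BASES[arr].tobytes().decode("ascii")


def _mutate_array(
    arr: np.ndarray, d: float, ti_tv_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """K2P forward simulation: per-site substitution count ~ Poisson(d).

    Each substitution event is a transition (A<->G, C<->T; ``b ^ 2`` in
    the 2-bit encoding) with probability R/(R+1) where R is the
    transition/transversion ratio, otherwise one of the two transversions
    chosen uniformly.  Multiple hits per site are allowed; N sites are
    left untouched.
    """
    if d < 0:
        raise SimulationError("divergence must be >= 0")
    out = arr.copy()
    if d == 0:
        return out
    p_ti = ti_tv_ratio / (ti_tv_ratio + 1.0)
    counts = rng.poisson(d, arr.size)
    counts[arr >= 4] = 0  # N sites never mutate

    one = np.where(counts == 1)[0]
    if one.size:
        b = arr[one]
        is_ti = rng.random(one.size) < p_ti
        tv_pick = rng.random(one.size) < 0.5
        out[one] = np.where(is_ti, b ^ 2, np.where(tv_pick, b ^ 1, b ^ 3))

    multi = np.where(counts >= 2)[0]
    for i in multi:
        b = int(arr[i])
        for _ in range(counts[i]):
            if rng.random() < p_ti:
                b ^= 2
            else:
                b ^= 1 if rng.random() < 0.5 else 3
        out[i] = b
    return out


def mutate_sequence(
    seq: str,
    age_years: float,
    rate: float = DEFAULT_RATE,
    ti_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Diverge ``seq`` for ``age_years`` under the K2P process.

    Expected substitutions per site is ``rate * age_years``; transitions
    and transversions occur in the ratio ``ti_tv_ratio``.  Deterministic
    under a fixed seed.
    """
    if age_years < 0 or rate < 0:
        raise SimulationError("age and rate must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return decode_sequence(
        _mutate_array(encode_sequence(seq), rate * age_years, ti_tv_ratio, rng)
    )


def random_background(
    length: int, gc: float = 0.39, rng: np.random.Generator | None = None
) -> np.ndarray:
    """I.i.d. background sequence with the given GC fraction (encoded)."""
    rng = rng or np.random.default_rng(0)
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at]).astype(np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one TE family to amplify from a random ancestor."""

    family_id: str
    repeat_class: str
    ancestor_length: int
    n_copies: int = 10
    age_years: float = 1.0e6
    is_ltr: bool = False
    ltr_length: int = 0
    internal_length: int = 0
    weight: float = 1.0  # relative planting abundance in clone building

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise SimulationError(f"{self.family_id}: n_copies must be >= 1")
        if self.age_years < 0:
            raise SimulationError(f"{self.family_id}: age must be >= 0")
        if self.is_ltr:
            if self.ltr_length < 20:
                raise SimulationError(
                    f"{self.family_id}: LTR length {self.ltr_length} < 20 bp "
                    "is too short to date"
                )
            if self.ancestor_length != 2 * self.ltr_length + self.internal_length:
                raise SimulationError(
                    f"{self.family_id}: element length must equal "
                    "2*ltr_length + internal_length"
                )
        elif self.ancestor_length < 1:
            raise SimulationError(f"{self.family_id}: ancestor_length must be >= 1")


@dataclass(frozen=True)
class SSRSpec:
    """Planting rule for perfect microsatellite arrays."""

    motif: str
    min_units: int = 8
    max_units: int = 25
    per_clone: float = 1.0  # expected number planted per clone


@dataclass(frozen=True)
class LowComplexitySpec:
    """Planting rule for AT-rich low-complexity tracts."""

    min_len: int = 40
    max_len: int = 90
    at_fraction: float = 0.95
    per_clone: float = 1.0


@dataclass(frozen=True)
class ClassTarget:
    """Number of clones to generate in one repetitive-fraction band."""

    label: str  # low / mid / high
    fraction_low: float
    fraction_high: float
    n_clones: int


def default_families() -> list[FamilySpec]:
    """Default family panel: LTR-RT dominated, ages 0.5-2.7 MY.

    Abundance weights roughly follow the composition of a repeat-rich
    plant genome survey (Copia + Gypsy majority, unclassified and novel
    Class I abundant, Class II and LINE/SINE minor).
    """
    return [
        FamilySpec("HaCopia1", "Ty1-Copia", 4200, 25, 1.8e6, True, 600, 3000, 0.10),
        FamilySpec("HaCopia2", "Ty1-Copia", 2400, 30, 0.9e6, True, 400, 1600, 0.08),
        FamilySpec("HaGypsy1", "Ty3-Gypsy", 5600, 25, 2.7e6, True, 900, 3800, 0.12),
        FamilySpec("HaGypsy2", "Ty3-Gypsy", 3200, 30, 1.2e6, True, 500, 2200, 0.10),
        FamilySpec("HaRT1", "ClassI-unclassified", 2800, 40, 2.2e6, weight=0.18),
        FamilySpec("HaRTnov1", "ClassI-novel", 2400, 40, 1.5e6, weight=0.20),
        FamilySpec("HaLINE1", "LINE_SINE", 1800, 10, 2.0e6, weight=0.02),
        FamilySpec("HaDNA1", "DNA-nonMITE", 900, 10, 1.0e6, weight=0.02),
        FamilySpec("HaMITE1", "MITE", 350, 15, 0.5e6, weight=0.02),
        FamilySpec("HaNov1", "novel", 1500, 30, 2.0e6, weight=0.14),
        FamilySpec("HaUnc1", "unclassified", 1200, 30, 1.6e6, weight=0.12),
    ]


def default_class_targets() -> list[ClassTarget]:
    """83% high / 15% mid / 2% low split over 96 clones."""
    return [
        ClassTarget("high", 0.75, 0.95, 80),
        ClassTarget("mid", 0.50, 0.65, 14),
        ClassTarget("low", 0.10, 0.30, 2),
    ]


def default_ssr_specs() -> list[SSRSpec]:
    return [
        SSRSpec("AT", 8, 20, 1.0),
        SSRSpec("TGG", 6, 15, 1.5),
        SSRSpec("GAA", 5, 12, 0.8),
        SSRSpec("AAAT", 5, 10, 0.7),
    ]


@dataclass
class SimulationConfig:
    """Full configuration of a synthetic clone set."""

    n_clones: int = 96
    clone_length_range: tuple[int, int] = (50_000, 200_000)
    rate: float = DEFAULT_RATE
    ti_tv_ratio: float = 2.0
    gc_background: float = 0.39
    class_targets: list[ClassTarget] = field(default_factory=default_class_targets)
    families: list[FamilySpec] = field(default_factory=default_families)
    ssr_specs: list[SSRSpec] = field(default_factory=default_ssr_specs)
    low_complexity_specs: list[LowComplexitySpec] = field(
        default_factory=lambda: [LowComplexitySpec()]
    )
    nesting_probability: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise SimulationError("n_clones must be >= 1")
        if self.rate <= 0 or self.ti_tv_ratio <= 0:
            raise SimulationError("rate and ti_tv_ratio must be > 0")
        if not 0 <= self.nesting_probability <= 1:
            raise SimulationError("nesting_probability must be in [0,1]")
        for t in self.class_targets:
            if not (0 <= t.fraction_low <= t.fraction_high <= 1):
                raise SimulationError(f"invalid fraction band for class {t.label}")
        if sum(t.n_clones for t in self.class_targets) != self.n_clones:
            raise SimulationError(
                "class target clone counts must sum to n_clones"
            )


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    """Echo a configuration to a YAML file (round-trips via from_yaml)."""
    doc = {
        "n_clones": config.n_clones,
        "clone_length_range": list(config.clone_length_range),
        "rate": config.rate,
        "ti_tv_ratio": config.ti_tv_ratio,
        "gc_background": config.gc_background,
        "nesting_probability": config.nesting_probability,
        "seed": config.seed,
        "class_targets": [vars(t).copy() for t in config.class_targets],
        "families": [vars(f).copy() for f in config.families],
        "ssr_specs": [vars(s).copy() for s in config.ssr_specs],
        "low_complexity_specs": [vars(s).copy() for s in config.low_complexity_specs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimulationConfig(
        n_clones=doc["n_clones"],
        clone_length_range=tuple(doc["clone_length_range"]),
        rate=doc["rate"],
        ti_tv_ratio=doc["ti_tv_ratio"],
        gc_background=doc["gc_background"],
        class_targets=[ClassTarget(**t) for t in doc["class_targets"]],
        families=[FamilySpec(**f) for f in doc["families"]],
        ssr_specs=[SSRSpec(**s) for s in doc["ssr_specs"]],
        low_complexity_specs=[
            LowComplexitySpec(**s) for s in doc["low_complexity_specs"]
        ],
        nesting_probability=doc["nesting_probability"],
        seed=doc["seed"],
    )


def simulate_ltr_element(
    spec: FamilySpec,
    rate: float = DEFAULT_RATE,
    ti_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str, str, dict]:
    """Simulate one LTR retrotransposon of age ``spec.age_years``.

    Both LTRs descend from a single ancestral LTR and diverge
    independently for the element's age, so the expected pairwise LTR
    divergence is ``2 * rate * age``.  Returns (element sequence, 5' LTR,
    3' LTR, truth dict).
    """
    if not spec.is_ltr:
        raise SimulationError(f"{spec.family_id} is not an LTR family")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = rate * spec.age_years
    anc_ltr = random_background(spec.ltr_length, rng=rng)
    internal = random_background(spec.internal_length, rng=rng)
    ltr5 = _mutate_array(anc_ltr, d, ti_tv_ratio, rng)
    ltr3 = _mutate_array(anc_ltr, d, ti_tv_ratio, rng)
    internal_m = _mutate_array(internal, d, ti_tv_ratio, rng)
    element = np.concatenate([ltr5, internal_m, ltr3])
    truth = {
        "family_id": spec.family_id,
        "age_years": spec.age_years,
        "expected_ltr_divergence": 2 * d,
        "element_length": 2 * spec.ltr_length + spec.internal_length,
    }
    return (
        decode_sequence(element),
        decode_sequence(ltr5),
        decode_sequence(ltr3),
        truth,
    )


def simulate_family(
    spec: FamilySpec,
    rate: float = DEFAULT_RATE,
    ti_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SequenceRecord], dict]:
    """Amplify ``spec.n_copies`` copies from one random ancestor.

    Each copy is mutated independently for the family age, so the
    expected per-copy divergence to the ancestor is ``rate * age``.
    Returns (copies, truth dict incl. the ancestor sequence).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ancestor = random_background(spec.ancestor_length, rng=rng)
    d = rate * spec.age_years
    copies = [
        SequenceRecord(
            id=f"{spec.family_id}:{i}",
            seq=decode_sequence(_mutate_array(ancestor, d, ti_tv_ratio, rng)),
        )
        for i in range(spec.n_copies)
    ]
    truth = {
        "family_id": spec.family_id,
        "ancestor": decode_sequence(ancestor),
        "age_years": spec.age_years,
        "expected_divergence": d,
    }
    return copies, truth


@dataclass
class GroundTruth:
    """Everything planted: per-copy annotations, divergences, family ages,
    per-clone repetitive fractions and class labels."""

    annotations: list[RepeatAnnotation]
    copies: pd.DataFrame  # copy_id, clone_id, family_id, true_divergence, true_age
    clones: pd.DataFrame  # clone_id, length, target_fraction, realized_fraction, clone_class
    family_ages: dict[str, float]
    family_ancestors: dict[str, str]

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotations(self.annotations, outdir / "truth.gff3", "GFF3")
        self.copies.to_csv(outdir / "truth_copies.tsv", sep="\t", index=False)
        self.clones.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
        fam = pd.DataFrame(
            {
                "family_id": list(self.family_ages),
                "true_age": [self.family_ages[f] for f in self.family_ages],
            }
        )
        fam.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)
        write_fasta(
            [
                SequenceRecord(fid, seq)
                for fid, seq in sorted(self.family_ancestors.items())
            ],
            outdir / "truth_ancestors.fasta",
        )


@dataclass
class _Segment:
    seq: np.ndarray
    copy_id: str | None  # None = background
    family_id: str | None = None
    repeat_class: str | None = None
    nestable: bool = False


def _plant_ssr_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[_Segment]:
    """Draw the SSR and low-complexity segments for one clone."""
    segs: list[_Segment] = []
    n = 0
    for s in config.ssr_specs:
        for _ in range(rng.poisson(s.per_clone)):
            units = int(rng.integers(s.min_units, s.max_units + 1))
            segs.append(
                _Segment(
                    encode_sequence(s.motif * units),
                    copy_id=f"ssr{n}",
                    family_id=f"SSR_{s.motif}",
                    repeat_class="SSR",
                )
            )
            n += 1
    for s in config.low_complexity_specs:
        for _ in range(rng.poisson(s.per_clone)):
            length = int(rng.integers(s.min_len, s.max_len + 1))
            at = s.at_fraction
            arr = rng.choice(
                4, size=length, p=[at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
            ).astype(np.uint8)
            segs.append(
                _Segment(
                    arr,
                    copy_id=f"lc{n}",
                    family_id="LC_AT",
                    repeat_class="low_complexity",
                )
            )
            n += 1
    return segs


def build_synthetic_clones(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate the full clone set with ground truth.

    Each clone draws a length and a target repetitive fraction from its
    class band; TE copies are planted (uniformly at random in background,
    or nested inside a previously placed element with probability
    ``nesting_probability``) until the planted repeat bp matches the
    target within +-0.03 of clone length (the last copy is truncated to
    land on the budget).  If ``outdir`` is given, the clone FASTA and all
    truth files are written there.
    """
    rng = np.random.default_rng(config.seed)
    d_by_family = {f.family_id: config.rate * f.age_years for f in config.families}
    weights = np.array([f.weight for f in config.families], dtype=float)
    weights /= weights.sum()

    # ancestral consensus per family, drawn once
    ancestors: dict[str, np.ndarray] = {}
    anc_parts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in config.families:
        if f.is_ltr:
            ltr = random_background(f.ltr_length, config.gc_background, rng)
            internal = random_background(f.internal_length, config.gc_background, rng)
            ancestors[f.family_id] = np.concatenate([ltr, internal, ltr])
            anc_parts[f.family_id] = (ltr, internal)
        else:
            ancestors[f.family_id] = random_background(
                f.ancestor_length, config.gc_background, rng
            )

    # expand per-clone (class label, target fraction) assignments
    per_clone: list[tuple[str, float]] = []
    for t in config.class_targets:
        for _ in range(t.n_clones):
            per_clone.append(
                (t.label, float(rng.uniform(t.fraction_low, t.fraction_high)))
            )

    clones: list[SequenceRecord] = []
    annotations: list[RepeatAnnotation] = []
    copy_rows: list[dict] = []
    clone_rows: list[dict] = []

    for ci, (label, target) in enumerate(per_clone):
        clone_id = f"clone{ci:03d}"
        length = int(rng.integers(*config.clone_length_range))
        repeat_budget = int(round(target * length))

        extra = _plant_ssr_segments(config, rng)
        extra_bp = sum(s.seq.size for s in extra)
        te_budget = repeat_budget - extra_bp
        if te_budget < 0:
            extra, extra_bp, te_budget = [], 0, repeat_budget

        # draw TE copies until the budget is met; truncate the last copy
        te_segments: list[_Segment] = []
        planted = 0
        copy_n = 0
        while planted < te_budget:
            fi = rng.choice(len(config.families), p=weights)
            fam = config.families[fi]
            copy = _mutate_array(
                ancestors[fam.family_id],
                d_by_family[fam.family_id],
                config.ti_tv_ratio,
                rng,
            )
            remaining = te_budget - planted
            if copy.size > remaining:
                if remaining < 50:  # too short to bother; budget met to +-0.03
                    break
                copy = copy[:remaining]
            cid = f"{clone_id}:{fam.family_id}:{copy_n}"
            te_segments.append(
                _Segment(copy, cid, fam.family_id, fam.repeat_class, nestable=True)
            )
            planted += copy.size
            copy_n += 1
            copy_rows.append(
                {
                    "copy_id": cid,
                    "clone_id": clone_id,
                    "family_id": fam.family_id,
                    "repeat_class": fam.repeat_class,
                    "length": int(copy.size),
                    "true_divergence": d_by_family[fam.family_id],
                    "true_age": fam.age_years,
                }
            )

        background_len = length - planted - extra_bp
        if background_len < 0:
            raise SimulationError(
                f"target fraction {target:.2f} infeasible for {clone_id} "
                f"(length {length})"
            )

        # assemble: insert each repeat segment into a growing segment list
        segments: list[_Segment] = [
            _Segment(
                random_background(background_len, config.gc_background, rng), None
            )
        ]
        for seg in te_segments + extra:
            element_hosts = [
                j
                for j, s in enumerate(segments)
                if s.nestable and s.seq.size >= 40
            ]
            nest = (
                seg.nestable
                and element_hosts
                and rng.random() < config.nesting_probability
            )
            if nest:
                j = int(rng.choice(element_hosts))
            else:
                bg = [j for j, s in enumerate(segments) if s.copy_id is None]
                sizes = np.array([segments[j].seq.size for j in bg], dtype=float)
                if sizes.sum() == 0:
                    j = bg[0]
                else:
                    j = int(rng.choice(bg, p=sizes / sizes.sum()))
            host = segments[j]
            cut = int(rng.integers(0, host.seq.size + 1)) if host.seq.size else 0
            left = replace(host, seq=host.seq[:cut])
            right = replace(host, seq=host.seq[cut:])
            new = [s for s in (left, seg, right) if s.seq.size > 0 or s is seg]
            segments[j : j + 1] = new

        # emit coordinates, merging contiguous fragments of the same copy
        parts = []
        pos = 0
        merged: list[tuple[int, int, _Segment]] = []
        for s in segments:
            if s.seq.size == 0:
                continue
            parts.append(s.seq)
            if s.copy_id is not None:
                merged.append((pos, pos + s.seq.size, s))
            pos += s.seq.size
        clone_arr = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        repeat_bp = 0
        for start, end, s in merged:
            repeat_bp += end - start
            annotations.append(
                RepeatAnnotation(
                    GenomicInterval(clone_id, start, end, "+"),
                    s.repeat_class,
                    s.family_id,
                    score=1.0,
                )
            )
        realized = repeat_bp / max(pos, 1)
        clone_rows.append(
            {
                "clone_id": clone_id,
                "length": pos,
                "target_fraction": target,
                "realized_fraction": realized,
                "clone_class": label,
            }
        )
        clones.append(SequenceRecord(clone_id, decode_sequence(clone_arr)))

    truth = GroundTruth(
        annotations=annotations,
        copies=pd.DataFrame(copy_rows),
        clones=pd.DataFrame(clone_rows),
        family_ages={f.family_id: f.age_years for f in config.families},
        family_ancestors={
            fid: decode_sequence(arr) for fid, arr in ancestors.items()
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(clones, outdir / "clones.fasta")
        truth.to_files(outdir)
        config_to_yaml(config, outdir / "config.yaml")
    return clones, truth
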