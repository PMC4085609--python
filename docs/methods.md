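# Methods

`repeatscape` is a desk-scale model of a BAC-based survey of a large,
repeat-rich plant genome (sunflower-like: ~3.6 Gb, predominantly
LTR-retrotransposon derived).  It simulates a clone library with known
repeat content and re-derives the standard survey statistics — k-mer
repeat landscape, de novo repeat families, composition tables, SSR
census, insertion dating, spatial randomness, and an RT-domain-style
phylogeny — so that every estimator can be scored against ground truth.

## Synthetic genome model (`repeatscape.simulate`)

- Background sequence is i.i.d. with GC = 0.39, matching a
  repeat-depleted plant genomic background.
- TE families are defined by an ancestral sequence (generated once per
  family), an age, and a superfamily class.  Copies are planted into
  clones until each clone's planted repeat fraction lands within ±3%
  of a target drawn from its class band (defaults: 80 clones in
  [0.75, 0.95], 14 in [0.50, 0.65], 2 in [0.10, 0.30]).  The last copy
  is truncated to land on the budget; with probability 0.10 a copy
  nests inside a previously placed element, mimicking TE-in-TE
  insertion.
- Divergence is simulated forward in time as Poisson(d) substitution
  events per site with d = r·T, r = 2·10⁻⁸ substitutions/site/year,
  and transition:transversion ratio κ = 2 (per-event transition
  probability κ/(κ+1)).  Multiple hits at a site are realized
  naturally, so the K2P correction is exercised, not assumed.
- LTR elements are built as LTR–internal–LTR with both LTRs copied
  identically at insertion and then diverging independently for the
  element's age: the pairwise LTR divergence is 2·r·T.
- Default family ages span 0.5–2.7 MY.  These are deliberately young:
  20-mer identity decays as e^(−20d), so families much older than ~3 MY
  shed most exact 20-mers and would degrade k-mer recall — a real
  phenomenon, but not one the class-recovery checks are meant to model.
  Old (14.4 MY) families are exercised directly in the dating analyses.

What the generator does not model: indels (substitution-only
divergence), solo LTRs and illegitimate recombination, segmental
duplication, gene space, and sequencing/assembly error.  Estimator
performance here is therefore an upper bound with respect to those
processes.

## K-mer landscape (`repeatscape.kmers`)

Canonical 20-mers (lexicographic min of forward and reverse-complement
encodings, base-4 integer codes) are counted over the whole clone set;
windows containing N are excluded.  A position is repetitive if any
20-mer spanning it occurs ≥ 4 times in the dataset (span projection via
a difference array).  Clones are classified by repetitive fraction:
low [0, 0.40), mid [0.40, 0.70), high [0.70, 1].  On the default
96-clone survey the measured confusion matrix against planted classes
is exactly diagonal (80/14/2).

## De novo discovery and clustering (`repeatscape.discovery`)

Maximal runs of repetitive positions (≥ 50 bp, gaps ≤ merge_gap
bridged) become candidate repeat copies.  Copies are clustered by
single linkage under blastclust-style semantics: two copies link when
an infix alignment (edlib, k-cutoff) shows ≥ 80% identity over ≥ 51%
of the shorter sequence; clusters with ≥ 5 members become families,
and a star-alignment majority consensus is built per family.

**Density limitation (measured).**  At the default ~80% planted repeat
density, copies abut, so discovered intervals concatenate copies of
*different* families; any such junction interval bridges two families
under match-over-the-shorter linkage, and single linkage then chains
essentially all families into one cluster (measured on the default
survey: 11 planted families collapse to one 3,212-member cluster,
family recall 0.09, even though base-level precision/recall of the
repeat mask stay at 0.998/0.995).  This is inherent to interval-level
clustering at high density, not a tuning issue: published surveys
cluster individually excised repeat sequences, not dense-survey
intervals.  Family-level recovery is therefore evaluated on a sparser
12-clone, ~30%-density survey where interval ≈ copy holds; there all
5 planted families are recovered (recall 1.0, base precision/recall
0.999/0.980).

## Annotation and composition (`repeatscape.annotation`)

Library masking is seed-and-extend homology search: shared 12-mers
seed diagonals (≥ 2 seeds), and a maximal-scoring segment
(+(1−t)/−t per match/mismatch at identity threshold t = 0.80) defines
each hit; both strands are searched.  Overlaps are resolved to a
disjoint annotation set by a score-ordered interval sweep
(score, then length, then lexicographic family id), which provably
matches per-base best-annotation assignment and preserves the covered
union.  Composition tables report bp, % of dataset, % of the
repetitive fraction, and a genome-wide extrapolation at 3.6 Gb.

## SSRs and low complexity (`repeatscape.ssr`)

Perfect tandem arrays of primitive 2–4 bp motifs (≥ 6/5/5 units)
are detected via period-equality runs; overlapping calls of different
period resolve to the longest locus.  Motifs are reported by canonical
class: the lexicographic minimum over all rotations of the motif and
its reverse complement (e.g. TGG, CCA, GGT, GTG, CAC, ACC → ACC).
AT-rich low-complexity tracts are windows with AT ≥ 0.90 over ≥ 30 bp,
trimmed to AT-consistent ends.

## Insertion dating (`repeatscape.dating`)

K2P distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) over unambiguous, ungapped
sites; saturation raises an error rather than returning NaN.
LTR-pair age is T = d/(2r); family age is the mean member-to-consensus
K2P distance k with T = k/r (one lineage separates each copy from the
ancestral element the consensus approximates).  Truncated members are
aligned to the consensus by infix alignment before site counting;
saturated members are excluded with a warning.

**Consensus shrinkage (measured).**  Against the *true* ancestor the
family estimator is essentially unbiased (50-copy, 14.4 MY family
dated at 14.37 MY, −0.2%).  A de novo majority consensus, however, is
built *from* the members and therefore sits slightly closer to them
than the ancestor does: main-cluster ages on the sparse survey land
4–14% low (e.g. planted 2.0 MY dated 1.76 MY), and small splinter
clusters of truncated copies can be far off (one 11-member splinter
dated 4.25 vs 2.0 MY), giving an overall relative RMSE of 0.33 across
all recovered clusters.

## Spatial statistics (`repeatscape.spatial`)

Clones with ≥ 50 kb of contiguous (N-free) sequence are cut into 5-kb
bins; a bin is repetitive if ≥ 50% of its bases are covered by the
resolved annotation; the trailing partial bin is kept if ≥ half a bin
wide.  The Wald–Wolfowitz runs test is applied per clone
(μ = 2n₁n₀/n + 1, σ² = 2n₁n₀(2n₁n₀−n)/(n²(n−1)), two-sided normal
p-value); constant series raise, and series with < 20 bins are flagged
approximate.

**Normal-approximation quality (measured).**  Type-I error is well
calibrated at survey scale: 0.0435 at α = 0.05 over 2,000 null
length-20 series.  At very small n the normal p-values are *not*
within 0.01 of exact permutation enumeration: the worst deviation over
all series with n₁+n₀ ≤ 12 is 0.68 (exact two-sided p = 1.0 vs normal
≈ 0.32 when R sits at the mean; 0.667 vs 0.221 at n₁=n₀=2, R=2), and
a continuity correction still leaves deviations ≥ 0.16.  This is an
inherent property of the approximation at tiny n; the `approximate`
flag exists for exactly this reason.  One validation test asserting
the 0.01 agreement is left failing rather than weakened
(`tests/test_acceptance.py::test_runs_test_exact_enumeration`).

## Phylogeny (`repeatscape.phylo`)

Poisson-corrected amino-acid distances (d = −ln(1−p), pairwise or
complete deletion) feed a from-scratch neighbor joining (Q criterion,
deterministic lexicographic tie-breaks, negative branch lengths
clamped to zero with the deficit transferred to the sister edge,
trifurcating root).  On exactly additive matrices NJ reproduces the
input patristic distances to machine precision (tested against
scikit-bio to 1e-9).  Bootstrap supports resample alignment columns
and score each internal bipartition of the full-data tree.

## Numerical choices

- Sequences are handled as NumPy uint8 code arrays; k-mer codes are
  uint64 Horner codes (exact for k ≤ 32).
- Alignment is edit-distance-based (edlib) rather than scored local
  alignment; for the substitution-dominated sequences generated here
  the two are equivalent, and alignment scoring parameters are
  deliberately not exposed.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; re-running any driver or the full
  pipeline with the same seed reproduces every output byte for byte.
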