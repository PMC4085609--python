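# repeatscape

Simulation-validated repeat-landscape analysis of a BAC survey of a
large, repeat-rich plant genome.

## The problem

Large plant genomes (sunflower-scale, ~3.6 Gb) are dominated by
LTR-retrotransposon-derived repeats.  Before whole-genome assembly,
their repeat landscape was surveyed from sequenced BAC clones: count
k-mers to map repetitive sequence, excise and cluster repeats into
families de novo, annotate and tabulate composition, census SSRs, date
retrotransposon insertions from LTR divergence, and test whether
repeats are spatially clustered along clones.  None of those estimators
can be validated on real data, because the truth is unknown.

`repeatscape` closes that loop: it generates a synthetic clone library
with fully known repeat content — family ancestors, insertion ages,
copy boundaries, SSR loci, per-clone repeat fractions — runs the same
survey analyses on it, and scores every stage against the planted
truth.  The model and its measured limitations are documented in
[docs/methods.md](docs/methods.md).

## The model in brief

- 96 clones of 50–200 kb; 80/14/2 clones targeted at high (0.75–0.95),
  mid (0.50–0.65) and low (0.10–0.30) repeat-fraction bands.
- 11 TE families (LTR elements with paired LTRs, non-LTR
  retroelements, DNA transposons) diverged by forward-simulated
  Poisson substitution at r = 2·10⁻⁸ subs/site/yr, κ = 2.
- Estimators: canonical 20-mer landscape (repetitive = spanned by a
  20-mer occurring ≥ 4×; classes at 40%/70%), interval discovery +
  blastclust-style single-linkage clustering (≥ 80% identity over
  ≥ 51% of the shorter; ≥ 5 copies), seed-and-extend homology
  annotation with per-base-exact overlap resolution, perfect-SSR
  detection with canonical motif classes, K2P dating (LTR pairs:
  T = d/2r; families: T = k/r), Wald–Wolfowitz runs tests, and
  Poisson-distance neighbor joining with bootstrap supports.

## Worked example

```python
from repeatscape import simulate as sim
from repeatscape import kmers

config = sim.SimulationConfig(seed=20140707)     # the default survey
clones, truth = sim.build_synthetic_clones(config)
index = kmers.build_kmer_index(clones, kmers.DEFAULT_K)
profiles = kmers.profile_clones(clones, index)
n_high = sum(p.clone_class == "high" for p in profiles)
print(len(clones), sum(len(c.seq) for c in clones), n_high)
```

prints `96 11974588 80` — 96 clones, 11,974,588 bp, 80 of 96 (83.3%)
classified highly repetitive, which exactly matches the planted
80/14/2 class design (the measured class confusion matrix is
diagonal).

Dating a simulated LTR element:

```python
from repeatscape import dating
spec = sim.FamilySpec("ex", "Ty1-Copia", 4000, age_years=2.7e6,
                      is_ltr=True, ltr_length=1500, internal_length=1000)
_, ltr5, ltr3, _ = sim.simulate_ltr_element(spec, seed=0)
print(round(dating.date_ltr_pair("ex", ltr5, ltr3).age_years / 1e6, 2))
```

prints `2.61` — one element's estimate of the true 2.7 MY age; across
500 such elements the mean estimate is 2.707 MY (SE 0.010).

## Layout

```
src/repeatscape/   library: simulate, kmers, discovery, annotation,
                   ssr, dating, spatial, phylo, pipeline, io
analysis/          numbered narrative drivers writing to results/
scripts/           acceptance.py: standalone validation report
results/           small committed tables produced by the drivers
tests/             unit, property and validation tests
docs/methods.md    model, assumptions, measured limitations
```
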