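# Methods

## Model

`svmix` treats local ancestry inference as supervised window
classification followed by probabilistic smoothing.

**Encoding.** Phased haplotypes over N shared biallelic SNPs are coded
±1: per column, the allele with frequency > 0.5 among the *ancestral*
(reference) haplotypes is the major allele (+1). Queries are encoded with
the ancestral polarity so the feature space is shared. A frequency tie at
exactly 0.5, and columns monomorphic for REF, declare REF major — a
deterministic, VCF-stable rule. Monomorphic columns are retained; they
become constant features the SVM simply ignores. Missing or unphased
genotypes are rejected rather than imputed: the method expects the output
of an upstream phasing tool, which is complete by construction.

**Window classifiers.** Each window of `w` consecutive SNPs gets an
independent one-against-one ensemble of soft-margin linear SVMs (penalty
`C`, default 1 — accuracy is empirically flat in `C` over 1..1e5 on
separable panels, which the suite checks). The binary subproblem is solved
by libsvm via scikit-learn; the one-vs-one voting, tie-breaking and
cross-validation logic is implemented here. Vote ties are broken by the
largest summed signed decision margin in the tied population's favour
across its classifiers, then by lowest population index — deterministic
and margin-respecting.

**Window reliability.** Each window's success rate `p` is the mean
accuracy of a three-fold cross-validation: haplotypes are split into three
folds stratified per population (seeded shuffle, remainders round-robin),
the full pairwise ensemble is trained on two folds and scored on the
third. `p` is a single pooled accuracy across populations, clamped to
[1e−3, 1 − 1e−3]: an unclamped `p = 1` would give zero emission
probability to every other state and make a confidently wrong window
impossible for its neighbours to override.

**HMM.** Hidden states are the k′ candidate ancestries; observations are
the per-window SVM labels. For a gap of `d` Morgans between window
midpoints, after `g` generations since admixture, the transition matrix
has off-diagonal `(1 − e^(−gd))/(k′ − 1)`; the diagonal is `e^(−gd)`, the
unique completion making rows stochastic. Emissions are `p` on the
diagonal and `(1 − p)/(k′ − 1)` off it. Posteriors are computed by the
scaled forward–backward recursion (per-step normalization, not log-space:
exact, fast, and validated to 1e−10 against explicit enumeration of all
k′^n hidden paths on short chains; row sums stay within 1e−9 at 10⁴
windows). Chains run independently per chromosome, restarting from the
uniform initial distribution — no genetic distance is defined across
chromosome boundaries. Decoding is the per-window argmax of the smoothing
posterior; argmax ties keep the previous decoded label (tract continuity)
and fall back to the lowest index. A Viterbi decoder is available but
non-default.

Two subtleties worth recording. First, the transition formula is *not*
uninformative in the gd → ∞ limit: for k′ = 2 the diagonal tends to 0, an
anti-correlated chain. Transitions are exactly uniform when
`e^(−gd) = 1/k′`, and that is the condition under which decoding provably
returns the raw labels. Second, the number of decoded ancestry switches is
monotone non-increasing as `g` decreases for the Viterbi decoder, but only
monotone in aggregate for posterior-argmax decoding — marginal decoding
does not trace a single path, and rare per-input violations occur (1 in
100 random chains in our check).

## Windowing

Each chromosome with `n` SNPs is tiled into `floor(n/w)` windows; the last
window absorbs the `n mod w` remainder rather than forming a short,
information-poor window. A chromosome with fewer than `w` SNPs becomes a
single short window with a logged warning. The inter-window distance `d`
is measured between window midpoint SNPs' genetic positions — symmetric
and insensitive to the remainder rule; boundary-to-boundary measurement
would also be defensible, but midpoints track where most of each window's
information sits. Genetic positions come from linear interpolation of a
HapMap-format cumulative map (constant extrapolation outside the mapped
range) or from a uniform rate in cM/Mb.

## Simulator

**Ancestral panels.** Balding–Nichols model: per SNP an ancestral
frequency q ~ Uniform(0.05, 0.95) (mirroring a 5 % MAF filter), and per
population a drifted frequency Beta(q(1−F)/F, (1−q)(1−F)/F) at the target
divergence F; haplotype alleles are independent Bernoulli draws. SNPs are
evenly spaced on a single chromosome of configurable genetic length
(default 1 Morgan). Realized Hudson F<sub>st</sub> recovers the target
within ±0.01 at 5 000 SNPs. A hierarchical variant adds "relative"
populations drifted from an ancestor at a small F (default 0.02) plus
optional unrelated decoys, for many-candidate experiments.

**Admixture.** One donor haplotype per mixed population is sampled
without replacement and paired by index. Per chromosome: the initial
origin is drawn from the mixing proportions α; recombination breakpoints
follow a homogeneous Poisson process at rate `g` per Morgan (run-length
CDF `1 − e^(−gd)`); at each breakpoint the origin is *independently
redrawn* from α. Redraws may hit the current origin; such self-transitions
are merged in the reported truth tracts, since origin is what is scored —
consequently the effective switch rate out of the current origin i is
`g(1 − αᵢ)`, and interior tract lengths at α = 0.5 average 2/g Morgans
(verified within 5 % over 10⁴ tracts). All sampled donors are removed from
the panel returned for training, so no simulated haplotype's source is
ever seen by the classifier.

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium within ancestral
populations (sites are independent given the population frequency),
realistic SNP spacing and recombination hotspots, genotyping error,
phasing switch errors, mutation since admixture, and continuous or
multi-wave admixture. Accuracy on real panels with strong internal LD and
imperfect phasing will be lower than the synthetic figures.

## Defaults and study conditions

| parameter | default | meaning |
|---|---|---|
| `w` | 100 SNPs | window size; CV success-rate summaries are printed to guide tuning (no automatic optimization) |
| `g` | 5 | generations since admixture (transition scale), in both simulator and HMM |
| `C` | 1 | SVM penalty; results flat over 1..1e5 |
| `F` | 0.15 | panel divergence of the reference synthetic scenario |
| α | equal | mixing proportions |
| offspring | 4 haploid genomes | simulated admixed sample size per population |
| panels | 2 × 50 haplotypes, 5 000 SNPs, 1 Morgan | reference scenario dimensions |

The benchmark scenarios in the test-suite and acceptance script use these
conditions; the three-way many-candidate scenario uses 10 populations
(3 ancestors, 2 relatives each at F = 0.02, 1 unrelated decoy, 20
haplotypes per population) — sized so the whole suite runs in minutes on
one CPU while keeping ≥ 10 windows per tract at the default `g`.

## Numerical and degenerate-input choices

- Fst: Hudson's estimator with the standard finite-sample correction,
  combined as ratio of averages across SNPs, monomorphic-in-both SNPs
  excluded. It is robust to unequal panel sizes; note that for two samples
  with identical allele counts it returns exactly −1/(n−1), not 0 — the
  correction's price for unbiasedness.
- Accuracy is scored at SNP resolution (windows expanded to columns), so
  the remainder window's extra SNPs are weighted correctly. No
  phase-switch leniency is applied: simulated haplotypes are intrinsically
  phased; for real unphased data this is a known limitation.
- Inseparable or identical training classes do not error: libsvm returns
  a valid (if useless) discriminant and cross-validation reports chance.
- All randomness (panel generation, admixture, CV folds) flows from a
  single seed via independent `SeedSequence` substreams; identical
  configuration and seed reproduce every output file bit-exactly.

## Known limitations

- The HMM observes only hard SVM labels; vote counts or margins are
  discarded (richer emissions are plausible but out of scope).
- `g` must be supplied, not estimated — though accuracy is insensitive to
  20-fold under- or 10-fold over-estimates, which the suite checks.
- Diploid (unphased) modelling, phase-error correction, multi-allelic and
  structural variants, and upstream QC (MAF/HWE filtering, LD pruning,
  phasing, imputation) are not provided.
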