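# Methods

`popgenscan` implements the computational core of a multi-population
resequencing study design: a target population genotyped on a sparse,
low-coverage platform (GBS) is compared and combined with
deeply sequenced reference populations, and screened for signatures of
selection, gene flow and population structure.  Every statistic is
validated on synthetic genotype data with known ground truth; this note
records the models, the parameter choices, and what the synthetic
validation does and does not establish.

## Synthetic genotype data

### Divergence model

Five populations sit on a fixed tree
`(((target, sister), distant), outgroup1), outgroup2` — by default a
Nigerian-zebu-like target (30 diploids), an East-African-zebu-like
sister control (12), a European-taurine-like distant control (12), and
two outgroup species, banteng-like (6) and water-buffalo-like (4).
Ancestral allele frequencies are drawn from a neutral-like density
proportional to 1/p, truncated to [0.05, 0.95].  Along each branch of
t generations in a population of effective size Ne, frequencies drift
by a Balding–Nichols Beta perturbation with mean p and variance
F·p·(1−p), where

    F = 1 − exp(−t / (2 Ne)).

Because Hudson and Weir–Cockerham FST estimators are (nearly) unbiased
for this quantity, a sister pair whose branches each span t generations
has expected windowed FST of 1 − exp(−t/(2Ne)) — an analytic recovery
target that the test suite checks to ±0.02.

Default parameters: Ne = 1000 everywhere; split times 200 (target /
sister), 500 (distant), 2000 and 2600 generations (outgroups); one
2-Mb chromosome at 0.002 segregating sites per bp.  The outgroup splits
deserve a comment: real outgroup species are vastly more diverged, but
this frequency-drift model carries no post-split mutations, so
near-absorbing outgroup drift would leave almost no site that is both
polarizable (outgroup fixed) and polymorphic in the ingroup —
starving the D statistic and the unfolded spectrum of information for
reasons that are an artifact of the approximation, not of the biology.
The chosen splits give per-branch F ≈ 0.6–0.75: outgroups are clearly
the most distant populations (they root the NJ tree and polarize
alleles) while shared ancestral polymorphism persists.

### Sweeps

A sweep is a deterministic distortion of the target branch only: within
`radius` bp of the center the derived (ALT) frequency is pushed toward
fixation,

    p' = p + intensity · w(d) · (1 − p),   w(d) = max(0, 1 − (d/r)²).

The quadratic taper keeps the push near-full across the core of the
affected region, emulating the fixed core of a hard sweep, and decays
to zero at the radius.  A linear taper was rejected: it leaves residual
mid-frequency variation at the center, which a folded spectrum cannot
distinguish from background, and no SFS-based scan can then localize
the sweep.  This is a ground-truth device, not a hitchhiking
simulation; the CLR model is additionally verified against exact
enumeration at the likelihood level, so the simulator does not need to
reproduce sweep genealogies.

### Gene flow

Optional directed edges mix a fraction w of a source population's
frequencies into a destination after divergence
(`p_dst' = (1−w)·p_dst + w·p_src`), giving the ABBA-BABA tests a known
alternative hypothesis.

### Platform emulation

The low-coverage re-call keeps each site independently with a retention
probability (restriction-site subsetting), draws a Poisson read depth
per genotype (default mean 4.87, matching a realistic GBS depth),
samples reads binomially from the true alleles with a per-read error
rate (default 0.005), and re-calls genotypes by flat-prior maximum
likelihood over {RR, RA, AA}, ties resolved toward RR; depth 0 is a
missing call.  Heterozygote under-calling emerges mechanically: at
depth d a true heterozygote presents all-reference or all-alternate
reads with probability 2^(1−d).  An exact Poisson-depth enumeration of
the same call rule provides the oracle for the match-rate tests.  The
emulator never changes positions, alleles or sample order.

## Statistics

- **Nucleotide diversity**: per site π = 2j(n−j)/(n(n−1)) for j ALT
  among n called alleles (the unbiased mean pairwise difference);
  window value = site sum / window span (default 100-kb non-overlapping
  windows on the coordinate grid).
- **FST**: Weir–Cockerham (1984) two-population components by default,
  Hudson as an alternative; windows aggregate as ratio of summed
  components (never a mean of per-site ratios).  Windows default to
  50 kb sliding by 2 kb, anchored per chromosome at its first variant;
  step = size gives the non-overlapping mode.  A site needs at least
  two called alleles in every involved population.
- **PBS**: the three pairwise windowed FST values are clamped to
  [0, 1−1e−9], transformed to branch lengths t = −ln(1−FST), and
  combined as PBS = (t_N,OT + t_N,D − t_OT,D)/2.  Negative FST clamps
  to t = 0; no NaN or infinity is ever emitted.  Four preset scenarios
  (European, Asian, pooled Euro-Asian, other-African-zebu controls)
  mirror the standard study design.
- **Empirical outliers**: the top-quantile threshold is the
  ceil((1−q)·n)-th smallest value; ties at the threshold are included;
  windows with no usable site carry a missing value and never rank.
- **CLR sweep scan**: the background SFS (folded by default; unfolded
  when two outgroups agree on the ancestral allele) is distorted at
  distance d from a putative sweep of strength α (units 1/bp): each of
  n lineages escapes independently with probability 1 − exp(−α·d),
  non-escapes coalesce into one lineage, the B+1 surviving lineages
  follow the hypergeometrically downsampled background, and the swept
  lineage is copied back to sample size n.  The composite likelihood at
  each of `grid` evenly spaced positions is maximized over a log-spaced
  α grid (default 20 values spanning 1e2/L to 1e6/L for chromosome
  length L, ties to the smallest α); the background model is always a
  candidate, so CLR = 2·ΔlnCL ≥ 0 exactly, with α̂ = ∞ reported when
  the background wins.  By default the scan conditions on segregating
  sites; `invariant_mass=True` augments the spectrum with the
  empirical monomorphic fraction so that fixation deserts count as
  evidence.  Scan probabilities are interpolated from a 2048-point
  table over the escape probability (≈1e−4 accuracy in per-site log
  likelihood); `exact=True` disables the table.
- **ABBA-BABA**: frequency-based Patterson's D with outgroup
  polarization (sites with outgroup ALT frequency inside (0.1, 0.9)
  are dropped as unpolarizable), delete-one block jackknife over
  contiguous blocks (5 Mb default, shrunk so at least 20 blocks exist
  on short synthetic chromosomes), and the |Z| ≥ 3 significance
  convention without multiple-testing correction.
- **PCA**: Patterson normalization (center 2p̂, scale √(2p̂(1−p̂))),
  per-site mean imputation of missing genotypes, eigendecomposition of
  the sample covariance; variance explained = eigenvalue / trace.
- **NJ tree**: Saitou–Nei agglomeration on the allele-sharing distance
  D(i,j) = mean |g_i − g_j|/2 over co-called sites (pairwise-complete —
  imputation is never used in distances).  Ties in the Q criterion
  resolve to the lexicographically smallest pair of cluster labels;
  negative branch estimates are clamped to zero with the excess moved
  to the sibling branch.  Population-level trees average
  across-population sample distances first.

## Concordance accounting

Every query site is assigned to exactly one class against the reference
call set: allele-concordant shared, ALT-discordant shared, or novel
(position absent).  Genotype-class match rates condition on the
reference call and exclude comparisons where either call is missing.
Percentages are reported to two decimals with round-half-up so that
printed percentages are exactly recomputable from integer counts.  The
published counts for the five-sample GBS/WGS comparison contain an
internal inconsistency (462,823 of 924,152 loci is 50.08%, not the
printed 49.4%, and the "completely novel" figure 32,201 does not equal
32,188 − 987); those two figures are therefore not reproduced anywhere
in this package.

## Validation scales

The tests and the acceptance script run the pipeline at desk scale,
chosen so each check has adequate statistical power on one CPU:

- FST drift recovery: one 6-Mb chromosome, 15,000 sites.
- PBS/CLR sweep recovery: 2-Mb chromosome at 0.006 sites/bp
  (12,000 sites), sweep radius 150 kb, intensity 0.9, 5 replicates;
  CLR grid of 80 positions (25-kb spacing).  Weaker settings (sparser
  sites or a much narrower sweep) leave the CLR test with too little
  information to localize reliably — a genuine power limit of the
  method, not of the implementation.
- D-statistic calibration: 10-Mb chromosome, 50,000 sites, 10 null and
  10 gene-flow replicates (mixing weight 0.2).
- Platform evaluation: a 10-sample panel (two per population),
  retention 0.5, depth 4.87×, error 0.005.

What passing these tests shows: the estimators are algebraically
correct (oracle equivalences), and they recover known truth under the
stated generative model.  What they do not show: behavior under real
linkage disequilibrium (sites are exchangeable given frequencies, so
the block jackknife is conservative-neutral here), real site-frequency
spectra shaped by demography and selection jointly, reference bias,
or calling artifacts beyond the depth/error model.  Genome-scale
figures from real cattle data (hundreds of samples, hundreds of
thousands of loci) are out of desk-scale reach and are not asserted by
any test.

## Numerical notes

- All randomness flows through seeded `numpy` generators; one child
  seed per operation call, derived via `SeedSequence`; a fixed seed
  yields byte-identical VCF output.
- FST clamps before the −ln transform: lower 0, upper 1 − 1e−9.
- Probabilities are floored at 1e−300 before logs in the CLR scan.
- Windows are 1-based inclusive internally (VCF convention); the
  BED-style 0-based half-open conversion lives in one utility and the
  table writers' `bed` mode.
- Pooled population groups concatenate samples before allele counting
  (so pooled controls are frequency-weighted by sample size).
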