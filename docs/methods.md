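# Methods

## The measurement being modelled

A senescence screen follows many replicate yeast cultures, each carrying a
gene deletion combined with a telomerase-subunit deletion, through serial
passages. At every passage each culture is diluted into fresh medium (or
re-pinned onto agar), grown, and photographed; an image-quantification tool
reports one culture-size number per culture per passage. Telomerase-deficient
cultures grow well at first, decline into senescence as telomeres shorten,
and then a random subset of cultures escapes senescence when rare
recombination-dependent "survivor" lineages take over; some cultures instead
go permanently sterile, because only a few microlitres are transferred at
each passage and a deeply senescent culture can fail to pass on any viable
cell.

Two designs are supported. The *liquid* design passages 96-well plates with
roughly 1:70 dilution per passage over 16 passages; each plate carries 60
query genotypes plus 36 control cultures, and a 16-plate screen therefore
carries 576 control replicates. The *solid* design pins 1536 colonies per
plate for 22 passages; the effective dilution is at most 16-fold, so cells
undergo fewer divisions per passage and senesce more slowly in calendar
passages.

## Variance stabilization

Raw culture sizes (integrated intensity, order 10^6 for a healthy culture)
are heteroscedastic. Sizes are stabilized with a Box-Cox power transform
with power λ = 0.6. Two variants are provided:

* `plain_power` (default): g(x) = x^0.6. A healthy raw size of 10^6 maps to
  10^3.6 ≈ 3981, i.e. the familiar "about 4000 units" fitness scale, and the
  recovery threshold of 1000 transformed units corresponds to a raw size of
  10^5.
* `scaled_power`: g(x) = (x^0.6 − 1)/0.6 with g(0) = −1/0.6, the textbook
  Box-Cox form.

Both are strictly increasing, so within-passage rankings are unchanged, and
because profile classification uses Pearson correlation — which is invariant
under positive-affine rescaling — the choice of variant does not affect
class memberships. It does move absolute-scale quantities (the passage-2
filter cutoff, the recovery threshold), which is why the default keeps the
conventional axis.

## Mean density profiles and profile statistics

The mean density profile (MDP) of a genotype is the per-passage arithmetic
mean of its replicate culture sizes; the per-passage spread is the sample
standard deviation (n − 1 denominator, 0 for a single replicate). Three
statistics compare profiles:

* **Pearson's r** between mean curves — shape similarity. A sick strain and
  a healthy strain with similarly shaped trajectories correlate strongly;
  this is deliberate and is what makes ranked heat maps look "stripy".
  A constant profile has no defined correlation; this is flagged as
  undefined rather than coerced to 0 (a silent 0 would fabricate
  anti-membership), and undefined entries sort after all defined values in
  ranked lists.
* **RMS difference** — sqrt of the mean squared per-passage difference; an
  absolute-fitness metric satisfying the triangle inequality.
* **Profile area** — the plain sum of mean sizes over all passages (no
  normalization), a total-fitness summary additive over passage ranges.

## Archetype classification

Each genotype is correlated against three archetype MDPs:

* **normal** (default archetype label `his3`): member iff r > 0.85.
* **no_recovery** (`rad52`): member iff r > 0.5 *and* the genotype's mean
  transformed size at passage 2 is below C^s = C_ave − 0.5·C_SD, where
  C_ave and C_SD are the mean and standard deviation of *all individual
  culture sizes* at that passage. The filter demands genuinely poor early
  growth, separating accelerated senescence from shape-only lookalikes.
  The filter population is individual cultures; the per-genotype quantity
  compared against the cutoff is the MDP mean at that passage, since MDPs
  are the unit of classification.
* **fast_recovery** (`rif1`): the top k = 20 genotypes by r. A strict
  r-threshold leaves this class nearly empty, so a rank-based class is
  used; ties at the k-th correlation value are all included (a deterministic
  superset rule). A strict-threshold mode can be emulated by filtering the
  ranked list.

Memberships are non-exclusive: a genotype may satisfy several criteria, and
no precedence rule is imposed. An undefined correlation never grants a
membership.

## Recovered fraction

A genotype's recovered fraction is the share of its replicate cultures that
recovered to at least 1000 transformed units by passage 19. Because every
culture *starts* healthy (well above 1000), "recovered by the deadline"
cannot be read as "ever exceeded the threshold up to the deadline" — that
would count every culture. The default `by_passage` mode therefore anchors
at the culture's fitness nadir: a culture counts as recovered iff its size
reaches the threshold at or after the minimum of its full trajectory and no
later than the deadline passage. Anchoring at the global minimum (rather
than the minimum within the deadline window) keeps the statistic
non-decreasing in the deadline and non-increasing in the threshold, at the
cost of missing the rare culture that recovers transiently and then dies
before the end of the experiment — a pattern the generative model does not
produce. An `at_passage` mode tests only the size at the deadline passage
itself. Class-level summaries are unweighted means over member genotypes.

## QT clustering

As an unsupervised alternative to archetype matching, MDPs can be grouped by
classic quality-threshold clustering: around every remaining profile a
candidate cluster is grown greedily — always adding the profile whose
inclusion least increases the cluster diameter, never letting the diameter
(maximum pairwise distance) exceed the threshold — and the largest candidate
is extracted; this repeats until no candidate reaches the minimum size
(default 2), with the remainder reported unclustered. Ties are resolved
deterministically (candidate seeded by the alphabetically first genotype;
within growth, alphabetically first among equal diameter increases), and
inputs are sorted internally so the result is independent of input order.
Distances are 1 − r (default; undefined-r pairs get the maximal distance 2)
or RMS. The default diameter threshold of 0.3 on the 1 − r scale requires
cluster members to correlate at r > 0.7 pairwise; threshold, distance and
minimum size are all configurable, since no canonical settings exist for
this analysis.

## The synthetic screen generator

The simulator produces screens with known ground truth so the classifier
and clusterer can be scored against the generator. Each culture follows a
deterministic log-fitness skeleton with three stochastic ingredients:

1. **Decline.** Fitness is flat at `initial_fitness` through
   `onset_passage`, then falls by `decline_rate × d` in log-fitness per
   passage, where d = log2(dilution_factor) is the per-passage division
   budget (≈ 6.1 divisions in liquid, 4.0 on solid). Tying the pace to the
   division budget reproduces, with a single mechanism, the observation
   that less-diluted solid cultures senesce more slowly. The decline floors
   at `nadir_fraction × initial_fitness`.
2. **Recovery.** Each culture is a recoverer with probability
   `recovery_prob` (Bernoulli). A recoverer starts regrowing a geometric
   number of passages (mean `recovery_onset_mean`, support ≥ 1) after the
   deterministic nadir passage, climbing at `regrowth_rate × d` per passage
   back toward (and capped at) its initial fitness.
3. **Sterility.** A non-recovering culture, once at the floor, becomes
   permanently sterile (exact zeros) with probability `extinction_prob`
   per passage. Recoverers are never sterilized, so the expected recovered
   fraction equals `recovery_prob` exactly.

Measurement noise is multiplicative lognormal with mean 1 and coefficient
of variation `cv` (default 0.25, chosen to match the visible replicate
scatter of healthy cultures); sizes below a detection floor are recorded
as 0, as an image-quantification tool does for an empty spot. Exact zeros
stay zero. Every culture draws from an independent RNG substream keyed by
(seed, plate, row, col), so screens are bit-reproducible and adding plates
never perturbs existing cultures.

### Preset classes

Four presets encode the canonical behaviours. Raw initial fitness 10^6
(≈ 3981 transformed); decline/regrowth rates are per division.

| preset | initial | onset | decline | nadir frac | ρ (recovery) | delay mean | regrowth | extinction |
|---|---|---|---|---|---|---|---|---|
| normal | 1e6 | 2 | 0.20 | 0.007 | 0.50 | 2 | 0.30 | 0.05 |
| no_recovery | 5e5 | 1 | 0.28 | 0.004 | 0.29 | 3 | 0.25 | 0.08 |
| fast_recovery | 1e6 | 1 | 0.30 | 0.007 | 0.81 | 1 | 0.40 | 0.05 |
| neutral_nonsenescing | 1e6 | — | 0 | — | 0 | — | — | 0 |

The recovery probabilities are the reported class-average recovered
fractions of the three behaviours; the shape parameters were set once from
the qualitative contract (normal reaches its nadir near passage 6 under
liquid dilution; the no-recovery class starts sicker and declines earlier;
the fast-recovery class both enters and exits senescence early) and from
one a-priori constraint: recovery onset and regrowth rates are fast enough
that, for a recoverer, the probability of crossing the 1000-unit threshold
after the passage-19 deadline (a geometric-tail event) is a few percent at
most, so the measured recovered fraction estimates ρ nearly unbiasedly.

### What the generator does and does not emulate

It emulates: decline to crisis, stochastic survivor emergence, permanent
sterility, slower senescence under lower dilution, multiplicative noise
with a detection floor, and the replicate structure of both designs. It
does not emulate: telomere-sequence dynamics or survivor subtypes, spatial
plate effects (neighbour or edge artifacts), contamination, onset-time
variance between replicates beyond what noise induces, or secondary
senescence of recovered cultures. Passing parameter-recovery tests
therefore shows the pipeline is correct and well-calibrated under this
generative model, not that real screens are free of the excluded effects.

## Study-scale experiments

Two seeded experiments exercise the whole pipeline; their sizes were chosen
as the smallest that leave comfortable statistical margins.

* **Three-class recovery**: 120 query genotypes (40 per senescing preset) at
  8 replicates, plus the three archetype genotypes at 36 replicates each
  (mirroring the heavier replication of controls in real screens), solid
  design, 22 passages. Scored by (a) nearest-archetype agreement — the
  fraction of genotypes whose truth class attains the highest of the three
  correlations — and (b) truth-class mean recovered fractions against
  ρ = 0.50/0.81/0.29 within three binomial standard errors (n = 320
  cultures per class). Recovery means are grouped by generator truth:
  grouping by the assigned top-k fast-recovery class would condition on
  the realized recovery outcomes and bias the class mean upward.
* **Fitness ladder**: 23 groups of 3 non-senescing genotypes at fitness
  levels 1000, 1500, …, 12000 transformed units (8 replicates, cv 0.05),
  clustered under the RMS distance with diameter threshold 250 — a
  known-ground-truth instance whose between-level gaps (≥ 500) dwarf the
  within-level noise scatter, so exactly 23 pure clusters are recoverable.

## Numerical choices and degenerate inputs

* Correlations are computed from mean-centred dot products and clipped to
  [−1, 1]; agreement with a from-definition implementation is tested to
  1e−12.
* Sample standard deviations use the n − 1 denominator throughout.
* Culture tables store sizes as shortest round-tripping decimal text and
  are parsed with round-trip float precision, so write-then-read is
  bit-exact.
* An empty culture table, a ragged passage range, or a negative size is a
  validation error naming the offending culture; an all-zero culture is
  legal (sterile from start) and is counted in the validation report.
* Layout generation, simulation, classification and clustering are all
  deterministic given their inputs; the pipeline driver writes a JSON
  manifest (seed, thresholds, input digest) and reruns are byte-identical.

## Known limitations

* The passage-2 filter cutoff is scale-dependent by construction; it is
  computed on the transformed scale and recorded with the filter object.
* The top-k fast-recovery class has no absolute quality guarantee: in a
  screen with fewer than k genuinely fast-recovering genotypes the class
  absorbs near misses, and with more than k it truncates.
* The recovered-fraction statistic cannot see a transient recovery that
  ends before the culture's global fitness minimum (see above).
* QT clustering is O(n³) per extracted cluster; it is intended for
  thousands of profiles at most.
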