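# Methods

## Model

An alignment of n sequences of length l over an alphabet of k residues
(gap included; DNA k = 5, protein k = 21) is encoded as the boolean sequence
matrix X (n × k·l): position j of sample i contributes a k-block of
indicator coordinates, laid out letter-major (all positions of symbol 1,
then of symbol 2, …).  The encoding is lossless and exactly reversible for
unambiguous residues; each k-block sums to one, so one degree of freedom per
position is spent on that constraint and, with mean centering, the effective
number of components is at most n − 1.

The centered matrix D (rows x⃗ − m⃗, with m⃗ the column-mean center or the
mean of a chosen reference subset) is factored by thin SVD, D = LΣRᵀ.
Sample components S = LΣ = DR and base components N = RΣ = DᵀL are two views
of the same rotation; pairwise Euclidean distances between rows of S equal
those between rows of D exactly.  The scaled components (sPC)

- Ŝ = S/√l — sample scores; the distance between two rows of Ŝ is
  √(2·p̂) for unambiguous data, with p̂ the substitution rate;
- N̂ = N/√n — base loadings; entries null on every axis mark conserved
  bases, entries beyond a magnitude threshold mark characteristic bases;

make magnitudes comparable across datasets of different size.  The
contribution of axis j is 100·σⱼ/Σσ — the raw singular value's share, not
the variance share; this follows the definition used with this method (a
variance-based convention would concentrate the percentages further into
the leading axes but ranks axes identically).

Distances between samples are ê = √(Σ(x⃗₁ − x⃗₂)²/2) — halved inside the
root because one substitution changes two indicator coordinates — and
p̂ = Σ|x⃗₁ − x⃗₂|/2l, with ê = √(p̂·l).  The comparison baseline
(`conventional_pca`) applies SVD to the column-mean-centered ê matrix and
scales scores by 1/(√2·√l); the √2 corrects for each distance appearing in
both triangles.  Double (row-and-column, PCoA-style) centering is available
behind a flag; single centering is the default because it mirrors the
centering used on the sequence matrix itself.

### JC69 compensation

Optionally, each row of D is stretched to its one-parameter Markov
(Jukes–Cantor 1969) evolutionary length: with per-sample divergence
p̂ = Σ|d|/2l from the center, d̂ = −¾·ln(1 − 4p̂/3) and the row is
multiplied by √(d̂/p̂) ≥ 1.  The ratio is fixed to 1 at p̂ = 0 (its analytic
limit) and the transform refuses rows at or beyond the saturation point
p̂ = 3/4, naming the offending sample.  Because members of a cluster are
compensated alike, the adjustment enlarges between-cluster gaps but rarely
reorders samples along an axis; it matters only at divergences well above
the p̂ ≲ 0.01 typical of within-species marker data.

## Numerical choices

- **Sign convention.**  SVD signs are arbitrary; each right-singular column
  is flipped (jointly with its left partner) so that its largest-magnitude
  entry — the first such entry on ties — is positive.  Outputs are thereby
  reproducible to the byte.
- **Rank truncation.**  Singular values below 1e−12·σ₁ are dropped from the
  result (rank, components, contributions).  An alignment with no variation
  yields an empty (rank-0) result with a warning rather than an error.
- **Consensus ties** break toward the earlier symbol in alphabet order.
- **Ambiguity codes** (IUPAC nucleotide codes, `X`/`B`/`Z`/`J` for protein)
  are encoded as the uniform distribution over their compatible non-gap
  symbols: the block-sum invariant is preserved and no directional signal is
  invented.  Such positions cannot be decoded back to a single character.
- **Axis numbering** is 1-based everywhere a user sees it (sPC1…), as are
  alignment positions.
- **Q-Q threshold rule.**  The characteristic-base threshold can be read
  off a normal quantile–quantile plot of an axis's loadings: noise-like
  loadings follow the straight central trend, structural ones peel away in
  the tails.  A line is fitted to the central 50% of the plot; residuals
  are standardized by the asymptotic standard deviation of each normal
  order statistic (tail order statistics wobble far more than central ones,
  and ignoring that flags ordinary sampling noise); loadings beyond 4
  standardized units are structural, and the suggested threshold is placed
  in the widest empty magnitude gap between the bulk and the structural
  tail.  With no structural loading the conventional default 0.05 is
  returned.  Band width and z-cutoff are exposed as parameters since no
  canonical values exist; the rule assumes structural loadings are few
  relative to the bulk.

## Simulations

The simulators generate the divergence structures the method is meant to
tell apart; all are deterministic given an integer seed.

- **Random walk** (`simulate_random_walk`, defaults l = 1000, 200 steps):
  a random ±1 sequence undergoes sequential rounds in which one uniformly
  chosen position flips sign; every round is recorded, so consecutive rows
  are at Hamming distance 1 and mutations may revert.  This mimics a single
  evolving lineage sampled through time.
- **I.i.d. group** (`simulate_iid_group`): every sample independently flips
  m positions (drawn with replacement) of one ancestral sequence — a group
  with a long shared history diverging in many directions at once.  For the
  attenuation contrast the group is matched to the walk's dimensions
  (n = 200, l = 1000) with m = 100 flips, placing samples at a divergence
  comparable to the walk's mid-history.
- **Clustered population** (`simulate_clustered_population`): founders are
  created by substituting exactly round(divergence·l) positions of a shared
  ancestor (one rate per cluster if desired — exact counts keep the
  between-cluster geometry stable across seeds); members mutate their
  founder at `within_rate` per position; hybrids are position-wise mosaics
  of the first two founders; an optional outlier carries a private
  contiguous motif.  Defaults (3 × 30 samples, l = 300, divergence 0.02,
  within 0.002) give tight clusters an order of magnitude closer-knit than
  their separation and a total dispersion of ≈ 0.1 on the sPC scale —
  the regime typical of within-species MHC or 16S marker studies.  The
  outlier-robustness experiment instead uses unequal depths
  (divergences 0, 0.017, 0.013; sizes 10, 12, 8) so that the two leading
  singular values are well separated and the leading axes carry only
  cluster structure, with the outlier's host cluster at the ancestral
  center.

The ±1 processes are written onto a gap-free two-symbol alphabet so the
standard encoding/PCA path is exercised; relative to raw ±1 coding this
rescales all distances by a constant and leaves components proportional.

### Attenuation profile

For a result of rank r, θ is the arithmetic sequence k·(π/2)/(r+1),
k = 1…r, open at both ends.  Component k (contributions in descending
order) is paired with θ_{r+1−k}, so the leading contribution meets the
angle nearest π/2: a lineage-like (random-walk) process has singular values
close to a cosecant sequence, i.e. proportional to the tangent of the
*descending* angles, so its contributions correlate strongly with the
paired tan θ, while an i.i.d. group attenuates at a near-constant rate and
correlates weakly.  The profile reports the least-squares slope, intercept
and Pearson correlation of contributions on the paired tan θ.  The walk's
sample components additionally oscillate like Fourier modes over the step
index: the number of sign changes grows with the component index.

## What the simulations do and do not show

The generators produce uniform random ancestors, position-independent
substitutions, exact mosaic hybrids and a single contiguous private motif.
Real marker data add alignment errors, indel blocks, compositional bias,
rate variation across sites and recombination — none of which are
emulated, so passing tests demonstrate the algebraic and structural
properties of the method (reversibility, rotation invariance, scale
conventions, robustness mechanics), not its behaviour under every field
condition.

One comparative property deserves honesty: with three clusters of ~30
samples total and a 10-base private motif, the conventional distance-matrix
baseline's leading-axis scores for the non-outlying samples are nearly as
stable as the direct method's (correlations ≈ 0.9999 for both).  The
outlier's row in the distance matrix grows like √n while cluster structure
grows like n, so at this sample size and motif length the outlier cannot
capture the baseline's leading axis; the direct method's distinctive
advantage at this scale is *where* the motif lands — on an axis of its own
below the cluster structure, leaving the leading axes untouched — which the
robustness experiment reports as `motif_axis`.

## Known limitations

- Inputs must be pre-aligned; the package neither aligns sequences nor
  builds trees (the ê matrix can be exported for external tree software).
- JC69 is the only substitution-model compensation offered; richer Markov
  models would change little at small divergences and rest on assumptions
  the data cannot verify.
- Per-column weighting (e.g. by standard deviation) is deliberately not
  implemented: it magnifies artefacts such as sequencing errors that appear
  as rare private motifs.
- Contributions are not normalized for dimension and should not be compared
  between analyses of different size.
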