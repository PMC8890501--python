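# Methods

This note records the models, conventions, and numerical choices behind
`ribolandscape`, and what the synthetic experiments do and do not establish.

## Library and genotype conventions

A genotype is the string of RNA alleles (A<C<G<U, ASCII order) at the
library's variable positions; the fixed remainder of the reference is
implied.  Variable positions are 0-based offsets into the supplied reference
sequence; the intron-numbering labels familiar from the ribozyme literature
(90, 119, 128, 153, 158, 177, 184 for the shipped design) are carried only
as display metadata.  The shipped reference is reconstructed from the
library's synthesis template; its randomized-site offsets plus 9 reproduce
the intron numbering exactly (the template starts at intron nucleotide 9),
and the wild-type alleles at those sites are C,A,A,A,C,C,U.  Genotypes are
encoded as base-4 integers so lexicographic and numeric order coincide;
every vectorized computation (squares, neighbor tables, distance vectors)
works on that encoding.

Sequencers emit DNA, so FASTQ I/O transparently maps U↔T; matching is
case-insensitive, substitution-only and exact-length, and any read with an
ambiguous base or a mutation outside the variable positions is rejected —
the counting stage implements exactly the wildcard-pattern rule used for the
real selection data.

## Fitness

Fitness is the enrichment ratio (post/pre proportion) normalized to the
wild-type, so W(wt) ≡ 1 per condition and replicate.  Conventions chosen
where the original analysis is silent:

- No pseudocounts.  A genotype present before and absent after selection has
  W = 0; a genotype absent *before* selection is **missing** (NaN), not
  zero, and is excluded downstream.  Pseudocounts would silently distort
  exactly the low-fitness regime where the interesting magnesium dependence
  lives.
- Replicates are combined as the arithmetic mean of per-replicate ratios
  (not a pooled-count ratio); CV uses the sample (n−1) standard deviation
  and is reported only where the mean is positive and ≥ 2 replicates exist.

## Epistasis squares and ruggedness

Every set of four genotypes {g, g+A, g+B, g+A+B} is a square.  With
fitness W0, WA, WB, WAB the square is epistasis-free when
WAB + W0 − WA − WB = 0; otherwise the sign of each mutation's effect in the
two backgrounds decides the class: both preserved → magnitude, one flipped
→ sign, both flipped → reciprocal sign.  The implementation states this as
two triangle-equality conditions and is cross-checked in the tests against
an independent sign-pattern oracle and for invariance to which corner
anchors the square.  Ruggedness is 2·f_RS + f_S over classified squares.

Numerical choices:

- Equality comparisons take an absolute tolerance `eps` (default 0, i.e.
  plain floating comparison, matching an exact-equality rule applied to
  floating data; synthetic exactness tests pass `eps≈1e-9`).  A
  zero-magnitude effect (|ΔW| ≤ eps) counts as sign-agreeing.
- Squares are enumerated deduplicated (each geometric square once, anchored
  at its lexicographically smallest corner): 16,384·21·9/4 = 774,144 for the
  full library.  Classification is anchor-invariant, so fractions are
  identical to any over-counting convention.
- Squares with a missing corner are skipped and tallied; fractions are over
  classified squares only.

The roughness-to-slope ratio r/s fits fitness by least squares to an
additive model (intercept + one indicator per non-reference allele per
position, 22 coefficients for the 7-position library); r is the RMS
residual, s the mean |allele coefficient|.  The reference level defaults to
the wild-type allele and is configurable; the additive-fit definition is the
standard one and is oracle-tested against an independent OLS.

## Dose–response models

Hill curves W(m) = wmax·mʰ/(kʰ + mʰ) are fit per genotype to the
replicate-mean titration profile by bounded nonlinear least squares
(`scipy.optimize.least_squares`), with deterministic multi-start
initialization (h ∈ {0.5, 1, 2, 4}; k from the interpolated half-max
crossing and the median mg).  Genotypes missing in any condition are
excluded rather than imputed.  Degenerate inputs are flagged, never reported
as valid fits: all-zero profiles (`no_activity`), flat profiles
(`degenerate_flat`, relative range < 1e-3 — a constant profile carries no
information about k or h), and solutions pinned at the parameter bounds.
Filters keep 0.15 < wmax < 3, h < 5, k < 16 mM, with a tally of exclusions
by reason.  `fit_hill` optionally accepts per-point standard errors and then
minimizes inverse-variance-weighted residuals (the `curve_fit` convention);
count-derived fitness is strongly heteroscedastic, and the recovery
experiments use count-based standard errors for exactly that reason.  The
pipeline's default fits are unweighted.

The decay law W(n) = exp(−α·n^β) is fit to the per-distance means
(distance n ≥ 1; W(0) = 1 holds by construction and is excluded).  Fitting
is done in log-fitness space when all means are positive (initialized from
the log–log linearization), falling back to the direct scale otherwise,
flagged in the output.  β = 1 on exactly multiplicative landscapes is the
calibration anchor: β > 1 means mutations hurt more in combination than
multiplicatively (negative/synergistic epistasis).

## Wright–Fisher simulation

Populations evolve in discrete non-overlapping generations at constant
N: offspring are drawn multinomially with probabilities proportional to
parental fitness, and each offspring independently mutates with probability
μ to one of its 3L single-substitution neighbors, chosen uniformly (at most
one substitution per offspring per generation).  Generational Wright–Fisher
dynamics were chosen over Moran dynamics; the constant-N,
fitness-proportional-reproduction description admits both, and WF is the
simpler canonical choice.  Genotypes with missing fitness reproduce with
fitness 0.  Trajectories have length generations+1 with index 0 the initial
monomorphic population, so "generation 50" (the G50 statistic) is index 50.
One master seed deterministically spawns per-replicate streams
(`numpy.random.SeedSequence`).

The starting genotype is chosen deterministically: among genotypes at
Hamming distance 7 from *every* per-condition fitness peak, the one with the
lowest across-condition mean fitness, ties broken lexicographically.  Two
refinements beyond the distance/low-fitness description: candidates must
have nonzero fitness in every condition (a zero-fitness monomorphic
population cannot reproduce at all), and if no genotype achieves the target
distance the maximum achievable distance is used and the choice is flagged.

Logistic fits f(x) = L/(1 + e^(−k(x−x₀))) use bounded multi-start least
squares; constant trajectories are flagged degenerate.

## The synthetic experiment

The generator stands in for the raw sequencing data and is the ground truth
for every recovery test.  Its model, per genotype:

- activity a(m) = wmax·mʰ/(kʰ + mʰ) — the same parameterization the fitter
  uses, by construction;
- log(wmax) = Σ single-mutation effects (Normal(−0.4, 0.35): most mutations
  deleterious) + sparse pairwise terms (Normal(−0.1, 0.2), 20% active:
  predominantly negative epistasis, so β > 1 at saturating magnesium);
- k = 2 mM + Σ midpoint shifts (Normal(+2.0, 1.5) mM, floored at −0.5:
  most mutations destabilize the fold, so midpoints rise with mutational
  distance) + sparse pairwise midpoint terms (Normal(−0.5, 1.5) mM, 15%
  active: partial compensatory stabilization).  Midpoints are clipped below
  at the wild-type's 2 mM — the wild-type is treated as the stability
  optimum of this local landscape, which is what confines
  fitter-than-wild-type variants to saturating magnesium;
- Hill slope h = 3 for all genotypes (cooperative magnesium-dependent
  folding, typical of group I introns; observed slopes in such titrations
  run to ~5);
- 5% of mutants are dead (wmax = 0) independent of the above;
- pre-selection pool from a symmetric Dirichlet (concentration 5: uneven
  synthesis), selection by proportional enrichment with activity weights,
  and multinomial sequencing of both pools at 10⁶ reads per
  condition-replicate.

The pairwise **midpoint** interactions are the load-bearing design choice:
they are what makes epistasis magnesium-dependent.  A compensatory pair
matters at low magnesium and is silenced once magnesium saturates folding,
so measured ruggedness falls along the titration; pure log-activity
epistasis alone is magnesium-independent and could not reproduce that.

Read depth interacts with the dynamics in an instructive way.  At 10⁶ reads
per sample the many low-magnesium variants with tiny activity sit near the
detection floor; their measured fitness values are zero or noise-dominated,
which is simultaneously (a) realistic — the real data's CVs rise steeply
below fitness ≈ 0.15 — and (b) what makes simulated low-magnesium
adaptation slow, since populations must cross plateaus whose measured
gradients are unreliable.  Much deeper simulated sequencing resolves those
tiny values exactly and, because only fitness *ratios* matter to selection,
makes low-magnesium adaptation artificially fast.  The default depth keeps
the measurement floor in the model.

What the synthetic experiment does **not** emulate: RT-PCR amplification
bias, sequencing substitution errors, paired-end merging artifacts,
genotype-by-replicate activity variation, and any kinetic saturation of the
selection reaction.  Passing recovery tests therefore show that the analysis
chain inverts its own generative model at realistic depths — not that the
model captures every feature of the laboratory data.

## Scaled-down validation studies

Two built-in experiments (`ribolandscape.recovery`) back the validation
suite and the reproduction script:

- **Hill recovery**: 1,000 variants with generator-regime parameters plus a
  saturated 10% spike-in reference (midpoint 0.01 mM, so each normalized
  profile is exactly a Hill curve), sequenced at 10⁵ reads per
  condition-replicate in triplicate.  Noiseless profiles recover all three
  parameters to ~1e-6 relative; with sequencing noise the median midpoint
  error is ~4–5%.
- **Magnesium gradient**: one full synthetic experiment; per magnesium
  level, measured-landscape ruggedness and Wright–Fisher adaptation
  summaries (10 replicates × 300 generations, N = 1000, μ = 0.01 — scaled
  down from 100 × 2000), then Spearman trends against magnesium.  At the
  pinned validation realization (seed 1) ruggedness and logistic x₀ fall
  with magnesium and G50 rises.  Across independent realizations the G50
  trend is robust and the ruggedness trend usually holds (occasional
  realizations show a high-magnesium uptick where activity-epistasis noise
  dominates the flattened landscape); the x₀ trend is the noisiest of the
  three at this simulation size.  The validation suite therefore pins the
  realization; the reproduction script reports whatever the supplied seed
  yields.

## Known limitations

- Ruggedness from measured landscapes conflates true sign epistasis with
  counting noise among low-fitness genotypes; the package reports class
  fractions and skipped-square counts so users can filter (e.g. by CV or a
  fitness floor) before classification if they prefer.
- Hill midpoints are only weakly identified when k approaches the top of
  the titration range (here 48 mM); the filters deliberately drop k ≥ 16.
- The r/s convention (reference level, coefficient averaging) follows the
  standard additive-fit definition; other conventions in the literature
  differ by bookkeeping, not substance, and the reference genotype is
  configurable.
- `choose_start` encodes stated constraints (distance from peaks, low but
  nonzero fitness); it is a reproducible convention, not a claim about the
  original study's unpublished choice.
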