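# Methods

## The triplet rule model

`rmnet` treats interaction inference as hypothesis screening over ordered
taxon triplets.  The underlying assumption is that a target taxon's
relative abundance behaves according to the abundances of a cooperating and
a competing taxon.  Because relative abundances from cross-sectional
surveys carry no time axis, changes are evaluated over *sample pairs*; two
pairings are supported:

* `all_pairs` (default): every unordered pair of samples, oriented by
  column order.  Appropriate for spatial designs, where no ordering of
  samples is privileged.  With n samples this yields n(n−1)/2 pairs.
* `consecutive`: successive samples only (n−1 pairs), for genuine time
  series and for noisy settings where fewer, independent comparisons are
  preferable (see *Calibration* below).

A change is discretized with a steady band of half-width ε (fraction
units): UP above +ε, DOWN below −ε, STEADY otherwise.  The rule table makes
a pair predictive only when cooperator and competitor move in opposite
directions; the predicted target direction follows the cooperator.  A
predictive pair with a STEADY target counts as a contradiction: the model
predicted a change that failed to materialize.  Pairs in which the
regulators co-move or are steady carry no information about the hypothesis
and are ignored.

The conformity score s = (support − contradiction)/informative lies in
[−1, 1]; s = 1 is perfect conformity, s = −1 perfect anti-conformity.
Acceptance requires `informative ≥ m_min` and `s ≥ s_min`.

This rule table and score are one concrete reconstruction of a model that
is usually stated only qualitatively; both are parameters of the engine
(`RMNParams`) so alternative discretizations or thresholds can be swapped
in without touching the network assembly.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `theta_min` | 0.001 | fraction | minimum max-abundance for a taxon to enter the network and to count as "present" at a site (0.1%) |
| `epsilon` | 0.001 | fraction | steady-band half-width of the discretization |
| `pair_mode` | `all_pairs` | — | sample pairing scheme |
| `m_min` | 3 | pairs | minimum informative pairs per triplet |
| `s_min` | 1.0 | — | minimum conformity score (1.0 = zero contradictions) |

The strict default `s_min = 1.0` reads "conform to the model" literally:
a single contradicting pair disqualifies a triplet.  This suppresses false
positives aggressively (on structure-free null data the median number of
accepted edges over 50 seeds at 8 taxa × 10 samples is 0) at the cost of
sensitivity under noise.

### Structural guarantee

Edges enter the network only in cooperator/competitor pairs from accepted
triplets, so every node with an incoming cooperative edge necessarily has
an incoming competitive edge.  This is enforced as a validation invariant
of the network container and checked property-style in the tests.

## Oligotyping

Oligotypes are defined by the residues at the k highest-Shannon-entropy
columns of an aligned read set (default k = 2).  Entropy is computed in
bits (log2) over pooled reads from all samples; the base affects only the
reported magnitudes, not the ranking that selects columns.  Ties break
toward the smaller column index.  Gaps (`-`) and ambiguity codes are
ordinary characters: silently dropping them would change counts.  Exactly
one round of component selection is performed — oligotypes are not
recursively purified — and no minimum-abundance or minimum-sample filters
are applied to the resulting oligotypes.  Reads are mapped to samples via
an explicit table or the `<sample>_<serial>` identifier convention.

## Alpha diversity

Estimators follow mothur's conventions so outputs are comparable with
standard amplicon summaries: Good's coverage 1 − n1/N; Chao1
S_obs + n1(n1−1)/(2(n2+1)); plug-in Shannon in natural log; the
non-parametric (Chao–Shen) Shannon with coverage-adjusted frequencies and
Horvitz–Thompson weighting; the unbiased inverse Simpson
N(N−1)/Σn_i(n_i−1) (the plug-in 1/Σp_i² is exposed separately); evenness
H/ln S_obs.  Undefined cases are NaN rather than errors: inverse Simpson
when every taxon is a singleton, evenness when S_obs = 1, np-Shannon when
coverage is 0.  Rarefaction ("normalize to the lowest sequencing outcome")
is a single seeded multivariate-hypergeometric draw per sample, not an
average over draws, matching mothur's sub.sample behaviour.

## Synthetic benchmark

`generate_planted` emulates the structure the rule model assumes.  Per
sample, background abundances are independent Gamma(`baseline_concentration`)
draws closed to fractions.  For each planted triplet the target row is
rewritten as

    raw_target = baseline + beta_coop·f_coop − beta_comp·f_comp + N(0, noise_sd)

with the default baseline set just above `beta_comp · max(f_comp)` so the
competitive term cannot drive the value negative (a 1e-6 floor remains as a
safety net).  Planted rows (target and both regulators) are kept exactly;
regulator trajectories are the null draws rescaled to a per-row cap chosen
so the planted block cannot exhaust a sample's total, and the untouched
background rows are rescaled per sample to absorb the remainder of the
simplex.  This makes closure exact for the planted rows, so at
`noise_sd = 0` every predictive pair of a planted triplet is supported by
construction (the response margin β(|ΔC| + |ΔK|) strictly exceeds ε when
β ≥ 0.5) and recall is deterministically 1.

What the generator does *not* emulate: read-count sampling noise,
taxon-correlated backgrounds, longitudinal autocorrelation, and ecological
dynamics (no Lotka–Volterra coupling).  Passing benchmarks on this
generator therefore demonstrates correctness of the inference machinery on
data that satisfy the model's own assumptions, not performance on real
communities.

### Identifiability limit at zero noise

On noise-free data where the target is an exact monotone function
X = b + βC − βK, the data equally satisfy the inverse hypothesis
"K is promoted by C and impeded by X": whenever C is UP and X DOWN, K must
have risen by more than ΔC + 2ε, and symmetrically for the other direction.
The inverse triplet therefore accumulates zero contradictions and is
accepted alongside the planted one, contributing the extra edges C→K
(cooperative) and X→K (competitive).  With one planted triplet measured
precision against the planted truth is exactly 0.5 while recall is 1.0.
This is not an implementation artifact but a property of the rule model:
the direction of a deterministic constraint among three taxa cannot be
oriented from discretized co-changes alone.  Noise breaks the exact
implication and removes the inverse triplet, at the price of occasional
contradictions against the true one.

### Calibration for the noisy benchmark

The noisy benchmark uses `noise_sd = 0.005`, i.e. 10% of the planted
response's across-sample standard deviation (≈0.05 at the benchmark
settings of 8 taxa × 40 samples, β = 0.5).  At β = 0.5 the forward support
margin over the steady band is 2βε − ε = 0, so with all-pairs scoring
(780 pairs) strict conformity is destroyed by any noise level regardless of
ε — some predictive pair always sits at the margin.  The benchmark
configuration therefore switches to consecutive pairing (39 comparisons),
ε = 0.02 and `m_min = 8`, keeping `s_min = 1.0`.  Achieved mean F1 over
seeds 1–20 is 0.913, recorded as the regression baseline; the
recommendation for noisy data generally is: fewer, coarser comparisons with
a higher evidence requirement, rather than a relaxed conformity threshold.

## Numerical and design choices

* Abundances are fractions in [0, 1] everywhere internally; the
  oligotyping percent dialect is converted at the I/O boundary.  This
  prevents double-scaling bugs.
* Triplet evaluation is vectorized over a precomputed taxa × pairs change
  matrix; an independent plain-Python enumerator is kept in the test suite
  and acceptance script as the oracle.
* Edge merge keeps the maximum contributing score; no tie-break is needed.
* All exports are deterministically ordered (source, target, sign), so
  repeated writes are byte-identical; rendering uses a seeded spring
  layout and is byte-reproducible at fixed seed.
* Multiple `label` blocks in mothur files: only the first block is read,
  with a warning (analyses here use a single OTU definition).
* Problem sizes in the test suite and acceptance script (≤8 taxa, ≤40
  samples, tens of seeds) were chosen so the full pipeline, including the
  brute-force oracle, runs in seconds while still exercising hundreds of
  sample pairs per triplet.

## Known limitations

* No statistical significance for edges (no permutation p-values); the
  conformity score is a descriptive, not inferential, quantity.
* Two-region site categorization only; >2-region designs raise an error.
* The oligotyper performs no alignment or quality filtering and does not
  implement the iterative supervised refinement of the original
  oligotyping workflow.
* Diversity values computed on subsampled counts depend on the seed; the
  package deliberately does not average over rarefaction draws.
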