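# Methods

## Models and Bayes factors

Four sampling designs for an R×C count table are distinguished by what they
hold fixed: nothing (Poisson), the grand total (joint multinomial), one
margin (independent multinomial), or both margins (hypergeometric).  Under
each design, the independence model H0 and the saturated dependence model H1
receive conjugate priors — gamma priors on Poisson rates, Dirichlet priors
on multinomial probabilities — with a common concentration `a_rc` per cell.
Because the priors are conjugate, both marginal likelihoods are available in
closed form as products of gamma functions, and each Bayes factor is a ratio
of Dirichlet normalizing constants `D(v) = Π Γ(v_i) / Γ(Σ v_i)` evaluated on
cell counts and margins shifted by the prior.  The successive designs
condition on progressively more of the data, and the evidence for dependence
weakens accordingly: on any 2×2 table, `BF10^Poisson ≥ BF10^joint ≥
BF10^indep ≥ BF10^hyper` (the first inequality is the exact identity
`BF^P/BF^M = 4(y..+3)/(3(y..+4)) > 1`); on null-like tables the ordering of
evidence *for* independence reverses.  The test suite verifies these
identities, and the remaining orientation-dependent ratio identities, by
exact rational arithmetic.

All kernels report the natural-log `BF10` (dependence over independence);
the underlying derivations produce `BF01`, and the sign is flipped at the
end.  Reported log Bayes factors are natural logs throughout.

## Parameters

- `a` (cell concentration, default 1): prior pseudo-count per cell.  `a = 1`
  is uniform over each probability simplex; larger `a` encodes smaller
  expected departures from independence and pulls H1's predictions toward
  H0's.  Non-unit and even cell-wise concentrations are supported by the
  general kernels; the factorial closed forms and the one-sided correction
  require the symmetric default.
- `b` (gamma scale, Poisson scheme only, default `R·C·a / y..`): the scale
  of the gamma prior on each cell's Poisson rate.  The default ties the
  prior's total intensity to the observed grand total and is data-dependent
  by construction; it can be overridden (`--b`).
- `fixed_margin` (`rows`/`columns`): which margin the independent
  multinomial design fixed.  Rows index the groups by package convention.
- `direction` (`greater`/`less`): one-sided hypothesis that the first
  group's first-outcome rate exceeds (trails) the second's; defined only for
  2×2 independent-multinomial designs.
- `enumeration_cap` (default 10⁷): upper bound on the number of
  fixed-margin tables the hypergeometric sum may enumerate.  For 2×2 tables
  the support size is `min(margins) + 1`, so the cap only matters for larger
  tables with large margins.

## Numerical choices

- Everything runs in natural-log space via `scipy.special.gammaln`; the
  hypergeometric numerator uses log-sum-exp.  The 14×14 example needs
  Γ(802)-scale values, far beyond direct factorials.
- The 2×2 factorial closed forms (valid at `a = 1`) are implemented
  separately from the general kernels and act as cross-checks, not as fast
  paths.  The hypergeometric closed form is stated for tables whose *first
  row total is the smallest of the four margins*; `canonicalize_min_margin`
  establishes that form, breaking ties by preferring identity, then row
  swap, then transposition (tied choices give identical values).  The
  independent-multinomial closed form reads the *fixed* margin totals as the
  binomial sample sizes and the first free-category counts as successes;
  the alternative symbol-for-symbol reading (free margins as sample sizes)
  does not reproduce the published two-sided factor for the bridge data
  (5.96 instead of 5.31) and was rejected.
- `P(θ₁ > θ₂)` under independent beta posteriors uses an exact finite-sum
  identity evaluated in rational arithmetic whenever the posterior
  parameters are integers (always true at integer `a`), keeping the
  one-sided factors fully deterministic; non-integer parameters fall back to
  adaptive quadrature of `f₁ · F₂` (absolute tolerance 1e-10).
- The binomial-type coefficient over a matrix in the hypergeometric kernel
  is read as the multinomial coefficient `y..! / Π y_rc!`; this reading
  makes the enumerated sum agree exactly with the 2×2 closed form and with
  exact rational arithmetic on random tables.
- Posterior log-odds-ratio summaries use percentile (not HPD) intervals and
  a fixed 1.96 Wald quantile for the classical 95% interval; the Pearson χ²
  applies no continuity correction.  Zero cells make the unadjusted log odds
  ratio undefined and raise an error rather than silently applying a
  correction.
- Randomness (posterior sampling, table generation) flows through a single
  `numpy.random.default_rng(seed)` per call; summaries are reproducible
  bit-for-bit given `(seed, n_draws)`.

## Bundled data and their checksums

Four historical tables ship as CSV under `ctbf/data/`: the 2×2 bridge,
doll-preference, and sibling-acceptance tables, and the 14×14 fathers/sons
occupation table (775 pairs).  The occupation table was transcribed from a
degraded printing in which digits run together; the transcription was
selected by constrained search as the *unique* digit segmentation whose
grand total is 775 and whose Pearson χ² equals the published 1005.45
(df = 169) at printed precision.  On that table the Poisson-scheme factor,
confirmed independently by exact rational arithmetic, is ln BF10 = 266.21,
whereas the original report prints 262.21; no segmentation reproduces both
published numbers (the closest match to 262.21 has χ² ≈ 976), so the
published pair is internally inconsistent and the χ²-validated table is
retained.  The corresponding comparison against the printed 262.21 is kept
in the test suite as a faithful record and fails by that margin (~1.5% in
log units).

Two further printed-precision artifacts are documented in the tests rather
than absorbed silently: the bridge study's one-sided factor is exactly
10.509 (the printed 10.50 pairs the correction factor with the 2-d.p.
two-sided value, 2 × 0.98890 × 5.31), and the doll study's classical log
odds ratio is exactly 2.5277 (printed as its truncation 2.52, while the
matching Wald interval rounds conventionally).

## Synthetic tables

`generate_table` draws tables that honor each design's constraints exactly:
independent Poisson cells; one multinomial over all cells given the grand
total; one multinomial per fixed row; or, for 2×2 hypergeometric designs, a
draw of the single free cell from the (noncentral, odds ratio ψ)
hypergeometric law over its enumerated support.  These generators emulate
the *sampling designs*, not any particular empirical phenomenon: real
contingency data add overdispersion, dependence between observations, and
misclassification that the generators deliberately omit, so passing tests
demonstrate correctness of the inferential machinery under each design's
own assumptions, not robustness to violations of them.  The
consistency smoke test uses two groups with success rates 0.7 vs 0.3 at
group sizes 10–160; the scaling experiments use the base tables (3,3;2,5)
(log odds ratio 0.92) and (5,5;5,5) (odds ratio 1) with factors up to 30,
matching the constructions the bundled analyses describe.

## Limitations

- Multi-way (3+ dimensional) tables, non-conjugate priors, MCMC samplers,
  HPD intervals, continuity corrections and exact (Fisher) tests are out of
  scope.
- One-sided tests are defined only for the 2×2 independent-multinomial
  design; their interaction with the other schemes is not defined by the
  underlying theory and is deliberately unsupported.
- The general hypergeometric kernel enumerates the fixed-margin fiber and is
  exponential in table size; it is intended for 2×2 and small R×C tables.
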