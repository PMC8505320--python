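# Methods

## The problem

Repeated censuses of the same plot yield a time series of communities. How
different the community is between censuses (temporal beta-diversity) is
usually measured on species composition alone, but when individuals are
tracked — forest dynamics plots, mark–recapture, bird ringing — two extra
questions open up: how fast are individuals themselves turning over
(mortality + recruitment), and does the observed pattern of *who* persists
deviate from what blind demographic chance would produce? `indbeta`
implements the individual-based index family and the persistence null model
that answer these questions.

## Data model

A `Census` is an ordered list of T census units plus, per individual, a
species label and a 0/1 occupancy vector of length T (1 = alive and counted
at that census). Collapsing individuals by species gives the
`AbundanceMatrix` x_ij (species i, unit j) with totals S_j (richness per
unit), S_T (pooled richness), I_j (individuals per unit), I_T (distinct
individuals), and T_AB = Σ_j I_j.

All components are exact integers; every index is formed as a ratio of
integers (`fractions.Fraction`) only at output time, so component identities
can be tested bit-exactly and the brute-force audits demand exact equality.

### Gap policy

Real censuses contain misses: an individual recorded, then absent, then
recorded again. The field protocols behind such data do not dictate a
single fix, so the package makes the choice explicit:

* `strict` (default) — refuse gapped vectors, naming the offenders. A gap
  silently read as a death + an (impossible) re-recruitment corrupts the
  interval flows that the null model conditions on, so the default is to
  stop.
* `fill` — set internal zeros between first and last presence to 1 and log
  how many cells were filled (the individual was presumably alive).
* `events` — leave vectors untouched. Every index is still well defined,
  but the null model rejects such censuses because a replayed census could
  not conserve the number of distinct individuals.

## Pairwise indices

For units j < k, with a/b/c the shared/unique species counts,
A/B/C = Σ_i min(x_ij, x_ik) and the column-wise complements, and P/M/R the
same construction on individual occupancy (persistent, dead, recruited):

    d_sor = (b+c)/(2a+b+c)
    d_bc  = (B+C)/(2A+B+C)
    d_mr  = (M+R)/(2P+M+R)
    v_s   = (B+C)/(M+R)

Mortality splits into individuals whose loss changed composition (B) and
those replaced by conspecifics (E_loss = M − B); recruitment likewise
(E_gain = R − C). The identities E_loss = E_gain = A − P hold for every
census (shown by expanding B = I_j − A, M = I_j − P), which gives
d_bc ≤ d_mr and v_s = d_bc / d_mr exactly — these are regression-tested
over random censuses, and d_bc is additionally cross-checked against the
SciPy Bray–Curtis distance.

v_s reads as the fraction of individual turnover that shifted composition:
0 = pure demographic churn at compositional equilibrium, 1 = every death
and recruit moved the community.

## Multiple-unit indices

The mean of pairwise dissimilarities over all T(T−1)/2 pairs double-counts
whatever is shared by three or more censuses: one long-lived tree
contributes "persistence" to every pair it spans. The multiple-unit shared
components instead count each shared element once, via inclusion–exclusion
over unit subsets (pairs − triples + quadruples − ...), which collapses to
closed forms:

    a_mu = Σ_j S_j − S_T
    A_mu = T_AB − Σ_i max_j x_ij
    P_mu = Σ_j I_j − I_T

The unique-side components symmetrize the pairwise exclusives p_jk (species
in j absent from k) and q_jk (individuals in j absent from k):
b_mu = Σ_{j<k} min(p_jk, p_kj), c_mu the max analogue, and likewise
M_mu/R_mu from q. The indices keep the x/(2·shared + x) form, and
v_s.mu = d_bc.mu / d_mr.mu.

`brute_force_shared` evaluates the alternating subset sum directly (O(2^T),
capped at T = 10) and is public API so any census can be audited; the test
and acceptance suites require exact integer agreement with the closed forms
over thousands of random censuses.

Because A_mu − P_mu = I_T − Σ_i max_j x_ij ≥ 0 and
B_mu + C_mu ≤ M_mu + R_mu pair by pair, d_bc.mu ≤ d_mr.mu and
v_s.mu ∈ [0, 1] always. That the multiple-unit indices are at least the
mean of their pairwise counterparts is, to our knowledge, an empirical
regularity rather than a theorem; it is asserted on the shipped worked
examples and on simulator output only, and holds in all of them.

## The persistence null model (P_ses.all)

Interval flows are extracted first: I_t alive per unit, D_t deaths and R_t
recruits per interval, satisfying I_{t+1} = I_t − D_t + R_t. Each
randomization replays the census with the flows held fixed: start with I_0
anonymous individuals; each interval kill exactly D_t of the currently
alive, chosen uniformly at random without replacement; add R_t brand-new
individuals (recruits are themselves mortal later). Every replicate
reproduces all I_t exactly, hence also P_mu = Σ I_t − I_T — only the
cross-interval sharing behind M_mu and R_mu, and therefore d_mr.mu, varies.
The standardized effect size is

    P_ses.all = (observed d_mr.mu − null mean) / null sd,

with the sample standard deviation (ddof = 1) over `n_rand` replicates
(default 100; raise it for a more stable sd). The SES is tagged undefined
when the null distribution is degenerate (e.g. zero flows, or T = 2 where
the flows fully determine the index, which is why at least three units are
required).

**Sign.** Under the literal definition above, an excess of long-lived
individuals *lowers* observed d_mr.mu relative to the null, giving a
negative score — this is visible already in the two-individual worked
example, where the long-lived case has d_mr.mu = 1/3 against a null mean of
17/39. Analyses in the literature have read positive values of this
statistic as excess persistence, which corresponds to the reversed
orientation (mean − observed). Both are exposed (`sign_convention=
"as_stated"` is the default, `"reversed"` negates); nothing is silently
flipped.

On the worked example's flows the null is exhaustively enumerable — the
single stochastic death falls on either of two individuals, giving exactly
two equiprobable worlds with d_mr.mu ∈ {1/3, 7/13} — and the Monte-Carlo
null mean is checked against the exact 17/39. (The example also shows that
the *mean pairwise* d_mr does not coincide between the two worlds: 1/6
vs 1/2.)

## The synthetic-census generator

`SimulationConfig` emulates a fixed-schedule forest-plot quadrat. Defaults:
8 censuses; 200 individuals initially; 20 deaths and 20 recruits per
interval (≈10% standing turnover per census interval, typical of tropical
forest plots on a 5-year schedule); a 50-species pool with geometric
ranked abundances (ratio 0.9, giving a realistic dominance structure);
recruit species proportional to current abundances (a `uniform` rule and a
`mixture` rule with immigration weight 0.1 model external seed input).
Death and recruit counts are realized exactly, lifespans are contiguous by
construction, so `interval_flows` recovers the configuration verbatim.

Mortality bias β is the one tunable that matters for the null model: the
death weight of an individual of age a (intervals since recruitment) is
(a+1)^(−β). β = 0 is uniform mortality — the generator then *is* the null
model's generative process, which is what licenses the calibration check
(mean P_ses.all across simulated censuses within 3 standard errors of 0,
sd near 1). β = 3 protects older individuals strongly enough that observed
d_mr.mu falls below the null mean in essentially every simulated census;
β → ∞ kills strictly youngest-first.

What the generator does **not** emulate: spatial structure and dispersal,
size/age-structured demography beyond the age bias, density dependence,
observation error (no gaps are generated), and species-dependent mortality.
Passing calibration therefore shows the SES machinery is unbiased under
drift with exact flows; it does not certify behavior under, e.g., spatially
clustered mortality.

## Numerical and design choices

* Integer components throughout; indices as `Fraction`s; undefined ratios
  (0/0) propagate as tagged `IndexValue`s with a reason, never as 0 or an
  exception in batch mode, so plot-level summaries stay honest.
* Pair direction: M is loss from the earlier unit, R gain in the later;
  `all_pairs` orders pairs by the declared unit order, and pair means skip
  undefined pairs while reporting their count.
* Species label conflicts across censuses: first appearance wins, with a
  warning (re-identifications occur in real plot data).
* Determinism: every stochastic routine takes a numpy `Generator` or seed;
  batch runs derive per-plot generators from one root `SeedSequence`, so a
  (seed, input) pair fixes every output byte.
* Problem sizes in the shipped checks (1000 random censuses for the oracle
  sweep, 100 simulated censuses × 100 randomizations for calibration and
  sensitivity, 500 censuses for the multiunit-vs-mean-pairwise property)
  were chosen to make the whole suite run in well under a minute per check
  on one CPU while keeping Monte-Carlo standard errors small.

## Known limitations

* Individuals are atomic: no stem counts, biomass or size weighting.
* No turnover/nestedness partition of the multiple-unit measures.
* The null model conditions on flows only; it cannot detect species-
  selective mortality that leaves flow totals and lifespans unchanged.
* `brute_force_shared` is exponential in T by design; use it for audits,
  not production batches.
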