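# Methods

This note documents the models and procedures implemented in `paleodiv`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data validation does and does
not demonstrate.

## Time bins and occurrence handling

All analyses run over an ordered `BinScheme` of contiguous time bins,
oldest first, ages in Ma. A bin is the half-open interval
`[older, younger)` with the older bound inclusive: an age lying exactly
on a boundary belongs to the bin that boundary opens. This convention is
applied uniformly — to occurrence assignment, taxon ranges, and lineage
intersection in the phylogenetic diversity estimate — and prevents any
record or lineage from being counted in two bins at once.

Two built-in schemes cover the Jurassic–Cretaceous (201.3–66.0 Ma):
a 23-bin stage-level scheme with GTS2012 stage ages, and a 14-bin
composite of approximately 10-Myr bins (J1–J6, K1–K8) assembled from
whole stages (J6 = Tithonian, K2 = Hauterivian–Barremian, K3 = Aptian).
The composite boundaries are this package's own approximation; every
function takes the scheme as an argument, so an alternative bin table
loaded with `read_bin_scheme` is a drop-in replacement.

Occurrences are retained only when assignable to a genus; duplicate
records of the same taxon in the same collection collapse to one for all
counting (they are preserved in the table itself). Under the
**constrained** policy an occurrence is kept only if its whole age range
`[age_min, age_max]` sits inside one bin; raw counts (TDE), taxon ranges
and turnover rates require this policy. Under the **unconstrained**
policy temporally uncertain occurrences are retained with their full
candidate-bin sets, and each subsampling trial independently resolves
every multi-bin occurrence to one candidate uniformly at random — the
record contributes exactly once per trial, so retaining uncertain
occurrences never double counts.

## Coverage-standardized subsampling (SQS)

Equal-size subsampling makes rich bins look poor; SQS instead
standardizes each bin to a fixed *coverage* `q` of its taxon frequency
distribution. Per bin:

1. coverage of the observed distribution is estimated by Good's
   `u = 1 − s₁/O` (`s₁` singleton taxa, `O` occurrences); an optional
   dominance correction uses `1 − s₁/(O − n_dominant)`;
2. collections are drawn in random order; each newly encountered taxon
   adds its frequency share `nᵢ/O` once;
3. drawing stops when the accumulated share reaches `q/u`, i.e. when the
   subsample covers a fraction `q` of the *true* frequency distribution;
4. the subsampled richness is the number of distinct taxa drawn, averaged
   over `trials` shuffles; the per-bin standard deviation across trials is
   reported alongside.

Defaults follow the established protocol: quorum `q = 0.4`, 1000 trials
(the plain dialect supports `replicates × trials` with per-replicate
means retained). The **throttled** dialect additionally caps each
publication at `pubs_cap = 3` collections per trial; the cap is enforced
by *skipping* a publication's surplus collections in the draw order, a
choice made so that the throttled and plain dialects agree exactly
whenever every publication contributes at most `pubs_cap` collections
(pulling a publication's collections forward instead would reorder draws
even below the cap).

Bins whose coverage is zero (all taxa singletons) or below the quorum
return an *undefined* estimate rather than a downward-biased number; this
is a feature, not a failure — a bin the record cannot support at the
requested coverage should not appear to carry information.

Tally flags: by default singleton taxa are excluded from the richness
tally and the dominant taxon is always counted, mirroring the original
protocol's variance-reduction choices on real data. For validation
experiments that compare an estimated trajectory against *true* richness,
the inclusive tally (`exclude_singletons=False`) is used instead: the
singleton exclusion deliberately biases the tally downward exactly in
sparsely sampled bins, which is orthogonal to the coverage
standardization those experiments test. Whether the dominant taxon's
share counts toward the quorum is a separate flag
(`count_dominant_share`, on by default).

## Time-scaling and phylogenetic diversity (PDE)

Supertree topologies are dated a posteriori: each internal node takes the
oldest first-appearance date (FAD) among its descendant tips; each tip
sits at its FAD. This creates zero-length branches along every path to a
locally oldest tip. Three strategies handle unresolved and zero-length
structure:

* **equal** — polytomies stay in place; each maximal run of zero-length
  branches shares, in equal parts, the duration of the first directly
  ancestral branch of positive length. Runs are processed deepest-first
  under a canonical (label-keyed) order, which makes the result invariant
  to tip input order; a run of `k` zero branches below a positive branch
  of length `L` yields `k+1` branches of length `L/(k+1)` each. A root
  stem of `root_extension` Myr (default 5; recorded in output metadata —
  the choice is arbitrary and exposed) provides slack above the root, so
  the root node may shift older.
* **random** — each polytomy is resolved by repeatedly joining random
  child pairs (uniform given the RNG), then dated basically.
* **ordered** — each polytomy becomes a caterpillar in which lineages
  branch in order of first stratigraphic appearance; identical FADs are
  ordered at random (both tie-break outcomes occur across seeds).

PDE for a bin counts every lineage whose time span intersects the bin:
a lineage runs from its parent node's age to its child node's age, and
terminal lineages extend to the tip's last appearance (tips lacking one
are point occurrences, LAD = FAD). Ghost lineages — branch segments
implied by topology but unsampled — are thereby included, so per-bin PDE
is never below the raw in-bin taxon count on matching data. A lineage
that originates and ends inside one bin counts once. The reported PDE is
the mean of the equal run and of `n_resolutions` (default 100) seeded
random and ordered runs each; it always lies inside the three methods'
envelope. Genus-level PDE collapses species tips to one lineage per genus
spanning the genus's pooled FAD–LAD (keeping only the earliest species'
own range is available behind a flag).

## Turnover rates

Both estimators consume a taxon-by-bin **range chart**: a `sampled`
matrix (at least one in-bin occurrence) and a `range_through` matrix
(filled from first- to last-appearance bin).

**Three-timer rates.** For bin *i*: `2T_bot` counts taxa sampled in
*i−1* and *i*; `2T_top` in *i* and *i+1*; `3T` in all three; `PT`
(part-timers) in the flanking bins but not *i*. The per-bin sampling
probability is `Ps = 3T/(3T+PT)`, and

    mu(i)     = ln(2T_bot/3T) + ln(Ps(i+1))
    lambda(i) = ln(2T_top/3T) + ln(Ps(i−1))

The `ln Ps` of the *following* bin corrects extinction (a taxon alive but
unsampled in *i+1* would otherwise look extinct — the Signor–Lipps
effect), and of the *preceding* bin corrects origination; a pooled-Ps
variant (one Ps from summed counts) is available as `ps_mode="pooled"`.
Estimates are undefined where any needed count is zero or Ps is 0/0, and
sampling noise can push the corrected value below zero, in which case it
is clamped to 0 and flagged. Edge bins are undefined.

**Boundary-crosser (Foote) rates.** With `N_bt` taxa crossing both
boundaries of bin *i*, `N_bL` crossing the bottom and ending within, and
`N_Ft` starting within and crossing the top:
`q = −ln(N_bt/(N_bt+N_bL))`, `p = −ln(N_bt/(N_bt+N_Ft))`.
Single-interval taxa contribute nothing. The method reads the
range-through record literally (assumes perfect sampling), which is why
under imposed undersampling its estimates drift further from truth than
the three-timer estimates — a directional property the test suite checks.
Rates are per-interval by default for the three-timer method and per-Myr
by default for Foote in configured runs, where bins are unequal;
both normalizations are flags.

## Driver model comparison

Environmental covariates are strongly autocorrelated, so each predictor
is detrended by a first-order autoregressive fit,
`x_t = c + φ x_{t−1} + ε`, estimated by conditional maximum likelihood
(least squares on the lagged pairs, conditioning on the first
observation — simple, and exact for the Gaussian conditional model);
the residuals `e_t` carry the short-term signal. The first bin's
residual is undefined; interior missing values drop pairwise. A constant
series is flagged (φ set to 0, residuals zero). Only predictors are
detrended by default; detrending the response as well is a sensitivity
flag.

Candidate models of a diversity response are the intercept-only null,
every single predictor, and every pair (`combos=2` default). Each is a
Gaussian linear fit by maximum likelihood; `k` counts intercept, slopes
and the residual variance, and models are ranked by
`AICc = −2logL + 2k + 2k(k+1)/(n−k−1)` and Akaike weights
`w_i ∝ exp(−ΔAICc_i/2)` (weights sum to 1 over the candidate set).
Undefined response bins drop listwise per candidate, so `n` can differ
between candidates and is reported per row; the null, having no
predictors of its own, is restricted to bins at least one candidate
predictor covers — otherwise its larger sample would make its likelihood
non-comparable with the predictors' fits. Candidates with `n ≤ k+1` are
skipped with a warning. The per-predictor report (one row per response ×
predictor: logL, weight, slope, Spearman ρ and Pearson r with two-sided
p-values, n) flags a predictor "strong" when it holds the top Akaike
weight and both correlation p-values fall below `alpha` (default 0.05,
configurable — significance conventions vary between studies).

## Synthetic records and what the validation shows

The generator is a discrete-bin birth–death process: `n0` taxa exist at
the scheme's older bound; in bin *i* every living taxon (including taxa
originating within the bin) goes extinct before the next bin with
probability `1 − exp(−μᵢ)`, and `Poisson(λᵢ·Nᵢ)` new taxa arise, with
`Nᵢ` the standing diversity entering the bin; origination and extinction
times are uniform within their bins, and survivors of the last bin are
censored at the scheme's younger bound. Under this birth step the
per-capita origination rate that boundary-crosser and three-timer
estimators are defined to measure is `ln(1+λ)` (the log ratio of cohort
size after to before the bin's originations), exposed as
`SimTruth.per_capita_origination`; extinction needs no mapping since the
survival probability is `exp(−μ)` by construction. Rate-recovery
experiments therefore compare μ̂ against μ* and λ̂ against `ln(1+λ*)`.

Sampling draws `Poisson(rᵢ)` occurrences per living taxon per bin,
scatters them over the bin's collections (uniform) and publications
(uniform over `pubs_per_bin`), and with probability `age_smear` widens an
occurrence's age range across the boundary with the next younger bin —
producing the temporally uncertain records the unconstrained policy
exists for. Tree topologies attach taxa in origination order, each as
sister to a uniformly chosen existing tip, so no taxon branches from a
later-originating lineage; a stated fraction of internal edges is then
collapsed into polytomies. Driver-coupled responses are
`y_t = β·e_t + u_t` with `e_t` the driver's AR(1) residuals and `u_t` an
AR(1)(φ, σ) noise process; they are centred anomalies and may be
negative.

The shipped scenario (`data/jk_scenario.yaml`) encodes a boundary-event
record on the 14-bin scheme: 40 initial taxa, origination 0.35/bin
through the Jurassic bins, an extinction spike of 0.9 at J6 over a 0.15
background, origination suppressed to 0.08 in K1–K3, and sampling
intensity 2.5 occurrences per taxon per bin except a five-fold crash
(0.5) in K1–K2, spread over 25 collections and 8 publications per bin
with a 0.3 polytomy fraction. These values are the package's fixed study
conditions for validation, chosen once to produce a realization with a
few hundred genera and a few thousand occurrences — the scale of a real
clade-level compendium.

Problem sizes used by the test suite and the acceptance script: 20
seeded scenario replicates for the subsampled-versus-raw comparison (100
trials per bin at `q = 0.4`); 20 replicates of a 10-bin, 200-taxon,
`μ* = λ* = 0.2` record at sampling intensity 5.0 (heavy) and 0.7
(undersampled) for rate recovery; 1000 seeded 5-taxon records for the
ghost-lineage dominance and branch-length sweeps; 100 replicates of the
driver-recovery experiment (`β = 0.8`, three decoy covariates, 14 bins)
and 20 series of length 500 for AR(1) recovery; one full end-to-end
pipeline run executed twice for byte-identical determinism. Trajectory
shape is compared by a scale-free L1 discrepancy (`relative_l1`): both
series are normalized by their means over the jointly defined bins before
averaging absolute differences, since subsampled richness is not on the
absolute richness scale.

What passing these checks shows: the estimators are implemented
correctly (formula oracles, exhaustive draw-order enumeration, worked
examples), are internally coherent (invariants, determinism), and
recover truth under the generator's assumptions. What they do not show:
performance on real records whose sampling is spatially structured,
whose taxonomy is inconsistent across publications, or whose age models
are correlated with facies — none of which the generator emulates. The
dataset-scale figures quoted in empirical studies of the J/K interval
require the corresponding archived occurrence datasets and supertrees,
which are inputs to, not products of, this package.

## Known limitations

* The SQS trial draws whole collections; occurrence-level draws (as in
  some implementations) are not offered.
* The equal time-scaling shares slack within runs of zero-length
  branches; likelihood-based dating (tip-dating, rate calibration) is out
  of scope, as is supertree construction itself.
* The AR(1) likelihood is conditional on the first observation, not the
  exact stationary likelihood; for the short series involved the
  difference is immaterial relative to model-selection uncertainty.
* No multiple-testing correction is applied to the per-predictor
  p-values; the report mirrors the raw-correlation convention of the
  literature it follows, and the AICc weights are the primary ranking.
* The birth–death generator is bin-discrete by design (matching the
  bin-level estimators); a continuous-time variant is not provided.
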