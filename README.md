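# paleodiv

Sampling-corrected palaeobiodiversity analysis for fossil occurrence data,
built around the workflow used to study the Jurassic/Cretaceous (J/K,
~145 Ma) crocodyliform biodiversity crash: the raw fossil record is so
unevenly sampled through time that uncorrected taxon counts mostly track
collecting effort, and any claim about a genuine extinction event has to
survive coverage standardization, phylogenetic correction, and explicit
model comparison against environmental covariates.

The package is aimed at palaeobiologists working with Paleobiology
Database–style occurrence exports (taxon, collection, publication, age
range, palaeocontinent, marine/non-marine habit) plus informal supertrees
and covariate time series. It provides:

* **TDE** — raw taxonomic diversity: per-bin counts of distinct genera
  (or species) under a documented half-open `[older, younger)` binning
  convention, with constrained (single-bin) and unconstrained
  (temporally uncertain) occurrence handling.
* **SQS** — shareholder quorum subsampling. Coverage of a bin's taxon
  frequency distribution is estimated by Good's *u* = 1 − *s*₁/*O*
  (singletons over occurrences); collections are drawn in random order
  until the summed frequency share of the taxa drawn reaches *q*/*u*,
  so every bin is standardized to the same coverage *q* of its true
  frequency distribution rather than to the same number of draws. Two
  dialects: one caps draws at three collections per publication, one
  does not.
* **PDE** — phylogenetic diversity on a-posteriori time-scaled trees:
  node ages from first appearance dates, zero-length branches resolved by
  the *equal* / *random* / *ordered* strategies, and per-bin counts of all
  lineages including ghost lineages (so PDE ≥ TDE per bin).
* **Rates** — per-interval extinction μ and origination λ by the
  three-timer method, μᵢ = ln(2T_bot/3T) + ln(Pₛ(i+1)) with the sampling
  probability Pₛ = 3T/(3T + PT) correcting Signor–Lipps smearing, and by
  Foote's boundary-crosser method, q = −ln(N_bt/(N_bt + N_bL)),
  p = −ln(N_bt/(N_bt + N_Ft)).
* **Drivers** — AR(1)-detrended environmental covariates (sea level,
  δ¹⁸O, δ¹³C, δ³⁴S, ⁸⁷Sr/⁸⁶Sr, sampling proxies) compared as Gaussian
  linear models of any diversity series, ranked by
  AICc = −2logL + 2k + 2k(k+1)/(n−k−1) and Akaike weights, with Pearson
  and Spearman correlations per predictor.
* **Synthetic records** — a discrete-bin birth–death generator with
  Poisson sampling, collection/publication clustering, age smearing,
  origination-ordered random trees and driver-coupled responses, so every
  estimator can be validated against known truth.

## Worked example

The shipped "J/K-like" scenario simulates a richness ramp, a
high-extinction bin at the end-Jurassic composite bin J6, suppressed
origination afterwards, and a five-fold sampling crash in the two
post-event bins (K1, K2):

```python
from paleodiv import (tenmyr_bins, simulate_scenario, assign_to_bins, tde,
                      SQSConfig, sqs_estimate, range_chart, timer_counts,
                      three_timer_rates)

real = simulate_scenario(seed=1)
scheme = tenmyr_bins()
binned = assign_to_bins(real.occurrences, scheme, "constrained")
raw = tde(binned)
sqs = sqs_estimate(binned, SQSConfig(quorum=0.4, trials=200, seed=1,
                                     exclude_singletons=False))
rates = three_timer_rates(timer_counts(range_chart(binned)))
print(f"{'bin':>4} {'true':>5} {'tde':>5} {'sqs':>6} {'mu_3t':>6}")
for i, b in enumerate(scheme):
    print(f"{b.label:>4} {real.truth.richness[i]:5.0f} {raw.values[i]:5.0f} "
          f"{sqs.mean[i]:6.1f} {rates.extinction[i]:6.2f}")
```

```
 bin  true   tde    sqs  mu_3t
  J1    52    50   20.6    nan
  J2    70    66   26.1   0.16
  J3    82    77   31.1   0.19
  J4    80    75   29.6   0.15
  J5    89    82   33.5   0.00
  J6    99    89   35.7   1.36
  K1    42    20    nan   0.00
  K2    38    13    nan   0.43
  K3    32    29   12.1   0.13
  K4    32    31   12.8   0.09
  K5    35    32   12.6   0.08
  K6    40    36   14.9   0.15
  K7    44    38   15.8    nan
  K8    48    40   15.8    nan
```

Reading the columns: true richness ramps to 99 genera at the event bin J6
and crashes to ~40 after it. The raw count (tde) exaggerates the crash in
K1–K2 because sampling also collapses there (20 and 13 observed of 42 and
38 alive). The subsampled estimate (sqs) refuses to report those two bins
— their coverage falls below the quorum 0.4 — instead of returning a
deflated number, and tracks the shape of the true curve elsewhere. The
three-timer extinction rate spikes at J6 (1.36 against a background of
~0.15; the generator's event rate is 0.9) and the edge bins are undefined
because the correction needs both flanking bins.

The same analyses run from the shell:

```sh
paleodiv simulate --seed 1 --out scratch/sim
paleodiv sqs scratch/sim/occurrences.csv --quorum 0.4 --trials 1000 \
    --dialect throttled --seed 1 --out scratch/sqs.csv
paleodiv rates scratch/sim/occurrences.csv --method 3t --out scratch/rates.csv
paleodiv pde scratch/sim/tree.nwk scratch/sim/dates.csv --out scratch/pde.csv
```

or as one configured, fully reproducible run (`paleodiv run config.yaml`),
which writes per-stage CSVs, a Table-1-style driver report, and a run log;
the same configuration and seed always produce byte-identical outputs.

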