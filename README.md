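# chromstate

Two-condition chromatin-state modeling and differential occupancy
statistics for epigenomics.

`chromstate` implements the computational core of a differential chromatin
analysis comparing a control and a perturbed cell population (for example,
a chromatin-remodeler knockdown) across many chromatin features — histone
variants and modifications, accessibility, and factor binding:

* **Equalized binarization.** Binned signal tracks (200-bp bins) are
  background-subtracted, converted to per-bin presence calls by a Poisson
  upper-tail test, and then *equalized*: per feature and chromosome, both
  conditions retain only their top-signal *n* calls, where *n* is the
  smaller condition's call count. This removes sequencing-depth and
  IP-efficiency bias before joint state modeling — if one condition calls
  27,000 present regions on a chromosome and the other 35,000, both keep
  exactly their top 27,000.
* **Chromatin-state HMM.** A K-state hidden Markov model with independent
  Bernoulli emissions per feature, P(x | k) = ∏_f E_{kf}^{x_f} (1−E_{kf})^{1−x_f},
  trained by Baum–Welch on both conditions *concatenated* (every
  chromosome × condition is an independent sequence sharing one parameter
  set), so state labels mean the same thing in both conditions.
* **Quantitative state-count selection.** Models fit over a range of K are
  compared against the most complex model by the median maximal Pearson
  correlation between emission rows, and by k-means on the pooled emission
  rows of all models (between-cluster / total sum of squares). The chosen
  K* is the smallest count where both criteria exceed 0.95.
* **Co-occupancy statistics.** Per-genomic-bp fold enrichment
  [observed / expected] with upper-tail hypergeometric probabilities,
  Fisher exact and chi-squared tests on 2×2 tables, replicate-consistency
  peak filtering (≥50% overlap with every replicate), enhancer
  classification (promoter-proximal within ±3 kb of a TSS; typical
  enhancers distal, accessible, outside super-enhancers), and a
  ReMap-style factor screen reporting site-level genomic odds ratios with
  OR > 2 and >0.1% overlap filters.
* **Differential occupancy.** Reads counted in consensus peak regions are
  filtered at average log2CPM ≥ −3, locally normalized by a loess fit on
  the MA representation, and tested with a moderated quasi-likelihood
  negative-binomial model; nearby regions are merged (gap ≤ 500 bp, merged
  width ≤ 5 kb, minimum member p representative) and Benjamini–Hochberg
  FDR < 0.05 defines increasing/decreasing regions.
* **Synthetic data with ground truth.** Generators for state-driven binned
  tracks in two conditions, factor catalogs with planted odds ratios, and
  NB count matrices with planted fold-changes make every stage testable
  end to end without external data.

The fit/transform-shaped stages follow scikit-learn conventions
(`BernoulliHMM`, `PoissonBinarizer`, `DifferentialAbundance`,
`StateCountSelector` — construct with hyper-parameters, `fit`, read
trailing-underscore attributes) and compose with sklearn tooling.

## Worked example

Simulate a two-condition epigenome, binarize + equalize, fit the state
model, and measure how well the truth is recovered:

```python
import numpy as np
from chromstate import (
    SyntheticScenario, simulate_chromatin, poisson_binarize, fit_hmm,
)
from chromstate.modelselect import median_max_state_correlation

scenario = SyntheticScenario(seed=1)          # 3 x 1 Mb, 8 states, 6 features
tracks, controls, truth_seg, truth_model = simulate_chromatin(scenario)

calls = [poisson_binarize(track, controls[cond])
         for (cond, feat), track in tracks.items()]

fitted = fit_hmm(calls, n_states=8, seed=11, max_iter=300, tol=1e-2)
print(f"median max state correlation vs truth: "
      f"{median_max_state_correlation(truth_model, fitted):.4f}")
```

This prints:

```
median max state correlation vs truth: 1.0000
```

meaning every true state's emission profile is recovered by some fitted
state essentially exactly (the corresponding maximum absolute emission
error, after optimally matching fitted to true states, is 0.019 at this
seed). The same pipeline is available from the shell:

```bash
chromstate simulate --out-dir sim --seed 5 --n-states 4 --n-features 4
chromstate binarize --track control feat1 sim/control.feat1.bedGraph ... \
    --chrom-sizes sim/chrom.sizes --out-dir calls
chromstate fit --calls calls/control.binary.txt --calls calls/depleted.binary.txt \
    --n-states 4 --seed 1 --out model.json
chromstate select --model model_5.json --model model_6.json ... --out criteria.tsv
```

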