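# skewsort

Automatic spike sorting for single-channel extracellular recordings, built
around two ideas: an **adaptive detection** stage that cleans and aligns
threshold-detected waveforms, and clustering by a **finite mixture of
multivariate skew-t distributions** whose component count is chosen
automatically.

It is written for electrophysiologists and methods researchers who need a
fully scriptable sorter — no manual curation in the loop — together with a
ground-truthed synthetic-recording simulator and the evaluation metrics to
score every stage against that truth.

## The method

A raw trace `r(t) = l(t) + s(t) + n(t)` (field potentials, spikes, noise)
is band-passed to 300–3000 Hz with a zero-phase fourth-order Butterworth
filter. The noise level is estimated robustly,

    sigma_n = median(|r_f|) / 0.6745,

and a spike is triggered when `m_d + 1` successive samples fall below
`-3 sigma_n`; each event then snaps to the first local minimum with no
smaller value in the next millisecond. Detected windows pass through

* **statistical filtering** — a window is discarded when, in `sigma_n`
  units, `|mean| > 1` or `std > 3` (noise and artifact windows masquerading
  as spikes), and
* **multi-point alignment** — waveforms are grouped by dominant extremum,
  a cubic smoothing spline is fitted to the histogram of extremum
  positions, and each waveform may shift up to `m_shift` samples onto the
  nearest of the `m_peak` largest histogram peaks.

Waveforms are projected onto the smallest number of principal components
explaining 95% of variance (capped at 15). Clusters are modelled as a
g-component mixture of multivariate skew-t densities

    ST_p(y | mu, Sigma, lam, v)
        = 2 t_p(y | mu, Sigma, v)
          T( sqrt((v+p)/(v+d)) lam' Sigma^(-1/2) (y-mu) | v+p ),

fitted by EM (closed-form E and M steps in the (Delta, Gamma)
parameterisation; shared degrees of freedom `v` by bounded 1-D search).
Heavy tails absorb outliers; the skewness vector `lam` absorbs the
asymmetric clusters produced by near-threshold units whose weak spikes are
truncated by detection. The number of units is found by a backward search:
fit at `g_max` from a fuzzy-c-means start, repeatedly delete the
lowest-weight component and refit, then keep the order with the best
selection score (BIC by default).

Sorting quality is scored by precision/recall of 1 ms one-to-one spike-time
matching, dominant-neuron accuracy and purity, and a single sorting index —
a normalised mutual information between true and predicted labelings in
which false alarms form a hypothetical extra true cluster and misses are
randomised over predicted clusters.

## Worked example

```bash
# one 60-second synthetic session, four Poisson neurons at 15 dB
skewsort simulate --sessions 1 --snr 15 --duration 60 --seed 1 --out data/

# sort it with the full pipeline
skewsort sort --input data/session000_snr15.bin --mode full --seed 1 --out sorted/

# score against the ground truth
skewsort eval --pred sorted/labels.csv --truth data/session000_snr15.truth.csv \
              --out report.json
```

The `sort` step prints, for this seed,

```
sorted 6938 spikes into 5 cluster(s); artifacts in sorted/
```

and `eval` prints

```
precision=0.9862 recall=0.7873 accuracy=0.6768 purity=0.6970 ssi=0.2664 g_est=5 g_true=4
```

meaning: 98.6% of reported events sit within 1 ms of a true spike; 78.7% of
true spikes were recovered (the weakest unit's troughs sit near the
detection threshold at this noise level); 67.7% of matched spikes received
their true unit under the dominant-neuron mapping; and the combined
detection-plus-clustering index — which also charges every miss and false
alarm — is 0.27. Python users get the same results
from `skewsort.run_pipeline` / `skewsort.evaluate_sorting`; the fitted
mixture is a results object with a statsmodels-style `summary()`.

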