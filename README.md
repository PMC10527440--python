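# cchp — EEG channel selection by correlation of Hjorth parameters

`cchp` implements CCHP (Correlation Coefficient of Hjorth Parameters), a
filter-style channel-selection method for EEG-based mental-stress
classification, together with the surrounding pipeline: stress/calm
labelling from valence/arousal self-reports, multi-domain feature
extraction on the selected channels, and cross-validated classifier
evaluation. It is aimed at researchers who want to reduce a dense scalp
montage (e.g. 32 channels) to a small, subject-independent channel set
before building a stress classifier or a wearable prototype.

## The method

Each trial of each channel is summarised by the three time-domain Hjorth
descriptors

- activity `A = var(x)`,
- mobility `M = sqrt(var(Δx) / var(x))` (a mean-frequency proxy),
- complexity `C = M(Δx) / M(x)` (a bandwidth proxy; 1 for a pure sine),

which are z-scored feature-wise across a subject's trials. Selection then
balances two correlations built on the (A, M, C) table:

- **redundancy** — a within-class channel–channel correlation. For channels
  S, K and class x ∈ {stress, calm}:

      P_x(S,K) = [cov(A_S,A_K) + cov(M_S,M_K) + cov(C_S,C_K)]
                 / [σ(A_S)σ(A_K) + σ(M_S)σ(M_K) + σ(C_S)σ(C_K)]

  pooled over the two classes as `Ch̄(S,K) = (P_s + P_c) / 2`;

- **relevance** — a channel–class correlation `Ch̄_q`: per descriptor, the
  point-biserial (Pearson) correlation with the binary stress indicator
  across all labeled trials, averaged in absolute value over the three
  descriptors.

A subset of k channels is scored by the correlation-feature-selection merit

    E = k · r_cf / sqrt(k + k(k−1) · r_ff)

with `r_cf` the mean relevance and `r_ff` the mean absolute pooled pair
correlation inside the subset; a greedy best-first forward search grows each
subject's subset until the merit stops improving. (An alternative printed
form of the merit, `k·r_cf / (k + k(k+1)·k·r_ff)`, is available as
`merit_mode="literal"`; see `docs/methods.md` for why it is not the search
default.) Finally, channels are ranked by how many subjects selected them,
and those selected by at least `f_thr` subjects (default: half) form the
**general optimal channel set**, truncated to `n_max` (default 8).

Downstream, each 60-s trial is cut into 16 contiguous 480-sample segments
and every (segment, channel) yields a 20-feature vector — line length,
peak-to-peak, kurtosis, skewness, the three Hjorth descriptors, five
relative Welch band powers (theta 4–8, low alpha 8–12, high alpha 12–15,
low beta 15–20, high beta 20–30 Hz, as % of 4–45 Hz power), six db4
wavelet detail energies, spectral entropy and Katz's fractal dimension —
evaluated by RBF-SVM (C=1), 10-NN and eigen-solver LDA under subject-wise
stratified 10-fold cross-validation (precision, recall, accuracy; stress
positive).

A synthetic-data module generates band-limited (4–45 Hz) 1/f-background
recordings in the standard 32-channel / 40-trial / 60-s / 128 Hz shape,
with a configurable set of *planted* channels whose Hjorth signature
differs between the classes — so the whole pipeline is testable without
any gated dataset.

## Worked example

`examples/03_channel_selection.py` simulates five subjects sharing three
planted channels (Fp1, AF3, F7) at effect size 2 and runs the selection
stage:

```
planted channels: ('Fp1', 'AF3', 'F7')
  sim00: selected ['F7', 'AF3', 'Fp1'] (merit 1.500)
  sim01: selected ['F7', 'AF3', 'Fp1'] (merit 1.477)
  sim02: selected ['Fp1', 'F7', 'AF3'] (merit 1.493)
  sim03: selected ['Fp1', 'AF3', 'F7'] (merit 1.524)
  sim04: selected ['AF3', 'Fp1', 'F7'] (merit 1.658)
occurrence counts: {'Fp1': 5, 'F7': 5, 'AF3': 5}
general optimal channels: ['Fp1', 'F7', 'AF3']
```

Every subject's greedy search keeps exactly the three planted channels
(merit ≈ √3 · r_cf since they are mutually uncorrelated), each therefore
occurs in 5 of 5 subjects, and the occurrence-ranked general optimal set
is the planted set. The other examples cover labelling
(`01_simulate_and_label.py`), the Hjorth descriptors
(`02_hjorth_parameters.py`), features + classification
(`04_features_and_classification.py`) and the one-shot pipeline
(`05_full_pipeline.py`).

The same stages are exposed as a CLI (`cchp simulate | annotate | hjorth |
select | extract | classify | run`); `cchp run --config config.yaml`
executes everything end to end and writes JSON/CSV reports that embed the
full configuration. `scripts/convert_deap.py` converts a locally licensed
copy of the DEAP preprocessed archive into the package's matrix format.

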