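# timma

Target inhibition modeling for rational anticancer drug combinations.

Multi-target kinase inhibitors kill cancer cells by blocking survival
pathways through *sets* of targets, and their promiscuity is information:
every drug tested on a cancer sample reports the efficacy of inhibiting one
particular target combination. `timma` turns a panel of single-drug
screening results — a drug × target binding profile matrix and a scalar
efficacy per drug (scaled IC50, activity area, or drug sensitivity score) —
into predictions for *untested* target and drug combinations, and into an
interpretable target inhibition network for the cancer cell type at hand.
It is aimed at computational biologists and translational researchers who
have drug sensitivity screens plus target profiling (e.g. kinome-wide Kd
assays) and want to prioritize combinations for experimental follow-up.

## The model

Let `X ∈ {0,1}^(n×m)` hold binarized target inhibition profiles for `n`
drugs over `m` targets, and `y ∈ [0,1]^n` the min–max scaled efficacies.
For a queried inhibition state `T` over a selected target set `S*`:

1. **Identical-set rule.** If training drugs with profile exactly `T`
   exist, predict the mean of their efficacies.
2. **Maximization rule (lower bound).** Among drugs whose profiles are
   subsets of `T`, take the most efficacious drug `k_max`; average its
   efficacy with those of subset-profile drugs that are supersets of
   `T(k_max)` yet less efficacious. Inhibiting a superset of a successful
   drug's targets cannot do worse.
3. **Minimization rule (upper bound).** Symmetrically from
   superset-profile drugs via the least efficacious drug `k_min`.
   Inhibiting a subset of an unsuccessful drug's targets cannot do better.

The prediction is the average of the available bounds; a state with
neither bound is non-identifiable. The cancer-specific target set `S*` is
selected by minimizing the mean absolute leave-one-out (LOO) prediction
error with a sequential forward floating search (SFFS): forward inclusions
plus conditional backward exclusions that are kept only when they beat the
best error previously seen at that cardinality. A probabilistic
subset/superset-averaging baseline (PKIM, after Pal & Berlow) with greedy
forward selection is included for benchmarking.

Downstream of the fitted model:

- **Synergy**: `S(A,B) = y_AB − (y_A + y_B − y_A·y_B)` (Bliss independence
  on the efficacy scale; pure product null available), extended to drug
  pairs by averaging over their cross target pairs.
- **Synthetic lethality**: compares the fit (within-group total sum of
  squares) of parallel vs series vs singleton pathway structures for a
  target pair; `score = min(TSS_series, TSS_singleton)/TSS_parallel`.
- **Target inhibition network**: binarize the predicted efficacy function,
  take prime implicants (minimal effective target sets) and their minimal
  hitting sets; the result is a family of parallel survival pathways such
  that a target set is effective iff it hits every pathway. Exported as
  GraphML and DOT.
- **siRNA validation**: replicate QC with an edge-well rule, single
  knock-down normalization and synergy scoring of measured pairwise
  knockdowns on the same null, for comparing predictions against screens.

## Worked example

```python
import pandas as pd
from timma import TimmaRegressor, synergy_target_pair, build_inhibition_network

X = pd.DataFrame(
    {"ALK": [1,1,0,0,1,0], "MEK1": [0,1,1,0,1,1],
     "CSF1R": [0,0,1,1,0,1], "GAK": [0,1,0,1,0,0]},
    index=["crizotinib","tae684","sorafenib","erlotinib","lapatinib","sunitinib"])
y = pd.Series([0.32,0.95,0.50,0.05,0.90,0.48], index=X.index)

est = TimmaRegressor().fit(X, y)
print(est.selected_targets_, round(est.loo_error_, 4))
M = est.efficacy_matrix()
print(M.to_pairwise_frame().round(3))
print(round(synergy_target_pair(M, "MEK1", "ALK"), 3))
print(build_inhibition_network(M, 0.9).pathways)
print(est.predict(pd.DataFrame([[1,1,1,0]], columns=X.columns)))
```

prints

```
('MEK1', 'ALK') 0.0963
       MEK1    ALK
MEK1  0.490  0.925
ALK   0.925  0.320
0.272
[['MEK1'], ['ALK']]
[0.925]
```

The floating search keeps two of the four candidate targets, at a mean LOO
error of 0.0963. The pairwise efficacy matrix (diagonal = single-target
inhibition, off-diagonal = joint inhibition) predicts that inhibiting MEK1
or ALK alone achieves 0.49 and 0.32 of the maximal efficacy, while joint
inhibition reaches 0.925 — a synergy of 0.272 above the Bliss expectation.
At an effectiveness threshold of 0.9 the network therefore consists of two
parallel single-node pathways, MEK1 and ALK: both must be hit. A
crizotinib + sorafenib combination (union profile inhibiting ALK, MEK1 and
CSF1R) is predicted at 0.925.

The same workflow is available from the shell via the `timma` command
(`timma binarize`, `timma select`, `timma matrix`, `timma synergy`,
`timma sl-score`, `timma network`, `timma bench sweep`, `timma sirna`,
`timma pipeline`); `timma pipeline` persists all intermediates together
with a manifest of the resolved configuration.

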