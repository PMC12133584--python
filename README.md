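# cpmkit

Connectome-based predictive modeling (CPM) of behavioral outcomes from
functional connectivity, with the diagnostics that matter when such models
fail: permutation inference, virtual network lesioning, a misclassification
index with covariate dissection, and the inverted-model experiment.

CPM is the workhorse of individual-difference prediction in network
neuroscience: given per-subject parcel-by-parcel functional-connectivity
matrices and a behavioral score (for example NIH Toolbox cognition composites
in early psychosis), it selects the edges whose connectivity correlates with
the outcome across training subjects, compresses them into a single
connectivity-strength summary score, and fits a linear model from score to
outcome. `cpmkit` implements that pipeline end to end and, because the
clinical datasets this kind of analysis targets are access-restricted, ships
a synthetic-connectome generator that reproduces the statistical structure
the pipeline assumes — including a *discordant* subgroup whose brain-behavior
coupling is sign-inverted, the mechanism behind systematic misprediction.

## The model

For a training set of *n* subjects with edge vectors *c<sub>i</sub>* and
outcomes *y<sub>i</sub>*:

1. **Feature selection.** For every edge *e*, the Pearson correlation
   *r<sub>e</sub>* between *c<sub>ie</sub>* and *y<sub>i</sub>*, with the
   two-sided p from the t transform (*n*−2 df). Edges with *p* < θ
   (default θ = 0.01) form the **positive** (*r* > 0) and **negative**
   (*r* < 0) feature sets.
2. **Summary score.** *s<sub>i</sub>* = Σ<sub>e∈pos</sub> c<sub>ie</sub> −
   Σ<sub>e∈neg</sub> c<sub>ie</sub> (or one set alone).
3. **Linear model.** OLS of *y* on *s*; test subjects are scored with the
   training-set masks and coefficients, and accuracy is the Pearson r between
   predicted and observed outcomes, averaged over 100 unique 70/30
   train/test splits.
4. **Inference.** Outcomes are permuted over subjects and the whole
   cross-validated pipeline is rerun per permutation; p is the proportion of
   permuted mean accuracies exceeding the observed one, Bonferroni-corrected
   over outcomes.

On top of this sit **virtual lesioning** (drop all edges incident to one of
the 12 Gordon networks, rerun everything with matched splits, and summarize
the per-split accuracy change), the **misclassification index** (how often a
subject's low/high-scorer class is predicted wrongly by a linear SVM over the
summary scores, across leave-one-out rounds with subsampled training sets),
its dissection against clinical/sociodemographic covariates, and the
**inverse model** (train on correctly classified subjects, apply to
frequently misclassified ones with summary-score signs negated — exactly
flipping the sign of the accuracy).

## Worked example

```python
from cpmkit import SplitScheme, generate, permutation_test, preset, run_cpm

cfg = preset("tiny", seed=7)            # 24 subjects, 20 parcels, 4 networks
conn, behavior, truth = generate(cfg)
y = behavior.outcome("total")

scheme = SplitScheme(n_splits=50, train_fraction=0.7, seed=7)
result = run_cpm(conn, y, scheme, p_threshold=0.05, score_mode="combined")
null = permutation_test(conn, y, scheme, p_threshold=0.05,
                        n_permutations=200, observed=result)

print(f"mean prediction accuracy r = {result.mean_r:.2f} "
      f"over {scheme.n_splits} splits ({result.n_failed_splits} skipped)")
print(f"permutation p {null.p_label} ({null.n_permutations} permutations)")
```

prints

```
mean prediction accuracy r = 0.40 over 50 splits (0 skipped)
permutation p 0.01 (200 permutations)
```

meaning: across 50 held-out test sets, predicted and observed outcomes
correlate 0.40 on average, and only 1% of label permutations reach that
accuracy by chance — the planted brain-behavior signal is detected.

The same chain is available from the shell:

```bash
cpmkit generate --preset tiny --seed 7 --out-dir data/tiny
cpmkit run-all --connectomes data/tiny/connectomes --atlas data/tiny/atlas.tsv \
    --behavior data/tiny/behavior.tsv --outcomes total --seed 7 \
    --p-threshold 0.05 --fast --out-dir results/tiny
```

which writes per-stage TSV tables (accuracy per split, permutation summary,
12-network lesion tables, per-subject MI, covariate dissection, inverse-model
results) plus a `config_echo.yaml` that reproduces the run bit for bit.

## Layout

| module | contents |
| --- | --- |
| `cpmkit.io` | connectome/atlas/behavior containers, edge vectorization, text I/O |
| `cpmkit.core` | selection, summary scores, fit/predict, split CV, external validation |
| `cpmkit.inference` | permutation test of mean accuracy, Bonferroni correction |
| `cpmkit.lesioning` | virtual network lesioning, selection-fraction matrices |
| `cpmkit.misclassification` | median split, MI, covariate dissection, partial-r accuracy |
| `cpmkit.inverse` | inverted-model experiment |
| `cpmkit.synthetic` | planted-signal generator, presets, fixture writer |
| `cpmkit.cli` | `cpmkit` subcommands and run orchestration |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
what the synthetic benchmarks do and do not establish.
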