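# solcurate

Curation and weighted evaluation of multi-source aqueous solubility
datasets — and a test bench for the ways sloppy curation and careless
statistics flatter a model.

## The problem

Public logS (log mol/L aqueous solubility) compilations are aggregates of
heterogeneous sources. The same compound appears under different SMILES
texts — salt forms, ionized vs. neutral species, records with and without
stereochemistry — and the same measurement is re-imported through several
publications. Three things go wrong downstream:

1. **Duplicate leakage.** When cross-validation splits *records* rather
   than *molecules*, a duplicated compound can sit in training and
   evaluation simultaneously, deflating the measured error.
2. **Incomparable metrics.** Weighted error metrics are attractive for
   training but not comparable to the plain RMSE. With record weights
   w_i, this package computes

   ```
   RMSE   = sqrt( Σ (ȳ_i − y_i)² / n )
   cuRMSE = sqrt( Σ (w_i·(ȳ_i − y_i))² / n )
   ```

   so a molecule split into two records of weight ½, each with error 0.6,
   scores cuRMSE 0.3 against RMSE 0.6. Reports here never mix the two
   columns.
3. **Hyperparameter overfitting.** Selecting a tuning knob on the same
   held-out folds that produce the reported error biases the estimate low.
   The remedy is nested validation: re-run the *entire* development
   procedure (tuning included) inside each outer fold.

`solcurate` implements the curation pipeline (structure standardization,
InChI-connectivity-key deduplication at 0.01 log-unit precision,
non-standard-condition filtering at 25 ± 5 °C / pH 7 ± 1, metal and
single-heavy-atom removal, intra-set weighting of 1/records-per-molecule,
and cross-set merging of values within d = 0.5 log units using
source-quality weights), the evaluation machinery (by-molecule and
by-record 10-fold CV with a 0.81/0.09/0.10 train/early-stop/eval split,
bootstrap confidence intervals, paired t-test model comparison, nested
validation), and a synthetic multi-source generator with known ground
truth and an exact duplicate log, so the whole pipeline is testable
without downloads, GPUs, or proprietary data.

## Worked example

Run the bundled demo pipeline (three synthetic sources, one with 30%
representation-variant duplicates):

```bash
solcurate run --seed 7 --out demo/
cat demo/report.txt
```

```
solcurate run (seed 7)
injected duplicate records: 150
detected duplicate records: 163

model       split policy  metric      value   CI low  CI high
ridge       by_molecule   rmse        0.646    0.604    0.680
ridge       by_molecule   curmse      0.337    0.307    0.366
memorizer   by_molecule   rmse        1.075    1.013    1.144
memorizer   by_molecule   curmse      0.562    0.508    0.615
ridge       by_record     rmse        0.643    0.606    0.679
ridge       by_record     curmse      0.333    0.305    0.362
memorizer   by_record     rmse        0.758    0.719    0.803
memorizer   by_record     curmse      0.434    0.393    0.482
```

Reading it: the curation stage detected all 150 injected duplicates (plus
13 sampling coincidences where a molecule was independently re-measured to
the same rounded value). The *memorizer* — a look-up table keyed on the
molecule's connectivity key, built to exploit leakage maximally — scores
RMSE 0.758 under a by-record split versus 1.075 under a by-molecule split:
almost a third of its apparent skill under record splitting is leaked
duplicates, not chemistry. The honest ridge baseline barely moves between
policies (0.643 vs 0.646). And in every row cuRMSE is about half of RMSE,
purely because intra-set weighting put weights of ½ or less on duplicated
molecules — the two columns measure different things and must never be
compared to each other.

The same machinery is available as a library
(`solcurate.curation.clean_pipeline`, `solcurate.evaluation.cross_validate`,
`solcurate.evaluation.nested_validation`, ...) and as CLI subcommands
`simulate`, `clean`, `curate`, `split`, `evaluate`, `compare`.

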