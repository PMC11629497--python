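# Methods

This note documents the models, procedures and numerical choices behind
`solcurate`, in the order data flows through the package.

## Structure standardization and identity keys

Every structure passes a fixed sequence: RDKit parse and sanitize;
de-salting that keeps the fragment with the most heavy atoms (ties broken
by the lexicographically smallest canonical SMILES, so the choice is
deterministic and independent of fragment order); optional charge
neutralization; canonical SMILES and standard InChIKey emission.

Two identities are derived from the InChIKey:

* **full key** — the complete key, stereo- and protonation-aware;
* **connectivity key** — the first 14-character block, which encodes the
  molecular skeleton only. Stereoisomers, ionized/neutral forms and
  de-salted salt forms of one compound share a connectivity key.

The connectivity key is the unit of identity for deduplication, intra-set
weighting, and by-molecule data splitting. Implementing the
"non-stereochemical part" of the key as the first block is standard: that
block is computed from the connectivity layer of the InChI alone.

Neutralization is **off** by default: downstream featurization tolerates
charged species, and pattern-based neutralization occasionally produces
molecules the toolkit cannot re-sanitize. When it is enabled and fails,
the record is kept un-neutralized, flagged and logged — never silently
dropped. The neutralization SMARTS targets atoms with a formal charge not
balanced by an adjacent opposite charge, so zwitterions survive.

The organic-element set (H, B, C, N, O, Si, P, S, Se, halogens, noble
gases) is configurable; anything outside it counts as a metal.
Classification order matters only for multi-fragment inorganic complexes
(e.g. an aluminium trichloride record), which de-salt to a single metal
atom: these are classified `metal_containing`, while genuine single-atom
species (`[Mo]`, methane, `[Mg+2]`) are `single_heavy_atom` — both are
unusable by graph models, but the accounting keeps the two causes apart.

## Cleaning rules (per set)

Stages, each with exact record accounting (`input = output + Σ removals`):

1. **Parse failures** removed.
2. **Condition filter**: records whose temperature or pH is present and
   outside 25 ± 5 °C or 7 ± 1 are removed. Missing metadata passes —
   compiled records mostly carry none, and discarding them would empty
   the set.
3. **Deduplication**: within a connectivity-key group, scanned in stable
   input order, a record is dropped when an already-kept record's value is
   less than 0.01 log units away (the earlier record survives). The
   0.01-log-unit comparison is on **raw** values; rounding
   (round-half-to-even on the decimal representation, for platform
   reproducibility) is used only when constructing explicit duplicate
   keys. Removals with identical raw values are counted `exact_duplicate`,
   the rest `near_duplicate`.
4. **Non-organic removal**: metals and single-heavy-atom species, counted
   separately.
5. **Intra-set weighting**: each record gets weight 1/(records per
   molecule), so each molecule carries total weight exactly 1.

## Cross-set curation

Each record first carries a user-supplied source-quality weight in (0, 1]
— quality is judged externally and is configuration, never inferred. Each
analyzed set is extended with the other sets' records for molecules it
contains. Within a molecule's pooled record group, merging is greedy:
records are ordered by descending weight (ties by value, then record id);
the current seed absorbs every unmerged record within d = 0.5 log units of
it (the conventional estimate of experimental accuracy for solubility);
absorbed members form one record whose value is the weight-weighted mean.
Greedy seeding makes chains that straddle d deterministic; the procedure
is insensitive to input row order by construction.

The merged record's weight is the **maximum of member weights capped at
1** by default — monotone, bounded, and never worse than the best member.
`sum_capped` (Σw capped at 1) and `mean` are available where a different
convention is wanted.

## The weighted error metric

```
RMSE   = sqrt( Σ (ȳ_i − y_i)² / n )
cuRMSE = sqrt( Σ (w_i·(ȳ_i − y_i))² / n )
```

The record weight scales the record's error; the divisor is the record
count n, not Σw. Consequences, both deliberate and both documented
prominently wherever results are printed:

* with unit weights cuRMSE equals RMSE exactly;
* a molecule split into k records at weight 1/k contributes a k-fold
  smaller error on the RMSE scale than the same molecule measured once —
  the canonical example being two records at weight ½ with error 0.6,
  which score cuRMSE 0.3 against RMSE 0.6.

That deflation is why cuRMSE values are never comparable to RMSE values,
and why every report in this package keeps them in separate labelled
columns. The challenge score `1000000·(2 − RMSE)` is provided for
completeness as a display transform of RMSE only.

## Fold assignment

Folds must be deterministic, insensitive to input order, reusable across
models, and — under the by-molecule policy — must keep all records of one
connectivity key together. Keys are ordered by a stable 64-bit hash
(first 8 bytes of SHA-256 of `key|seed`) and dealt into n contiguous
blocks, so fold sizes differ by at most one key. A pure `hash mod n`
assignment would make fold sizes multinomial (±3% at n = 1000); the
hash-rank construction keeps every determinism property and yields exactly
balanced folds, which is what makes the 0.81/0.09/0.10 role fractions hold
to integer rounding. Within each outer fold's training portion, a second
hash (`key|seed|inner{k}`) sets aside 10% of keys for early stopping —
also molecule-aware, so early-stop leakage cannot occur either.

## Bootstrap, comparison, nested validation

Confidence intervals are percentile bootstrap over **records** (not
molecules), B = 1000 by default, deterministic per seed. Model comparison
is a paired two-sided t-test on per-record squared errors, defined only
for tables covering identical record sets (i.e. identical folds);
zero-variance differences are handled explicitly (all-equal → p = 1,
constant shift → p = 0). The pairing unit is the record because shared
folds make per-record errors directly comparable.

Nested validation implements the two-step protocol: the final model is
built on all data by an opaque `model_builder` that encapsulates the whole
development procedure — internal splits, early stopping, any tuning — and
its accuracy is estimated by re-running that builder from scratch on each
of n−1 subset unions and pooling predictions on the held-out subsets. With
a builder that tunes nothing the protocol coincides exactly with plain
n-fold CV (verified in the tests). The negative control in the acceptance
suite tunes a knob whose candidates differ only through sampling noise:
selecting it on the final evaluation folds produces a visibly lower
(overfitted) estimate than the nested protocol, averaged over ten seeds.

## The synthetic generator

The generator emulates the redundancy structure of real compilations, not
their chemistry:

* **Universe**: molecules assembled by concatenating one scaffold with 0–3
  substituents from a ~35-fragment library, validity checked by parsing,
  uniqueness enforced on the connectivity key.
* **Truth**: logS is a fixed linear function of five descriptors (heavy
  atoms, aromatic rings, H-bond donors, H-bond acceptors, heteroatom
  fraction) with coefficients (−0.30, −0.40, 0.35, 0.25, 2.0), spanning
  roughly −8 to 0 log mol/L. This gives a smooth learnable signal with a
  known noise floor; it is not solubility physics.
* **Sources** sample molecules with replacement (so molecules recur across
  sources), add per-source Gaussian noise and calibration bias, and round
  to 0.01 log units. Default noise is 0.5 log units — the commonly quoted
  experimental accuracy of solubility measurements.
* **Duplicates**: a configured fraction of records are copies of an
  existing record with the same value and a variant text: appended
  counterion (Na⁺/Cl⁻/K⁺), toggled carboxylic-acid/amine protonation,
  stereo markers stripped or added at an unassigned center. A variant kind
  that does not apply to a structure falls back to a verbatim copy,
  logged. Duplicate counts are exact by construction
  (`round(dup_fraction·n)`), and every duplicate carries a pointer to its
  original — the generation log is the oracle against which duplicate
  detection is tested.
* **Inorganic fixtures**: a configurable fraction of records draw from a
  hard-coded metal/single-atom list; their values are drawn from
  Normal(−1, 1.5) since the linear truth does not apply to them.

What passing tests on this generator do **not** show: performance on real
chemical space (fragment-concatenated molecules are far simpler than drug
like compounds), robustness to tautomer-level duplicates (not generated,
and tautomer canonicalization is out of scope), or behaviour under
source-specific systematic drift beyond a constant bias.

## Problem sizes and determinism

All randomness flows from explicitly passed seeds; the pipeline derives
stage seeds from one master seed via stable labels, so a run is
reproducible from (config, seed) alone and single stages can be replayed.
The test and acceptance workloads use universes of 50–250 molecules and
compilations of 150–2000 records with 10-fold CV — sizes at which every
statistical check (noise-floor recovery at n = 2000, leakage gaps at 30%
duplication, ten-seed nested-validation averages) is stable while the full
suite runs in well under a minute on one CPU.

## Known limitations

* De-salting keeps the largest fragment; genuinely multi-component
  records (co-crystals, mixtures) are misrepresented by design.
* The greedy merge's handling of value chains straddling d is a
  documented tie-break, not a statistical model; a weighted consensus
  across drifting sources would need an explicit drift model, which is
  out of scope.
* Quality weights are taken as configuration; the package deliberately
  provides no way to estimate them from model performance.
* The memorizer is a diagnostic instrument, not a baseline anyone should
  deploy: its sole purpose is to bound duplicate leakage from above.
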