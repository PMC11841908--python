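# surveybbn

Discrete Bayesian belief networks for trust-level patient-experience survey
data, with a calibrated synthetic-data generator.

National maternity-experience surveys are summarized per NHS trust as mean
scores (0–10) over eight care sections — from the start of antenatal care
(S1) through labour and birth (S4), staff caring (S5), and care after birth
(S6–S8). `surveybbn` models the joint behaviour of these section scores with
a discrete Bayesian network: each section becomes a node with two or three
ordered states, arcs are learned from data, and the fitted network supports
exact probabilistic queries, cross-validated prediction of any section, and
"what if" sensitivity analysis (e.g. *if the probability of high staff-caring
scores doubled, how would labour-and-birth scores respond?*).

Because trust-level survey microdata is not generally redistributable, the
package ships a synthetic generator calibrated to published summary
statistics: per-section means and standard deviations, the section-level
Pearson correlation matrix, per-section Cronbach-alpha reliabilities (used to
build item-level blocks with compound-symmetry correlation), and a 7%
missing-completely-at-random mask applied over the 122 × 8 trust-by-section
table. Every analysis in the package runs identically on a real table
supplied as CSV.

## What is in the box

| Module | Contents |
| --- | --- |
| `surveybbn.synth` | Gaussian section-score generator, Spearman–Brown inversion for item blocks, exact-count MCAR injection, nearest-correlation (PSD) repair |
| `surveybbn.preprocess` | mean imputation, Cronbach alpha, descriptives, Pearson correlations |
| `surveybbn.discretize` | equal-width / equal-frequency / 1-D k-means binning, silhouette-based 2-vs-3 state selection, reusable binning specs |
| `surveybbn.bbn` | network representation, CPT fitting with Laplace smoothing, BDeu scoring, exact inference by variable elimination with hard and virtual (soft) evidence, BIF and text serialization, forward sampling |
| `surveybbn.learn` | Bayesian Search (hill climbing + restarts), Greedy Thick Thinning, and the PC algorithm (G² tests, v-structures, Meek rules, DAG extension) |
| `surveybbn.validate` | stratified k-fold cross-validation, confusion matrices, rank-based (Mann–Whitney) AUC incl. one-vs-rest |
| `surveybbn.sensitivity` | doubling interventions via virtual evidence or graph surgery, influence ranking, one-at-a-time CPT perturbation scans |
| `surveybbn.pipeline` / `surveybbn.cli` | end-to-end pipeline (generate/load → impute → discretize → learn 3 schemes × 3 algorithms → validate → sensitivity) and the `surveybbn` command-line interface |

## Worked example

```python
from surveybbn import (GeneratorConfig, generate_survey, impute_mean,
                       reliability, apply_scheme, LearnConfig, learn_structure,
                       fit_cpts, make_folds, cross_validate,
                       accuracy_from_confusion, influence_scan)

# 1. synthesize a trust-level survey table (122 rows, 8 sections, 7% MCAR)
raw = generate_survey(GeneratorConfig(seed=42), with_items=True)
print(f"{raw.n_rows} rows x {len(raw.columns)} item columns, "
      f"{raw.n_missing()} missing cells")

# 2. impute and check internal consistency
clean = impute_mean(raw)
print(reliability(clean).table.round(2).to_string(index=False))

# 3. discretize the section scores and learn a structure
sections = impute_mean(generate_survey(GeneratorConfig(seed=42)))
disc = apply_scheme(sections, scheme="mixed", method="equal_width")
structure = learn_structure(disc, LearnConfig(algorithm="GTT", seed=0))
print("arcs:", structure.arcs)

# 4. cross-validate prediction of staff caring (S5)
plan = make_folds(disc.n_rows, 10, disc.codes["S5"].to_numpy(), seed=0)
report = cross_validate(disc, structure, "S5", plan)
pct, rounded = accuracy_from_confusion(report.confusion)
print(f"10-fold accuracy {pct:.1f}% (~{rounded}%), AUC {report.auc:.2f}")

# 5. doubling-intervention sensitivity scan
net = fit_cpts(structure, disc)
print(influence_scan(net).ranking.round(2).to_string())
```

Output:

```text
122 rows x 50 item columns, 427 missing cells
section  n_items  alpha  acceptable
     S1        7   0.81        True
     S2        6   0.72        True
     S3        6   0.77        True
     S4        6   0.74        True
     S5        6   0.91        True
     S6        6   0.51        True
     S7        6   0.62        True
     S8        7   0.91        True
arcs: [('S1', 'S2'), ('S2', 'S3'), ('S2', 'S8'), ('S3', 'S4'), ('S4', 'S5'), ('S5', 'S7'), ('S7', 'S6')]
10-fold accuracy 80.3% (~80%), AUC 0.82
S2    212.82
S3    173.31
S1    142.38
S7    139.67
S5    136.45
S4    129.89
S6     48.48
S8     36.54
```

The ranking lists each section by the summed absolute percent change it
induces in the other sections' top-state probabilities when its own top
state's probability is doubled.

## Command line

```sh
surveybbn generate --seed 42 --out survey.csv     # synthetic table
surveybbn preprocess --input survey.csv --out clean.csv
surveybbn learn --input clean.csv --algorithm GTT --out arcs.txt
surveybbn validate --input clean.csv --algorithm GTT --target S5
surveybbn sensitize --input clean.csv
surveybbn run --seed 7 --outdir results/          # full pipeline
```

`surveybbn run` evaluates all nine scheme × algorithm combinations
(two-state, three-state, mixed × Bayesian Search, PC, Greedy Thick
Thinning), selects the best by cross-validated accuracy then AUC, and writes
a bundle of CSV/BIF/text artifacts, each stamped with a hash of the run
configuration. Pass `--config pipeline.yaml` to analyze your own CSV
(`input_path: mytable.csv`) or override any setting.

## Scope and caveats

- The generator produces *trust-level aggregate* scores, not respondent-level
  answers; n = 122 rows matches one trust per row.
- Discretizing 0–10 scores into 2–3 states loses information by design; the
  network models coarse co-movement of section scores, not fine-grained
  effects.
- Structure learning at n = 122 is unstable across schemes and algorithms —
  that is why the pipeline evaluates the full grid rather than one model.
- Doubling interventions are implemented as virtual (soft) evidence by
  default, which propagates both along and against arcs; pass `mode="do"`
  for interventional (graph-surgery) semantics.

See `docs/methods.md` for the model definitions, generator mathematics and
numerical conventions.
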