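# tskfuzzy

Interpretable Takagi–Sugeno–Kang (TSK) fuzzy classification with
subspace-clustered antecedents, for binary recognition problems on
continuous feature tables — the motivating case being dementia recognition
from region-mean PET intensities, where a clinician needs to see *why* a
model decided, not just what it decided.

A TSK fuzzy classifier is a rule base. Rule *k* reads

    If x_1 is A_1^k ∧ … ∧ x_d is A_d^k
    then f^k(x) = p_0^k + p_1^k x_1 + … + p_d^k x_d

with Gaussian fuzzy sets A_j^k; the system output is the normalized
firing-strength weighted sum y(x) = Σ_k μ̃^k(x) f^k(x), and the predicted
class is the sign of y(x). Rules over many features stop being readable, so
this package learns the antecedents with a **feature-weighted fuzzy
subspace clustering**: each cluster (= rule) carries its own weight vector
w_c on the probability simplex,

    J(U, V, W) = Σ_c Σ_i μ_ci^m Σ_j w_cj (x_ij − v_cj)² + Σ_c δ_c Σ_j w_cj²,

and thresholding w_c at τ keeps only the features that rule actually needs.
Consequents are then one ridge least-squares solve over normalized firing
strengths. Interpretability is quantified as **model complexity (MC)** —
the count of trainable parameters, 2·d_k per rule antecedent plus d_k + 1
per reduced consequent — and the fitted rule base can be rendered with
linguistic terms ("If x6 is Low ∧ x10 is Higher then …").

See `docs/methods.md` for the full model description, numerical choices,
and limitations.

## Worked example

```python
import tskfuzzy as tf

data = tf.generate_adni_like_table(seed=0)          # 200 x 15, labels AD/HC
model = tf.fit_tsk_classifier(data, n_rules=15, threshold=0.06, seed=0)

report = tf.model_complexity(model.antecedent.active, mode="reduced")
preds = tf.predict_labels(data.values, model)
print("per-rule active features:", report.active_counts)
print("model complexity:", report.total)
print("training accuracy:", round(tf.accuracy(preds, data.labels.tolist()), 3))

clauses = tf.assign_linguistic_terms(model.antecedent, data)
print(tf.render_rule_base(model, clauses).to_text().splitlines()[0][:100])
```

prints

```
per-rule active features: [13, 12, 12, 10, 12, 12, 11, 13, 9, 12, 12, 12, 11, 10, 11]
model complexity: 531
training accuracy: 0.975
Rule 1: If x1 is Medium ∧ x2 is Lower ∧ x4 is Medium ∧ x5 is Medium ∧ x6 is Medium ∧ x7 is Medium ∧
```

At τ = 0.06 the 15 rules keep 9–13 of the 15 features each, for 531
trainable parameters instead of the 690 a dense 15-rule system costs
(τ = 0: every rule keeps all 15 features, MC = 2·15·15 + 15·16 = 690);
raising τ sheds parameters further at some cost in accuracy. The same
pipeline is available from a shell:

```bash
tskfuzzy synth --preset adni-like --seed 0 --out table.csv
tskfuzzy fit --input table.csv --rules 15 --threshold 0.06 --seed 0 --out model.json
tskfuzzy predict --model model.json --input table.csv --label-col label --out scores.csv
tskfuzzy rules --model model.json --data table.csv --format text
tskfuzzy complexity --model model.json
```

For volume inputs, `tskfuzzy.extract_roi_features_from_nifti` pools
per-region mean intensities from a NIfTI volume and an integer label atlas
on the same voxel grid, and `tskfuzzy.fisher_score_select` provides a
simple univariate filter to cut a wide table down before fitting.

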