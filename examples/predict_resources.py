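"""Predict runtime and memory orders of magnitude before fitting anything.

Characterizes a continuous-variable medical dataset, evaluates the matching
published formulas for each of the eight algorithms, and lists which
applicability rules fire.  Predictions are log10 magnitudes on the original
benchmark hardware — compare them across algorithms rather than reading
them as absolute seconds or bytes.
"""

from metaselect import (
    BaseDatasetSpec,
    characterize,
    dataset_category,
    generate_base_dataset,
    load_formula_bank,
    predict_resource_magnitudes,
)
from metaselect.formula_bank import applicable_rules

spec = BaseDatasetSpec(n_rows=2000, n_continuous=20, n_discrete=0,
                       n_binary=0, n_classes=2, class_separation=1.0,
                       continuous_offset=10.0)  # positive-valued measurements
dataset = generate_base_dataset(spec, seed=12)
mf = characterize(dataset)
category = dataset_category(dataset)

bank = load_formula_bank()
preds = predict_resource_magnitudes(mf, category, bank)
print(f"dataset category: {category.value}  (P={mf['P']:.0f}, N={mf['N']:.0f})")
print(preds.round(3).to_string())

print("\nfired applicability rules:")
for alg, verdict, rule in applicable_rules(mf, category):
    print(f"  {alg.value} [{verdict.value}] {rule.note}")
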