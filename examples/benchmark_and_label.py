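"""Benchmark the eight base classifiers and discretize the ranking.

Runs LR, C4.5, SVM, AdaBoost, kNN, NB, RF and BP on one synthetic dataset
with a stratified 70/30 holdout, then turns the test-accuracy ranking into
recommendation labels: top three Y, next two M, rest (and failures) No.
"""

from metaselect import (
    BaseDatasetSpec,
    assign_labels,
    benchmark_suite,
    generate_base_dataset,
    rank_algorithms,
)

spec = BaseDatasetSpec(n_rows=400, n_classes=3, class_separation=1.2,
                       attribute_class_dependence=0.5)
dataset = generate_base_dataset(spec, seed=3)
records = benchmark_suite([dataset], seed=0)

print(f"{'alg':>5} {'status':>9} {'acc_test':>8} {'S_least':>8} "
      f"{'log10(s)':>9} {'log10(B)':>9}")
for r in records:
    print(f"{r.algorithm.value:>5} {r.status:>9} {r.acc_test:8.3f} "
          f"{r.s_least:8.1f} {r.log10_time:9.3f} {r.log10_memory:9.3f}")

labels = assign_labels(rank_algorithms(records))
print("\nrecommendation labels (Y = top 3 by test accuracy, M = ranks 4-5):")
for alg, label in labels.items():
    print(f"  {alg.value:>5}: {label.value}")
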