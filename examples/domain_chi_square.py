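"""Does an algorithm's recommendation pattern differ between fields?

Rebuilds the published LR contingency table (34 discrete-variable datasets,
rows medical/biology/general, columns Y/M/No) from its per-dataset
assignments and tests independence with the R×C chi-square in its
marginal-product form.  At alpha 0.05 with 4 degrees of freedom the critical
value is 9.488, so 3.8052 means no detectable domain difference for LR.
"""

from metaselect import build_contingency, chi_square_rc, significance
from metaselect.synthetic import fixture_table2_assignments

labels, domains = fixture_table2_assignments()
table = build_contingency(labels, domains)

print("contingency table (rows: domain, cols: label):")
print(table.to_frame())
chi2 = chi_square_rc(table)
verdict = significance(chi2, 3, 3, alpha=0.05)
print(f"\nchi-square = {chi2:.4f}  (n = {table.n})")
print(f"domain difference at alpha 0.05, df 4: {'yes' if verdict else 'no'}")
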