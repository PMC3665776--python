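"""Charge variation across a simulated ortholog family.

Simulates two ortholog groups over seven species with different charge-flip
rates, counts charge-variable surface columns per group, tests cross-group
heterogeneity with a chi-square, and tests enrichment of variation at a set
of "selected" columns with Fisher's exact test.
"""

from cspstruct import (
    FamilySpec,
    charge_variation_table,
    chisq_independence,
    enrichment_test,
    estimate_flip_rate,
    simulate_family,
)
from cspstruct.family_map import charge_class

spec = FamilySpec(base_length=69, n_species=7,
                  groups={"1": 0.02, "2": 0.15},       # conserved vs variable group
                  selected_columns=frozenset(range(1, 9)), q_selected=0.5,
                  seed=7)
family, truth = simulate_family(spec)

columns = list(range(1, spec.base_length + 1))
table = charge_variation_table(family, {"1": columns, "2": columns})
for row in table.rows.values():
    print(f"group {row.group}: {row.n_variable}/{row.n_surface} variable columns "
          f"({row.percent}%)  [generator truth: {truth.variable_counts[row.group]}]")

chi2 = chisq_independence(table.contingency())
print(f"cross-group heterogeneity: X^2 = {chi2.statistic:.2f}, df = {chi2.df}, "
      f"p = {chi2.p_value:.3g}")

# enrichment at the selected columns of group 2 (elevated flip rate)
group2 = [r for r in family.records if r.group == "2"]
variable = {}
for col in columns:
    letters = {r.sequence[col - 1] for r in group2}
    variable[col] = len({charge_class(l) for l in letters}) > 1
selected = set(range(1, 9))
res = enrichment_test(selected, set(columns) - selected, variable)
print(f"selected-site enrichment: table {res.observed}, Fisher p = {res.p_value:.4f}")

q_hat = estimate_flip_rate(table.rows['2'].fraction, spec.n_species)
print(f"flip rate recovered for group 2: {q_hat:.3f} (true 0.15)")
# Low p in the heterogeneity test says the groups differ in how freely their
# surface charge drifts; low enrichment p says the selected columns vary
# more than the background, the signature of positive selection on charge.
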