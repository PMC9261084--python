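"""Simulate a calibrated cohort and describe its first-order behaviour.

Builds the default two-group cohort (30 controls, 30 psychosis patients;
240 virtual-hand trials each), applies the pre-registered trial exclusions,
and prints per-group signal-detection statistics.  d' is the ability to
discriminate one's own movement from an altered one; a negative criterion c
is a bias toward answering "identical" (self-attribution).
"""

import soameta as sm

dataset = sm.build_cohort(seed=7)
dataset, report = sm.apply_exclusions(dataset)
for group, r in report.items():
    print(f"{group}: {r['n_excluded']}/{r['n_total']} trials excluded ({100 * r['fraction']:.1f}%)")

table = sm.sdt_table(dataset)
means = table.groupby("group")[["hit_rate", "fa_rate", "d_prime", "criterion_c"]].mean()
print("\nGroup means:")
print(means.round(3))

ctl = table[table["group"] == "control"]
psy = table[table["group"] == "psychosis"]
test = sm.group_compare(ctl["d_prime"], psy["d_prime"])
print(
    f"\nWelch t({test.df:.1f}) = {test.t:.2f}, p = {test.p:.2g}, "
    f"Cohen's d = {test.cohens_d:.2f}"
)
print("-> controls discriminate self from altered movements far better; "
      "patients' more negative c means stronger over-attribution.")
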