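"""Behavioral statistics on a synthetic 4-dose design (n = 6 per group).

Injects a dose-dependent decrease in open-field distance travelled, runs
the per-measure one-way ANOVA with Tukey post hocs, and tests the
novel-object investigation ratio against chance (0.5) per group.
"""

from phmrikit import behavior as beh
from phmrikit.simulate import generate_behavior_table

pattern = {
    "distance": {"vehicle": 24.0, "3mg": 22.0, "10mg": 20.0, "30mg": 12.0},
    "ir": {"vehicle": 0.65, "3mg": 0.52, "10mg": 0.50, "30mg": 0.48},
}
table, truth = generate_behavior_table(
    {"vehicle": 6, "3mg": 6, "10mg": 6, "30mg": 6}, effect_pattern=pattern, seed=5
)

res = beh.analyze_measure(table, "distance")
print(f"Distance travelled: F{res.anova['df']} = {res.anova['F']:.2f}, "
      f"p = {res.anova['p_value']:.4f}")
for pair, stats in sorted(res.pairwise.items()):
    print(f"  Tukey {pair[0]} vs {pair[1]}: p = {stats['p_value']:.4f}")

print("\nInvestigation ratio vs chance (0.5), one-sample two-tailed t:")
for group in ("vehicle", "3mg", "10mg", "30mg"):
    irs = table[(table.measure == "ir") & (table.group == group)]["value"].to_numpy()
    t, p = beh.ir_vs_chance(irs)
    if p < 0.05:
        verdict = "above chance" if t > 0 else "below chance"
    else:
        verdict = "at chance"
    print(f"  {group:8s} t = {t:6.2f}, p = {p:.4f}  ({verdict})")
print("\nOnly the vehicle group discriminates the novel object; the dosed groups")
print("perform at chance, and the top dose travels markedly less distance.")
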