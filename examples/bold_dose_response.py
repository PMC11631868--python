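"""Dose-response BOLD analysis on a synthetic 4-group session.

Builds a small atlas, injects an inverse dose-response deactivation (the
lowest dose carries the strongest negative percent change), runs the voxel
chain (percent change -> Welch t -> ranked-p filter -> +-1% classification)
and prints the per-region volume-of-activation table with Kruskal-Wallis
statistics.
"""

from phmrikit import activation as act
from phmrikit.simulate import BoldDesign, RegionEffectSpec, generate_bold, make_atlas

atlas = make_atlas(shape=(24, 24, 8), n_regions=8)
design = BoldDesign(
    groups=(("vehicle", 0.0, 4), ("3mg", 3.0, 4), ("10mg", 10.0, 6), ("30mg", 30.0, 5)),
    seed=7,
)
effects = [
    RegionEffectSpec(1, {"3mg": -1.6, "10mg": -1.25, "30mg": -1.05},
                     responder_fraction=1.0, noise_sd=0.5)
]
subjects, truth = generate_bold(design, atlas, effects, global_noise_sd=0.5)
print(f"{len(subjects)} subjects, 250 acquisitions each; injected effect in region 1:")
print(truth.to_string(index=False))

counts, labels = [], []
for s in subjects:
    stat = act.subject_voxel_stats(s, atlas)  # q=0.2, c(V)=1, |d%| >= 1
    counts.append(act.region_voxel_counts(stat.sign_class, atlas))
    labels.append(s.group)

table = act.region_activation_table(counts, labels, measure="negative")
ranked, fdr = act.rank_table(table, alpha=0.05)
print("\nSignificant regions, ranked by Kruskal-Wallis p (negative voxel counts):")
cols = ["region", "vehicle_mean", "3mg_mean", "10mg_mean", "30mg_mean", "p_value", "omega_sq"]
print(ranked[cols].round(3).to_string(index=False))
print(f"\nAcross-region BH summary: {fdr}")
print("Region 1's group means fall with dose (3 > 10 > 30 mg/kg > vehicle): the")
print("injected inverse dose-response pattern, recovered by the voxel chain.")
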