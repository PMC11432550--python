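"""Landrace-vs-modern breeding signatures at every locus.

For Xian and Geng, compares landraces (LAN) against modern varieties (MV):
delta E_H with a bootstrap Z test (** p<0.01, * p<0.05), the number of new
gcHaps modern breeding introduced, and the chi-square drift of the dominant
haplotype's frequency F(P).  The selection-effect label is "up" when
breeding increased evenness at the locus.
"""

from gchapkit import simulate as sim
from gchapkit.breeding import breeding_table, compare_groups
from gchapkit.calling import call_gchaps

dataset = sim.simulate_all(sim.default_config(seed=1))

comparisons = []
for pop in ("Xian", "Geng"):
    lan = dataset.panel.members(population=pop, improvement="LAN")
    mv = dataset.panel.members(population=pop, improvement="MV")
    for i, model in enumerate(dataset.gene_models):
        table = call_gchaps(dataset.reference, model, dataset.variants,
                            dataset.panel)
        comparisons.append(compare_groups(
            table, lan, mv, label_a=f"LANs-{pop}", label_b=f"MVs-{pop}",
            n_boot=1000, seed=i,
        ))

cols = ["gene_id", "group_A", "group_B", "E_H_A", "E_H_B", "delta_E_H",
        "n_new_gcHaps", "F_P_A", "F_P_B", "chi2_p", "selection_effect",
        "significance"]
print(breeding_table(comparisons)[cols].round(4).to_string(index=False))
print()
print("The generator plants a -0.10 dominant-haplotype drift in MVs-Xian "
      "and -0.05 in MVs-Geng, so delta_E_H is mostly positive ('up').")
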