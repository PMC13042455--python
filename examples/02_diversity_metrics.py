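"""Richness, clonality and Gini on hand-sized repertoires.

Clonality = 1 - Shannon/log(N) rises with dominance; the Gini coefficient
measures clone-size inequality independently of richness.
"""

from tcrdyn import CloneTable, ClonotypeKey, clonality, copy_number_spectrum, gini, richness


def table(counts):
    return CloneTable(
        specimen=("P1", "post"),
        counts={
            ClonotypeKey("TRAV1", "TRAJ1", f"A{k}", "TRBV1", "TRBJ1", f"B{k}"): n
            for k, n in counts.items()
        },
    )


for name, counts in [
    ("uniform  {1,1,1,1}", {"a": 1, "b": 1, "c": 1, "d": 1}),
    ("skewed   {3,1}", {"a": 3, "b": 1}),
    ("dominant {8,1,1}", {"a": 8, "b": 1, "c": 1}),
]:
    t = table(counts)
    print(
        f"{name}: richness {richness(t)}, "
        f"clonality {clonality(t):.4f}, gini {gini(t):.4f}"
    )
# uniform  -> clonality 0, gini 0 (perfect evenness)
# {3,1}    -> clonality 0.1887, gini 0.25
# {8,1,1}  -> clonality 0.4183, gini 0.4667 (one clone holds 80% of cells)

spectrum = copy_number_spectrum(table({"a": 1, "b": 1, "c": 2, "d": 12, "e": 60}))
print("copy-number spectrum bins:", spectrum.bins)
print("clonotypes per bin:       ", spectrum.counts)
# the default bins separate singletons, moderately expanded clones, and the
# highly expanded clones with more than 10 or more than 50 copies
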