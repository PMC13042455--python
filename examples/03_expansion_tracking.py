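"""Track clonotypes across paired pre/post specimens of one patient.

Each clone's (pre, post) copy numbers determine its expansion class:
novel expanded (0 -> >=2), persistent expanded (>=1 -> more, >=2),
novel nonexpanded (0 -> 1), or other (unchanged / contracted / lost).
"""

from tcrdyn import CloneTable, ClonotypeKey, pair_repertoires


def key(k):
    return ClonotypeKey("TRAV1", "TRAJ1", f"A{k}", "TRBV1", "TRBJ1", f"B{k}")


pre = CloneTable(("P1", "pre"), {key("a"): 2, key("b"): 1, key("c"): 4})
post = CloneTable(("P1", "post"), {key("a"): 9, key("c"): 2, key("d"): 5, key("e"): 1})

for clone in pair_repertoires(pre, post):
    label = clone.clonotype.tra_cdr3[1:]
    lost = " (lost)" if clone.lost else ""
    print(
        f"clone {label}: pre {clone.pre_copies} -> post {clone.post_copies}: "
        f"{clone.expansion_class}{lost}"
    )
# a: 2 -> 9  persistent_expanded (carried over and grew)
# b: 1 -> 0  other, tagged lost
# c: 4 -> 2  other (contracted)
# d: 0 -> 5  novel_expanded (treatment-emergent clone)
# e: 0 -> 1  novel_nonexpanded (newly detected single cell)
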