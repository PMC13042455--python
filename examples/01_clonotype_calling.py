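"""Call paired alpha/beta clonotypes from a small contig table.

Builds six contigs for three cells, applies the two-step QC (contig flags,
metadata whitelist, dominant chain per locus) and prints each retained
cell's clonotype key.
"""

import pandas as pd

from tcrdyn import ContigRecord, build_clone_table, call_clonotypes


def contig(barcode, chain, cdr3_nt, umis=5, productive=True):
    return ContigRecord(
        barcode=barcode, chain=chain, v_gene=f"{chain}V1", j_gene=f"{chain}J1",
        cdr3_nt=cdr3_nt, cdr3_aa="CASS", umis=umis, reads=umis * 10,
        productive=productive, full_length=True, is_cell=True, high_confidence=True,
    )


contigs = [
    contig("cell1", "TRA", "TGTGCAGCA"), contig("cell1", "TRB", "TGTGCCAGC"),
    # cell2 has two productive TRAs; the higher-UMI one is its dominant chain
    contig("cell2", "TRA", "TGTGCAGCA", umis=9), contig("cell2", "TRA", "TGTGCTTTT", umis=2),
    contig("cell2", "TRB", "TGTGCCAGC"),
    # cell3's TRA is nonproductive, so the cell lacks a functional pair
    contig("cell3", "TRA", "TGTGCAGCA", productive=False), contig("cell3", "TRB", "TGTGCCAGC"),
]
metadata = pd.DataFrame(
    {
        "barcode": ["cell1", "cell2", "cell3"],
        "patient": "P1", "timepoint": "post", "response": "PCR",
        "subset": "c05_CD8_Tem-GZMA",
    }
)

cells = call_clonotypes(contigs, metadata)
print(f"retained {len(cells)} of 3 cells (cell3 lacks a productive TRA):")
for cell in cells:
    print(f"  {cell.barcode}: TRA CDR3 {cell.clonotype.tra_cdr3}, TRB CDR3 {cell.clonotype.trb_cdr3}")

table = build_clone_table(cells, ("P1", "post"))
print(f"clone table: {len(table)} clonotype(s), copy numbers {sorted(table.counts.values())}")
# cell1 and cell2 share the same dominant alpha/beta pair, so they form one
# clone with copy number 2.
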