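from __future__ import annotations

import pytest
from hypothesis import settings

from tcrdyn.vdj_io import CellClonotype, CloneTable, ClonotypeKey, ContigRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_key(name: str) -> ClonotypeKey:
    """Distinct clonotype keys that differ only in their CDR3s."""
    return ClonotypeKey(
        tra_v="TRAV1", tra_j="TRAJ1", tra_cdr3=f"A{name}",
        trb_v="TRBV1", trb_j="TRBJ1", trb_cdr3=f"B{name}",
    )


def make_table(counts: dict[str, int], patient: str = "P1", timepoint: str = "pre") -> CloneTable:
    return CloneTable(
        specimen=(patient, timepoint),
        counts={make_key(name): n for name, n in counts.items()},
    )


def make_cell(
    barcode: str,
    clone: str,
    subset: str = "c05_CD8_Tem-GZMA",
    patient: str = "P1",
    timepoint: str = "post",
    response: str = "PCR",
) -> CellClonotype:
    return CellClonotype(
        barcode=barcode,
        clonotype=make_key(clone),
        patient=patient,
        timepoint=timepoint,
        response=response,
        subset=subset,
    )


def make_contig(
    barcode: str,
    chain: str = "TRA",
    cdr3_nt: str = "TGTGCA",
    umis: int = 5,
    reads: int = 50,
    productive: bool = True,
    full_length: bool = True,
    is_cell: bool = True,
    high_confidence: bool = True,
    v_gene: str = "TRAV1",
    j_gene: str = "TRAJ1",
) -> ContigRecord:
    return ContigRecord(
        barcode=barcode,
        chain=chain,
        v_gene=v_gene,
        j_gene=j_gene,
        cdr3_nt=cdr3_nt,
        cdr3_aa="CA",
        umis=umis,
        reads=reads,
        productive=productive,
        full_length=full_length,
        is_cell=is_cell,
        high_confidence=high_confidence,
    )


@pytest.fixture
def metadata_frame():
    import pandas as pd

    def build(barcodes, subset="c05_CD8_Tem-GZMA", patient="P1", timepoint="post",
              response="PCR"):
        return pd.DataFrame(
            {
                "barcode": list(barcodes),
                "patient": patient,
                "timepoint": timepoint,
                "response": response,
                "subset": subset,
            }
        )

    return build
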