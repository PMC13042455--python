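"""Contig parsing, two-step QC, dominant-chain selection and clone tables."""

from __future__ import annotations

import collections

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tcrdyn.vdj_io import (
    ClonotypeKey,
    ContigDialect,
    VdjFormatError,
    build_clone_table,
    call_clonotypes,
    read_contigs,
    read_metadata,
    records_from_frame,
)

from conftest import make_cell, make_contig, make_key

TENX_COLUMNS = [
    "barcode", "is_cell", "high_confidence", "chain", "v_gene", "j_gene",
    "cdr3", "cdr3_nt", "reads", "umis", "productive", "full_length",
]


def _contig_csv(tmp_path, rows, columns=TENX_COLUMNS, name="contigs.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def _row(barcode="c1", chain="TRA", umis=5, reads=50, **kw):
    base = {
        "barcode": barcode, "is_cell": "True", "high_confidence": "True",
        "chain": chain, "v_gene": "TRAV1", "j_gene": "TRAJ1",
        "cdr3": "CA", "cdr3_nt": "TGTGCA", "reads": reads, "umis": umis,
        "productive": "True", "full_length": "True",
    }
    base.update(kw)
    return base


class TestReadContigs:
    def test_identity_parse_preserves_chain_labels(self, tmp_path):
        path = _contig_csv(
            tmp_path,
            [_row(chain="TRA"), _row(chain="TRB"), _row(chain="IGH")],
        )
        records = read_contigs(path)
        assert [r.chain for r in records] == ["TRA", "TRB", "IGH"]
        assert all(r.umis == 5 and r.productive for r in records)

    def test_missing_column_names_it(self, tmp_path):
        rows = [_row()]
        cols = [c for c in TENX_COLUMNS if c != "umis"]
        path = _contig_csv(tmp_path, [{k: v for k, v in rows[0].items() if k != "umis"}], cols)
        with pytest.raises(VdjFormatError, match="umis"):
            read_contigs(path)

    def test_bad_integer_cites_line_number(self, tmp_path):
        path = _contig_csv(tmp_path, [_row(), _row(umis="x")])
        with pytest.raises(VdjFormatError, match="line 3"):
            read_contigs(path)

    def test_bad_boolean_cites_line_number(self, tmp_path):
        path = _contig_csv(tmp_path, [_row(productive="maybe")])
        with pytest.raises(VdjFormatError, match="line 2"):
            read_contigs(path)

    def test_custom_dialect_true_tokens(self, tmp_path):
        path = _contig_csv(tmp_path, [_row(productive="yes", is_cell="1")])
        records = read_contigs(path, ContigDialect())
        assert records[0].productive and records[0].is_cell


class TestCallClonotypes:
    def test_hand_enumerated_retention_and_dominance(self, metadata_frame):
        # c1 full pair; c2 TRB only; c3 two productive TRAs (umis 5 vs 2);
        # c4 nonproductive TRA + productive TRB
        contigs = [
            make_contig("c1", "TRA", cdr3_nt="AAA"),
            make_contig("c1", "TRB", cdr3_nt="CCC", v_gene="TRBV1", j_gene="TRBJ1"),
            make_contig("c2", "TRB", cdr3_nt="CCC"),
            make_contig("c3", "TRA", cdr3_nt="AAA", umis=5),
            make_contig("c3", "TRA", cdr3_nt="GGG", umis=2),
            make_contig("c3", "TRB", cdr3_nt="CCC"),
            make_contig("c4", "TRA", cdr3_nt="AAA", productive=False),
            make_contig("c4", "TRB", cdr3_nt="CCC"),
        ]
        cells = call_clonotypes(contigs, metadata_frame(["c1", "c2", "c3", "c4"]))
        assert {c.barcode for c in cells} == {"c1", "c3"}
        c3 = next(c for c in cells if c.barcode == "c3")
        assert c3.clonotype.tra_cdr3 == "AAA"  # the umis-5 contig wins

    def test_cell_absent_from_metadata_is_dropped(self, metadata_frame):
        contigs = [make_contig("cX", "TRA"), make_contig("cX", "TRB")]
        assert call_clonotypes(contigs, metadata_frame(["other"])) == []

    def test_umi_tie_broken_by_reads_then_cdr3(self, metadata_frame):
        contigs = [
            make_contig("c1", "TRA", cdr3_nt="TTT", umis=3, reads=8),
            make_contig("c1", "TRA", cdr3_nt="GGG", umis=3, reads=10),
            make_contig("c1", "TRB", cdr3_nt="CCC"),
        ]
        cells = call_clonotypes(contigs, metadata_frame(["c1"]))
        assert cells[0].clonotype.tra_cdr3 == "GGG"
        # full tie falls back to lexicographically smallest cdr3_nt
        contigs[1] = make_contig("c1", "TRA", cdr3_nt="GGG", umis=3, reads=8)
        cells = call_clonotypes(contigs, metadata_frame(["c1"]))
        assert cells[0].clonotype.tra_cdr3 == "GGG"

    def test_empty_contig_list_gives_empty_output(self, metadata_frame):
        assert call_clonotypes([], metadata_frame(["c1"])) == []

    def test_metadata_missing_column_raises(self, metadata_frame):
        meta = metadata_frame(["c1"]).drop(columns=["subset"])
        with pytest.raises(VdjFormatError, match="subset"):
            call_clonotypes([make_contig("c1")], meta)

    def test_aa_key_mode_groups_by_amino_acid_cdr3(self, metadata_frame):
        # same aa CDR3, different nt CDR3 -> same clonotype only in aa mode
        contigs = [
            make_contig("c1", "TRA", cdr3_nt="AAA"),
            make_contig("c1", "TRB", cdr3_nt="CCA"),
            make_contig("c2", "TRA", cdr3_nt="AAG"),
            make_contig("c2", "TRB", cdr3_nt="CCG"),
        ]
        meta = metadata_frame(["c1", "c2"])
        nt_cells = call_clonotypes(contigs, meta, key_mode="nt")
        aa_cells = call_clonotypes(contigs, meta, key_mode="aa")
        assert nt_cells[0].clonotype != nt_cells[1].clonotype
        assert aa_cells[0].clonotype == aa_cells[1].clonotype

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),   # number of productive TRAs
                st.integers(0, 5),   # number of productive TRBs
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_dominance_is_total_exactly_one_pair_per_retained_cell(
        self, cell_specs
    ):
        contigs = []
        for i, (n_tra, n_trb) in enumerate(cell_specs):
            bc = f"cell{i}"
            for j in range(n_tra):
                contigs.append(make_contig(bc, "TRA", cdr3_nt=f"AA{j}", umis=j % 3))
            for j in range(n_trb):
                contigs.append(make_contig(bc, "TRB", cdr3_nt=f"CC{j}", umis=j % 3))
        meta = pd.DataFrame(
            {
                "barcode": [f"cell{i}" for i in range(len(cell_specs))],
                "patient": "P1", "timepoint": "post", "response": "PCR",
                "subset": "c05_CD8_Tem-GZMA",
            }
        )
        cells = call_clonotypes(contigs, meta)
        expected_retained = {
            f"cell{i}" for i, (a, b) in enumerate(cell_specs) if a > 0 and b > 0
        }
        assert {c.barcode for c in cells} == expected_retained
        assert len({c.barcode for c in cells}) == len(cells)  # one pair per cell

    def test_idempotence_on_retained_cells(self, metadata_frame):
        contigs = [
            make_contig("c1", "TRA", cdr3_nt="AAA", umis=5),
            make_contig("c1", "TRA", cdr3_nt="GGG", umis=2),
            make_contig("c1", "TRB", cdr3_nt="CCC"),
            make_contig("c2", "TRA", cdr3_nt="TTT"),
            make_contig("c2", "TRB", cdr3_nt="CCC"),
        ]
        meta = metadata_frame(["c1", "c2"])
        first = call_clonotypes(contigs, meta)
        surviving = [
            c for c in contigs
            if any(c.cdr3_nt in (cell.clonotype.tra_cdr3, cell.clonotype.trb_cdr3)
                   and c.barcode == cell.barcode for cell in first)
        ]
        assert call_clonotypes(surviving, meta) == first


class TestBuildCloneTable:
    def test_counts_cells_per_clonotype(self):
        cells = [make_cell(f"c{i}", k) for i, k in enumerate("AAABC")]
        table = build_clone_table(cells, ("P1", "post"))
        assert table.counts == {make_key("A"): 3, make_key("B"): 1, make_key("C"): 1}
        assert table.total_cells() == 5

    def test_empty_input_gives_empty_table(self):
        table = build_clone_table([], ("P1", "pre"))
        assert table.counts == {} and table.total_cells() == 0

    def test_key_equality_is_fieldwise_exact(self):
        from tcrdyn.vdj_io import CellClonotype

        a = make_cell("c1", "A")
        b_key = ClonotypeKey(
            tra_v="TRAV1", tra_j="TRAJ1", tra_cdr3="Adifferent",
            trb_v="TRBV1", trb_j="TRBJ1", trb_cdr3="BA",
        )
        b = CellClonotype(
            barcode="c2", clonotype=b_key, patient="P1", timepoint="post",
            response="PCR", subset="c05_CD8_Tem-GZMA",
        )
        table = build_clone_table([a, b], ("P1", "post"))
        assert len(table) == 2

    def test_mixed_specimens_rejected(self):
        cells = [make_cell("c1", "A"), make_cell("c2", "A", timepoint="pre")]
        with pytest.raises(ValueError, match="specimen"):
            build_clone_table(cells, ("P1", "post"))

    @given(st.lists(st.sampled_from("ABCDEFG"), min_size=0, max_size=60))
    def test_conservation_copy_sum_equals_cell_count(self, labels):
        cells = [make_cell(f"c{i}", lab) for i, lab in enumerate(labels)]
        table = build_clone_table(cells, ("P1", "post"))
        assert table.total_cells() == len(cells)
        assert collections.Counter(labels) == {
            key.tra_cdr3[1:]: n for key, n in table.counts.items()
        }


def test_records_from_frame_matches_file_reader(tmp_path):
    rows = [_row(), _row(barcode="c2", chain="TRB")]
    path = _contig_csv(tmp_path, rows)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    assert records_from_frame(df) == read_contigs(path)


def test_read_metadata_requires_unique_barcodes(tmp_path):
    df = pd.DataFrame(
        {
            "barcode": ["c1", "c1"], "patient": "P1", "timepoint": "pre",
            "response": "PCR", "subset": "s",
        }
    )
    path = tmp_path / "meta.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(VdjFormatError, match="unique"):
        read_metadata(path)
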