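"""Translation, block selection, concatenation, and root-to-tip rates."""

import numpy as np
import pytest

from mitocompare.supermatrix import (
    BlockParams,
    GeneAlignment,
    SupermatrixError,
    concatenate,
    read_partition_file,
    root_to_tip_rates,
    select_blocks,
    translate_mito,
    write_partition_file,
)


# -- translation (invertebrate mitochondrial code, table 5) -----------------

@pytest.mark.parametrize(
    "cds,aa",
    [
        ("ATATGA", "MW"),      # ATA -> M, TGA -> W
        ("AGA", "S"),          # AGA -> S (not R, not stop)
        ("AGG", "S"),
        ("ATGTAA", "M"),       # terminal stop stripped
        ("ATGGCATTA", "MAL"),
        ("TGATGG", "WW"),
    ],
)
def test_table5_translation(cds, aa):
    assert translate_mito(cds) == aa


def test_trailing_incomplete_codon_dropped():
    with pytest.warns(UserWarning):
        assert translate_mito("ATGGCAT") == "MA"


def test_internal_stop_raises_unless_allowed():
    with pytest.raises(SupermatrixError):
        translate_mito("ATGTAAATG")
    assert translate_mito("ATGTAAATG", allow_internal_stops=True) == "MXM"


def test_too_short_cds():
    with pytest.raises(SupermatrixError):
        translate_mito("AT")


# -- block selection (Gblocks default rules) --------------------------------

def aln(rows, gene="g"):
    return GeneAlignment(gene, [f"t{i}" for i in range(len(rows))], rows)


def test_blocks_identical_rows_all_kept():
    a = aln(["MKLVINSEQWRD"] * 4)
    assert select_blocks(a).kept_columns == tuple(range(12))


def test_blocks_gap_column_never_kept():
    rows = ["MKLVINSEQWRD"] * 5 + ["MKLVI-SEQWRD"]
    mask = select_blocks(aln(rows))
    assert 5 not in mask.kept_columns


def test_blocks_long_nonconserved_run_removed():
    """Two 10-column conserved blocks split by 9 nonconserved columns:
    both blocks survive, the run is removed."""
    left = "MKLVINSEQW"
    right = "ACDEFGHIKL"
    noisy = ["ACDEFGHIK", "CDEFGHIKL", "DEFGHIKLM", "EFGHIKLMN"]
    rows = [left + noisy[i] + right for i in range(4)]
    mask = select_blocks(aln(rows))
    assert set(mask.kept_columns) == set(range(10)) | set(range(19, 29))


def test_blocks_short_nonconserved_run_kept_inside_block():
    """A nonconserved run of <=8 interior columns stays when flanked."""
    core = "MKLVINSEQW"
    noisy = ["ACD", "CDE", "DEF", "EFG"]
    rows = [core + noisy[i] + core for i in range(4)]
    mask = select_blocks(aln(rows))
    assert set(mask.kept_columns) == set(range(23))


def test_blocks_flank_trimming_and_min_length():
    # nonconserved edges are trimmed to highly conserved flanks; a block
    # shrinking below 10 columns disappears entirely
    rows = ["ACDEFGHIK", "CDEFGHIKL", "DEFGHIKLM", "EFGHIKLMN"]
    assert select_blocks(aln(rows)).kept_columns == ()
    short = ["MKLVINSE"] * 4  # conserved but only 8 columns
    assert select_blocks(aln(short)).kept_columns == ()


def test_blocks_majority_threshold_boundary():
    """N=5 taxa: a column needs floor(5/2)+1 = 3 identical residues to count
    as conserved.  A 9-column interior stretch at exactly 3/5 survives; the
    same stretch at 2/5 is a >8 nonconserved run and is removed."""
    flank = "M" * 10
    conserved_mid = ["M", "M", "M", "K", "L"]   # top residue count 3
    nonconserved_mid = ["M", "M", "K", "K", "L"]  # top residue count 2
    rows3 = [flank + c * 9 + flank for c in conserved_mid]
    assert set(select_blocks(aln(rows3)).kept_columns) == set(range(29))
    rows2 = [flank + c * 9 + flank for c in nonconserved_mid]
    assert set(select_blocks(aln(rows2)).kept_columns) == (
        set(range(10)) | set(range(19, 29))
    )


def test_blocks_row_permutation_invariance(full_study):
    gene, a = sorted(full_study.alignments.items())[0]
    m1 = select_blocks(a)
    perm = np.random.default_rng(0).permutation(len(a.rows))
    a2 = GeneAlignment(gene, [a.taxa[i] for i in perm], [a.rows[i] for i in perm])
    assert select_blocks(a2).kept_columns == m1.kept_columns


def test_blocks_need_four_rows():
    with pytest.raises(SupermatrixError):
        select_blocks(aln(["MKL", "MKL", "MKL"]))


# -- concatenation ----------------------------------------------------------

def test_concatenate_widths_and_partitions():
    a1 = aln(["MKLVINSEQW"] * 4, gene="g1")
    a2 = aln(["ACDEFGHIKLMW"] * 4, gene="g2")
    m1, m2 = select_blocks(a1), select_blocks(a2)
    sm = concatenate([(a1, m1), (a2, m2)])
    assert sm.width == len(m1.kept_columns) + len(m2.kept_columns)
    assert sm.partitions == [
        ("g1", 0, len(m1.kept_columns)),
        ("g2", len(m1.kept_columns), sm.width),
    ]


def test_concatenate_gap_fill_missing_taxon():
    a1 = aln(["MKLVINSEQW"] * 4, gene="g1")
    a2 = GeneAlignment("g2", ["t0", "t1", "t2", "t3", "t9"], ["ACDEFGHIKLMW"] * 5)
    m1, m2 = select_blocks(a1), select_blocks(a2)
    sm = concatenate([(a1, m1), (a2, m2)])
    row_t9 = sm.rows[sm.taxa.index("t9")]
    assert row_t9[: len(m1.kept_columns)] == "-" * len(m1.kept_columns)
    sm2 = concatenate([(a1, m1), (a2, m2)], taxon_union_policy="intersect")
    assert "t9" not in sm2.taxa


def test_partition_file_round_trip(tmp_path):
    a1 = aln(["MKLVINSEQW"] * 4, gene="g1")
    a2 = aln(["ACDEFGHIKLMW"] * 4, gene="g2")
    sm = concatenate([(a1, select_blocks(a1)), (a2, select_blocks(a2))])
    p = tmp_path / "parts.txt"
    write_partition_file(sm, p)
    assert read_partition_file(p) == sm.partitions


# -- root-to-tip rates ------------------------------------------------------

def test_root_to_tip_example_tree():
    tree = "((A:1.0,B:2.0):0.5,(C:1.5,D:1.5):0.5);"
    cmap = {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}
    summary = root_to_tip_rates(tree, cmap, ("c1", "c2"))
    d = {t: r for t, _, r in summary.per_tip}
    assert d == {"A": 1.5, "B": 2.5, "C": 2.0, "D": 2.0}
    assert summary.per_clade["c1"][0] == pytest.approx(2.0)
    assert summary.per_clade["c2"][0] == pytest.approx(2.0)


def test_root_to_tip_ultrametric_equal_distances():
    tree = "((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5);"
    summary = root_to_tip_rates(
        tree, {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}, ("c1", "c2")
    )
    vals = [r for _, _, r in summary.per_tip]
    assert all(v == pytest.approx(2.0) for v in vals)
    assert summary.per_clade["c1"][0] == summary.per_clade["c2"][0]


def test_root_to_tip_outgroup_excluded_from_aggregates():
    tree = "(((A:1.0,B:1.0):1.0,(C:2.0,D:2.0):0.1):0.5,OG:3.0);"
    cmap = {"A": "c1", "B": "c1", "C": "c2", "D": "c2", "OG": "outgroup"}
    summary = root_to_tip_rates(tree, cmap, ("c1", "c2"))
    assert set(summary.per_clade) == {"c1", "c2"}
    assert summary.per_clade["c1"] == (pytest.approx(2.0), pytest.approx(0.0), 2)


def test_root_to_tip_missing_taxon_raises():
    with pytest.raises(SupermatrixError):
        root_to_tip_rates("((A:1,B:1):1,C:2);", {"A": "c1", "Z": "c2"}, ("c1", "c2"))


def test_clade_rate_ratio_recovered(full_study):
    """~1.4-fold planted clade contrast is recovered within 10% from the
    estimated (realized substitution density) tree at the full study scale."""
    summary = root_to_tip_rates(
        full_study.estimated_tree_newick,
        full_study.clade_map,
        ("Teredinidae", "Xylophagaidae"),
    )
    ratio = (
        summary.per_clade["Teredinidae"][0] / summary.per_clade["Xylophagaidae"][0]
    )
    assert ratio == pytest.approx(full_study.config.rate_ratio, rel=0.10)
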