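"""Record IO, gene-name normalization, gene orders and intergenic regions."""

import pytest

from mitocompare.mito_io import (
    AnnotationSet,
    GeneFeature,
    MitoGenome,
    MitoError,
    UnknownGeneNameError,
    coding_coverage,
    compute_igrs,
    extract_gene_order,
    normalize_gene_name,
    read_records,
    write_records,
)


@pytest.mark.parametrize(
    "raw,key,cls",
    [
        ("COI", "cox1", "PCG"),
        ("COX1", "cox1", "PCG"),
        ("CYTB", "cob", "PCG"),
        ("COB", "cob", "PCG"),
        ("ND4", "nad4", "PCG"),
        ("NAD4", "nad4", "PCG"),
        ("nd4l", "nad4l", "PCG"),
        ("atp8", "atp8", "PCG"),
        ("12S", "rrnS", "rRNA"),
        ("s-rRNA", "rrnS", "rRNA"),
        ("16S", "rrnL", "rRNA"),
        ("l-rRNA", "rrnL", "rRNA"),
        ("tRNA-Met", "trnM", "tRNA"),
        ("trnM", "trnM", "tRNA"),
        ("tRNA-Leu(UUR)", "trnL2", "tRNA"),
        ("tRNA-Leu(CUN)", "trnL1", "tRNA"),
        ("trnL1", "trnL1", "tRNA"),
        ("tRNA-Ser(AGN)", "trnS1", "tRNA"),
        ("trnS2", "trnS2", "tRNA"),
    ],
)
def test_normalize_gene_name(raw, key, cls):
    assert normalize_gene_name(raw) == (key, cls)


def test_normalize_is_case_insensitive():
    assert normalize_gene_name("cytb") == normalize_gene_name("CytB")


def test_unknown_and_ambiguous_names_raise():
    with pytest.raises(UnknownGeneNameError):
        normalize_gene_name("mystery7")
    with pytest.raises(UnknownGeneNameError):
        normalize_gene_name("tRNA-Leu")  # isoacceptor unresolvable


def test_feature_invariants():
    with pytest.raises(MitoError):
        GeneFeature("cox1", "PCG", 100, 100, "+")
    # wrapping feature may have start >= end
    f = GeneFeature("cox1", "PCG", 900, 50, "+", wraps_origin=True)
    assert f.length_on(1000) == 150


def test_end_beyond_genome_rejected(tmp_path):
    genome = MitoGenome("r1", "ACGT" * 100)
    ann = AnnotationSet("r1", [GeneFeature("cox1", "PCG", 0, 500, "+")])
    with pytest.raises(MitoError):
        write_records([(genome, ann)], tmp_path / "g.fasta")
        read_records(tmp_path / "g.fasta", "fasta_plus_table")


def test_fasta_table_round_trip(tmp_path, small_study):
    pairs = small_study.records[:4]
    write_records(pairs, tmp_path / "bundle.fasta")
    back = read_records(tmp_path / "bundle.fasta", "fasta_plus_table")
    assert len(back) == len(pairs)
    for (g0, a0), (g1, a1) in zip(pairs, back):
        assert g0.record_id == g1.record_id
        assert g0.sequence == g1.sequence
        assert [(f.gene_key, f.start, f.end, f.strand) for f in a0.features] == [
            (f.gene_key, f.start, f.end, f.strand) for f in a1.features
        ]


def test_genbank_reader(tmp_path, small_study):
    genome, ann = small_study.records[0]
    gb = tmp_path / "one.gb"
    _write_minimal_genbank(gb, genome, ann)
    pairs = read_records(gb, "genbank")
    assert len(pairs) == 1
    g, a = pairs[0]
    assert g.length_bp == genome.length_bp
    assert len(a.features) == len(ann.features)
    assert [(f.gene_key, f.start, f.end) for f in a.features] == [
        (f.gene_key, f.start, f.end) for f in ann.features
    ]


def _write_minimal_genbank(path, genome, ann):
    class_to_type = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    with open(path, "w") as fh:
        fh.write(
            f"LOCUS       {genome.record_id}  {genome.length_bp} bp    DNA  circular  INV\n"
        )
        fh.write(f"DEFINITION  synthetic mitogenome {genome.record_id}.\n")
        fh.write("FEATURES             Location/Qualifiers\n")
        for f in ann.features:
            loc = f"{f.start + 1}..{f.end}"  # GenBank is 1-based closed
            if f.strand == "-":
                loc = f"complement({loc})"
            fh.write(f"     {class_to_type[f.feature_class]:<16}{loc}\n")
            fh.write(f'                     /gene="{f.gene_key}"\n')
        fh.write("ORIGIN\n")
        seq = genome.sequence.lower()
        for i in range(0, len(seq), 60):
            chunk = seq[i : i + 60]
            blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            fh.write(f"{i + 1:>9} {blocks}\n")
        fh.write("//\n")


def test_extract_gene_order_classes_and_signs(small_study):
    genome, ann = small_study.records[0]
    pcg = extract_gene_order(ann, classes=("PCG",))
    assert len(pcg) == 12
    assert all(not e.startswith("-") for e in pcg.elements)
    full = extract_gene_order(ann, classes=("PCG", "tRNA", "rRNA"))
    assert len(full) == 36
    assert not any(e.lstrip("-").startswith("trn") for e in pcg.elements)


def test_extract_gene_order_duplicate_policy():
    feats = [
        GeneFeature("cox1", "PCG", 0, 300, "+"),
        GeneFeature("trnM", "tRNA", 310, 370, "+", quality=1e-9),
        GeneFeature("trnM", "tRNA", 400, 465, "+", quality=1e-3),
        GeneFeature("cob", "PCG", 500, 800, "+"),
    ]
    ann = AnnotationSet("dup", feats)
    order = extract_gene_order(ann, classes=("PCG", "tRNA"), duplicate_policy="best")
    assert list(order.elements) == ["cox1", "trnM", "cob"]
    # the kept copy is the better-quality (lower) one at 310
    with pytest.raises(MitoError):
        extract_gene_order(ann, classes=("PCG", "tRNA"), duplicate_policy="error")


def test_extract_gene_order_empty_after_filter():
    ann = AnnotationSet("e", [GeneFeature("trnM", "tRNA", 0, 60, "+")])
    with pytest.raises(MitoError):
        extract_gene_order(ann, classes=("PCG",))


def test_igrs_simple_circle():
    genome = MitoGenome("c", "A" * 400)
    ann = AnnotationSet(
        "c",
        [GeneFeature("g1", "PCG", 0, 100, "+"), GeneFeature("g2", "PCG", 150, 300, "+")],
    )
    compute_igrs(ann, genome)
    assert [(i.label, i.start, i.end) for i in ann.igrs] == [
        ("g1-g2", 100, 150),
        ("g2-g1", 300, 400 % 400),
    ]
    assert sum(i.length_on(400) for i in ann.igrs) == 400 - 250


def test_igrs_abutting_genes_yield_no_gap():
    genome = MitoGenome("c", "A" * 200)
    ann = AnnotationSet(
        "c",
        [GeneFeature("g1", "PCG", 0, 100, "+"), GeneFeature("g2", "PCG", 100, 200, "+")],
    )
    compute_igrs(ann, genome)
    assert ann.igrs == []


def test_igrs_with_wrapping_feature():
    genome = MitoGenome("c", "A" * 300)
    ann = AnnotationSet(
        "c",
        [
            GeneFeature("g1", "PCG", 250, 50, "+", wraps_origin=True),
            GeneFeature("g2", "PCG", 100, 200, "+"),
        ],
    )
    compute_igrs(ann, genome)
    labels = {(i.label, i.length_on(300)) for i in ann.igrs}
    assert labels == {("g1-g2", 50), ("g2-g1", 50)}


def test_feature_plus_igr_lengths_tile_genome(small_study):
    for genome, ann in small_study.records:
        compute_igrs(ann, genome)
        total = coding_coverage(ann, genome) + sum(
            i.length_on(genome.length_bp) for i in ann.igrs
        )
        assert total == genome.length_bp


def test_gene_order_rotation_covariance(small_study):
    genome, ann = small_study.records[0]
    base = extract_gene_order(ann, classes=("PCG",))
    off = 1000
    L = genome.length_bp
    rotated_feats = []
    for f in ann.features:
        s = (f.start - off) % L
        e = s + f.length_on(L)
        rotated_feats.append(
            GeneFeature(f.gene_key, f.feature_class, s, e if e <= L else e - L,
                        f.strand, wraps_origin=e > L)
        )
    rot = extract_gene_order(AnnotationSet("rot", rotated_feats), classes=("PCG",))
    doubled = rot.elements + rot.elements
    n = len(base.elements)
    assert any(doubled[i : i + n] == base.elements for i in range(n))
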