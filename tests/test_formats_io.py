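"""Format dialect contracts: strict parsing, boundary conversion, round-trips."""

import math

import pytest
from hypothesis import given, strategies as st

from orthofuzz.errors import FormatError, ValidationError
from orthofuzz.formats_io import (
    PROTEIN_ALPHABET,
    GeneModel,
    HitRecord,
    SequenceRecord,
    SupportTree,
    read_fasta,
    read_gff3,
    read_hit_table,
    read_newick,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_newick,
)

ids = st.text(alphabet="abcdefgh0123456789_.", min_size=1, max_size=12).filter(
    lambda s: not s.startswith(".")
)
residues = st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=50)


# ---------------------------------------------------------------------------
# FASTA


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMKV\n")
        (rec,) = read_fasta(p)
        assert rec.id == "a" and rec.residues == "MKV"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\n>a\nMV\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_lowercase_normalised_and_bad_residues_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nmkv\n")
        assert read_fasta(p)[0].residues == "MKV"
        p.write_text(">b\nMK1\n")
        with pytest.raises(ValidationError, match="alphabet"):
            read_fasta(p)

    @given(st.lists(st.tuples(ids, residues), min_size=1, max_size=8, unique_by=lambda t: t[0]))
    def test_round_trip(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("fasta") / "x.fasta"
        recs = [SequenceRecord(id=i, residues=r) for i, r in records]
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


# ---------------------------------------------------------------------------
# hit tables


class TestHitTable:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t100.00\t50\t0\t0\t1\t50\t1\t50\t1e-30\t100.0\n")
        (h,) = read_hit_table(p)
        assert h.query_id == "q" and h.subject_id == "s"
        assert h.percent_identity == 1.0
        assert h.bitscore == 100.0
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 50, 1, 50)

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "h.tsv"
        good = "q\ts\t100.00\t50\t0\t0\t1\t50\t1\t50\t1e-30\t100.0"
        p.write_text(good + "\n" + "\t".join(good.split("\t")[:11]) + "\n")
        with pytest.raises(FormatError, match="line 2"):
            read_hit_table(p)

    def test_extra_columns_warn_but_parse(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t90.00\t50\t5\t0\t1\t50\t1\t50\t1e-30\t100.0\textra\n")
        with pytest.warns(UserWarning, match="extra columns"):
            (h,) = read_hit_table(p)
        assert h.percent_identity == pytest.approx(0.9)

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t90.00\t50\t5\t0\t50\t1\t1\t50\t1e-30\t100.0\n")
        with pytest.raises(FormatError, match="line 1"):
            read_hit_table(p)

    @given(
        st.lists(
            st.tuples(
                ids, ids,
                st.floats(0, 1), st.integers(1, 500),
                st.integers(1, 100), st.integers(1, 100),
                st.floats(0, 1e-3), st.floats(0, 500),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_up_to_float_formatting(self, tmp_path_factory, raw):
        path = tmp_path_factory.mktemp("hits") / "h.tsv"
        recs = [
            HitRecord(
                query_id=q, subject_id=s, percent_identity=round(pid, 4), aln_len=alen,
                q_start=qs, q_end=qs + alen, s_start=ss, s_end=ss + alen,
                evalue=ev, bitscore=round(bs, 1),
            )
            for q, s, pid, alen, qs, ss, ev, bs in raw
        ]
        write_hit_table(recs, path)
        back = read_hit_table(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.query_id, a.subject_id) == (b.query_id, b.subject_id)
            assert a.percent_identity == pytest.approx(b.percent_identity, abs=1e-4)
            assert a.bitscore == pytest.approx(b.bitscore, abs=0.05)
            assert math.isclose(a.evalue, b.evalue, rel_tol=1e-2, abs_tol=1e-300)
            assert (a.q_start, a.q_end, a.s_start, a.s_end) == (b.q_start, b.q_end, b.s_start, b.s_end)


# ---------------------------------------------------------------------------
# GFF3


GFF_HEADER = "##gff-version 3\n"


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(
            GFF_HEADER
            + "c1\tx\tgene\t101\t160\t.\t+\t.\tID=g1\n"
            + "c1\tx\tmRNA\t101\t160\t.\t+\t.\tID=m1;Parent=g1\n"
            + "c1\tx\tCDS\t101\t160\t.\t+\t0\tID=m1.c;Parent=m1\n"
        )
        (model,) = read_gff3(p, species="sp")
        assert model.exons == ((100, 160),)
        assert model.strand == "+"

    def test_multi_cds_grouped_by_parent(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(
            GFF_HEADER
            + "c1\tx\tgene\t101\t220\t.\t+\t.\tID=g1\n"
            + "c1\tx\tmRNA\t101\t220\t.\t+\t.\tID=m1;Parent=g1\n"
            + "c1\tx\tCDS\t101\t160\t.\t+\t0\tID=m1.c;Parent=m1\n"
            + "c1\tx\tCDS\t181\t220\t.\t+\t0\tID=m1.c;Parent=m1\n"
        )
        (model,) = read_gff3(p)
        assert model.exons == ((100, 160), (180, 220))

    def test_orphan_cds_rejected(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(GFF_HEADER + "c1\tx\tCDS\t101\t160\t.\t+\t0\tID=c1\n")
        with pytest.raises(ValidationError, match="no mRNA parent"):
            read_gff3(p)

    def test_round_trip(self, tmp_path, rng):
        models = []
        for i in range(5):
            n_ex = int(rng.integers(1, 4))
            cursor = int(rng.integers(0, 500))
            exons = []
            for _ in range(n_ex):
                start = cursor + int(rng.integers(1, 50))
                end = start + int(rng.integers(30, 200))
                exons.append((start, end))
                cursor = end
            models.append(
                GeneModel(
                    model_id=f"m{i}", species="sp", seqid="c1",
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                    provenance="published" if rng.random() < 0.5 else "predicted",
                )
            )
        path = tmp_path / "rt.gff3"
        write_gff3(models, path)
        back = read_gff3(path, species="sp")
        assert len(back) == len(models)
        by_id = {m.model_id: m for m in back}
        for m in models:
            b = by_id[m.model_id]
            assert b.exons == m.exons
            assert b.strand == m.strand
            assert b.provenance == m.provenance


# ---------------------------------------------------------------------------
# Newick


class TestNewick:
    def test_internal_support_parsed(self):
        tree = SupportTree.from_newick("((A,B)95,C);")
        supports = [
            SupportTree.node_support(n)
            for n in tree.dtree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert supports == [95.0]

    def test_polytomy_preserved(self):
        tree = SupportTree.from_newick("(A,B,C);")
        assert len(tree.dtree.seed_node.child_nodes()) == 3

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),C;\n")
        with pytest.raises(FormatError):
            read_newick(p)

    def test_duplicate_leaves_rejected(self):
        with pytest.raises((ValidationError, FormatError)):
            SupportTree.from_newick("((A,A),B);")

    def test_round_trip_random_trees(self, tmp_path, rng):
        for trial in range(20):
            n = int(rng.integers(2, 17))
            nodes = [f"T{i}" for i in range(n)]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                a, b = nodes[i], nodes[j]
                support = int(rng.integers(0, 101))
                merged = f"({a},{b}){support}"
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
            text = nodes[0] + ";"
            tree = SupportTree.from_newick(text)
            path = tmp_path / f"t{trial}.nwk"
            write_newick(tree, path)
            back = read_newick(path)
            assert set(back.leaf_labels()) == set(tree.leaf_labels())
            assert back.bipartitions() == tree.bipartitions()

            def support_map(t):
                return {
                    SupportTree.leaf_set(nd): SupportTree.node_support(nd)
                    for nd in t.dtree.preorder_node_iter()
                    if not nd.is_leaf() and nd.parent_node is not None
                }

            assert support_map(back) == support_map(tree)
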