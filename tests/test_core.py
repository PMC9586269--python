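import logging

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix, make_samples
from texscreen.core import (
    FormatError,
    LinkageError,
    NormalizationError,
    SchemaError,
    gene_lengths_from_gff3,
    read_counts,
    read_rpkm,
    rpkm,
    write_rpkm,
)
from texscreen.simulate import SimulationConfig, simulate, write_fixture


def genes_frame(lengths: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"length_bp": list(lengths.values()), "annotation": ""},
        index=pd.Index(lengths.keys(), name="gene_id"),
    )


class TestRpkm:
    def test_direct_formula(self):
        # C=100, L=1000 bp, N=1e6 -> RPKM = 1e9*100/(1e6*1000) = 100
        cm = make_count_matrix(
            {"g1": [100, 0, 0, 0], "g2": [999_900, 10, 10, 10]}
        )
        expr = rpkm(cm, genes_frame({"g1": 1000, "g2": 5000}))
        assert expr.values.loc["g1", "f-hl"] == pytest.approx(100.0, rel=1e-12)
        assert expr.values.loc["g1", "f-fl"] == 0.0  # zero count -> zero RPKM

    def test_zero_iff_zero_count(self):
        cm = make_count_matrix({"g1": [3, 0, 1, 0], "g2": [5, 2, 0, 1]})
        expr = rpkm(cm, genes_frame({"g1": 700, "g2": 1500}))
        assert ((expr.values.to_numpy() == 0) == (cm.counts.to_numpy() == 0)).all()

    def test_scale_invariance_per_library(self):
        cm = make_count_matrix({"g1": [10, 4, 0, 2], "g2": [90, 7, 3, 5]})
        genes = genes_frame({"g1": 400, "g2": 2500})
        doubled = cm.counts.copy()
        doubled["f-fl"] *= 2
        cm2 = make_count_matrix({g: list(doubled.loc[g]) for g in doubled.index})
        e1, e2 = rpkm(cm, genes), rpkm(cm2, genes)
        np.testing.assert_allclose(
            e1.values["f-fl"], e2.values["f-fl"], rtol=1e-12
        )

    def test_sum_identity(self):
        # sum_g RPKM(g,j) * L(g) == 1e9 for every library when N is the column sum
        rng = np.random.default_rng(0)
        counts = {f"g{i}": list(rng.integers(0, 500, 4)) for i in range(40)}
        cm = make_count_matrix(counts)
        genes = genes_frame({g: int(l) for g, l in zip(counts, rng.integers(300, 9000, 40))})
        expr = rpkm(cm, genes)
        lengths = genes["length_bp"].to_numpy(dtype=float)
        totals = (expr.values.to_numpy() * lengths[:, None]).sum(axis=0)
        np.testing.assert_allclose(totals, 1e9, rtol=1e-6)

    def test_zero_library_total_rejected(self):
        cm = make_count_matrix({"g1": [5, 0, 1, 1], "g2": [2, 0, 3, 4]})
        with pytest.raises(NormalizationError, match="f-fl"):
            rpkm(cm, genes_frame({"g1": 500, "g2": 800}))

    def test_missing_length_rejected(self):
        cm = make_count_matrix({"g1": [5, 1, 1, 1], "g2": [2, 1, 3, 4]})
        with pytest.raises(LinkageError, match="g2"):
            rpkm(cm, genes_frame({"g1": 500}))

    def test_provenance_records_library_totals(self):
        cm = make_count_matrix({"g1": [5, 1, 1, 1], "g2": [2, 1, 3, 4]})
        expr = rpkm(cm, genes_frame({"g1": 500, "g2": 800}))
        assert expr.provenance["total_counts_per_library"]["f-hl"] == 7


class TestReadCounts:
    def test_negative_count_names_gene_and_library(self, tmp_path):
        paths = write_fixture(simulate(SimulationConfig(n_genes=50, seed=2)), tmp_path)
        text = paths["counts"].read_text().splitlines()
        gene, rest = text[3].split("\t", 1)
        fields = text[3].split("\t")
        fields[2] = "-4"
        text[3] = "\t".join(fields)
        paths["counts"].write_text("\n".join(text) + "\n")
        with pytest.raises(FormatError) as err:
            read_counts(paths["counts"], paths["genes"], paths["samples"])
        assert gene in str(err.value) and "f-fl" in str(err.value)

    def test_non_integer_count_rejected(self, tmp_path):
        paths = write_fixture(simulate(SimulationConfig(n_genes=50, seed=2)), tmp_path)
        text = paths["counts"].read_text().splitlines()
        fields = text[1].split("\t")
        fields[1] = "3.5"
        text[1] = "\t".join(fields)
        paths["counts"].write_text("\n".join(text) + "\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_counts(paths["counts"], paths["genes"], paths["samples"])

    def test_duplicate_gene_id_rejected(self, tmp_path):
        paths = write_fixture(simulate(SimulationConfig(n_genes=50, seed=2)), tmp_path)
        text = paths["counts"].read_text().splitlines()
        text.append(text[1])
        paths["counts"].write_text("\n".join(text) + "\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_counts(paths["counts"], paths["genes"], paths["samples"])

    def test_no_target_library_rejected(self, tmp_path):
        paths = write_fixture(simulate(SimulationConfig(n_genes=50, seed=2)), tmp_path)
        paths["samples"].write_text(
            paths["samples"].read_text().replace("\t1", "\t0")
        )
        with pytest.raises(SchemaError, match="is_target"):
            read_counts(paths["counts"], paths["genes"], paths["samples"])

    def test_gene_set_mismatch_rejected(self, tmp_path):
        paths = write_fixture(simulate(SimulationConfig(n_genes=50, seed=2)), tmp_path)
        text = paths["genes"].read_text().splitlines()
        del text[1]
        paths["genes"].write_text("\n".join(text) + "\n")
        with pytest.raises(LinkageError, match="only in counts"):
            read_counts(paths["counts"], paths["genes"], paths["samples"])

    def test_two_target_replicates_accepted(self, tmp_path):
        cfg = SimulationConfig(n_genes=30, replicates_per_sample=2, seed=4)
        paths = write_fixture(simulate(cfg), tmp_path)
        cm, _ = read_counts(paths["counts"], paths["genes"], paths["samples"])
        assert cm.target_libraries == ["f-hl-r1", "f-hl-r2"]
        assert len(cm.nontarget_libraries) == 6

    def test_missing_file_is_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="not found"):
            read_counts(tmp_path / "x.tsv", tmp_path / "y.tsv", tmp_path / "z.tsv")


def test_rpkm_write_read_round_trip(tmp_path):
    paths = write_fixture(simulate(SimulationConfig(n_genes=60, seed=8)), tmp_path)
    cm, genes = read_counts(paths["counts"], paths["genes"], paths["samples"])
    expr = rpkm(cm, genes)
    write_rpkm(expr, tmp_path / "rpkm.tsv", decimals=6)
    back = read_rpkm(tmp_path / "rpkm.tsv", paths["samples"])
    np.testing.assert_allclose(back.values, expr.values, atol=5e-7)
    pd.testing.assert_frame_equal(back.samples, expr.samples)


GFF_HEADER = "##gff-version 3\n"


class TestGff3Lengths:
    def test_single_exon_length(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            GFF_HEADER
            + "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
            + "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=geneA.t1;Parent=geneA\n"
            + "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=geneA.t1\n"
        )
        lengths = gene_lengths_from_gff3(gff)
        assert lengths.loc["geneA", "length_bp"] == 100

    def test_overlapping_exons_merge_to_union(self, tmp_path):
        # brute-force union of 1-based positions 101..200 and 151..250
        expected = len(set(range(101, 201)) | set(range(151, 251)))
        gff = tmp_path / "b.gff3"
        gff.write_text(
            GFF_HEADER
            + "chr1\tsrc\tgene\t101\t250\t.\t+\t.\tID=geneB\n"
            + "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=geneB.t1;Parent=geneB\n"
            + "chr1\tsrc\tmRNA\t151\t250\t.\t+\t.\tID=geneB.t2;Parent=geneB\n"
            + "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=geneB.t1\n"
            + "chr1\tsrc\texon\t151\t250\t.\t+\t.\tParent=geneB.t2\n"
        )
        lengths = gene_lengths_from_gff3(gff)
        assert lengths.loc["geneB", "length_bp"] == expected == 150

    def test_disjoint_exons_sum(self, tmp_path):
        gff = tmp_path / "c.gff3"
        gff.write_text(
            GFF_HEADER
            + "chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=geneC\n"
            + "chr1\tsrc\tmRNA\t1\t1000\t.\t+\t.\tID=geneC.t1;Parent=geneC\n"
            + "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=geneC.t1\n"
            + "chr1\tsrc\texon\t501\t700\t.\t+\t.\tParent=geneC.t1\n"
        )
        lengths = gene_lengths_from_gff3(gff)
        assert lengths.loc["geneC", "length_bp"] == 100 + 200

    def test_gene_without_exons_falls_back_to_span(self, tmp_path, caplog):
        gff = tmp_path / "d.gff3"
        gff.write_text(
            GFF_HEADER + "chr1\tsrc\tgene\t1001\t1500\t.\t-\t.\tID=geneD\n"
        )
        with caplog.at_level(logging.WARNING):
            lengths = gene_lengths_from_gff3(gff)
        assert lengths.loc["geneD", "length_bp"] == 500
        assert any("gene span" in rec.message for rec in caplog.records)

    def test_exon_with_unknown_parent_is_linkage_error(self, tmp_path):
        gff = tmp_path / "e.gff3"
        gff.write_text(
            GFF_HEADER
            + "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneE\n"
            + "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=ghost.t1\n"
        )
        with pytest.raises(LinkageError, match="unknown gene"):
            gene_lengths_from_gff3(gff)


def test_all_target_metadata_rejected():
    with pytest.raises(SchemaError):
        make_count_matrix(
            {"g1": [1, 1, 1, 1]},
            make_samples(targets=("f-hl", "f-fl", "af-hl", "m-hl")),
        )
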