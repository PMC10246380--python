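"""Domain-type invariants and format readers/writers."""

import numpy as np
import pandas as pd
import pytest

from hgtkit import io as hio
from hgtkit.io import ReportBundle, summarize_bundle, write_report
from hgtkit.model import (
    ExonInterval,
    ExpressionMatrix,
    GeneRecord,
    HgtCall,
    HgtStatus,
    OrthogroupTable,
    RoleMap,
)


class TestRoleMap:
    def test_requires_exactly_one_focal(self):
        with pytest.raises(ValueError, match="focal"):
            RoleMap.from_dict({"a": "donor_clade", "b": "relative_clade", "c": "outgroup"})
        with pytest.raises(ValueError, match="focal"):
            RoleMap.from_dict(
                {"a": "focal", "b": "focal", "c": "donor_clade",
                 "d": "relative_clade", "e": "outgroup"}
            )

    def test_requires_donor_relative_outgroup(self):
        with pytest.raises(ValueError, match="donor"):
            RoleMap.from_dict({"a": "focal", "b": "relative_clade", "c": "outgroup"})
        with pytest.raises(ValueError, match="outgroup"):
            RoleMap.from_dict({"a": "focal", "b": "donor_clade", "c": "relative_clade"})

    def test_accessors(self, roles):
        assert roles.focal == "Shim"
        assert set(roles.donor_species) == {"Vvin", "Tpla"}
        assert set(roles.outgroup_species) == {"Osat"}


class TestGeneRecord:
    def test_protein_length_excludes_terminal_stop(self):
        rec = GeneRecord("g", "s", "c", "+", [ExonInterval(1, 9)], "ATGAAATAA")
        assert rec.protein_len_aa == 2
        rec2 = GeneRecord("g", "s", "c", "+", [ExonInterval(1, 6)], "ATGAAA")
        assert rec2.protein_len_aa == 2

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneRecord("g", "s", "c", "+", [ExonInterval(1, 10), ExonInterval(5, 20)], "A" * 26)

    def test_partial_flag_for_frameshifted_cds(self):
        rec = GeneRecord("g", "s", "c", "+", [ExonInterval(1, 7)], "ATGAAAT")
        assert rec.partial

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            ExonInterval(10, 5)


class TestGeneModelReader:
    def _write(self, tmp_path, contig_len=300, exon_lines=None, strand="+"):
        rng = np.random.default_rng(0)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, contig_len))
        (tmp_path / "genome.fa").write_text(f">c1\n{contig}\n")
        exon_lines = exon_lines or [(1, 100), (201, 300)]
        lines = ["##gff-version 3",
                 f"c1\tx\tgene\t1\t300\t.\t{strand}\t.\tID=gene:g1",
                 f"c1\tx\tmRNA\t1\t300\t.\t{strand}\t.\tID=g1;Parent=gene:g1;species=sp1"]
        for k, (s, e) in enumerate(exon_lines, 1):
            lines.append(f"c1\tx\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID=cds{k};Parent=g1")
        (tmp_path / "genes.gff3").write_text("\n".join(lines) + "\n")
        return contig

    def test_plus_strand_two_exon_gene(self, tmp_path):
        contig = self._write(tmp_path)
        records = hio.read_gene_models(tmp_path / "genes.gff3", tmp_path / "genome.fa")
        rec = records["g1"]
        assert len(rec.exons) == 2
        assert rec.cds_length == 200
        assert rec.cds_seq == contig[:100] + contig[200:300]
        assert rec.species_id == "sp1"

    def test_minus_strand_reverse_complement(self, tmp_path):
        from Bio.Seq import Seq

        contig = self._write(tmp_path, strand="-", exon_lines=[(1, 99), (201, 300)])
        records = hio.read_gene_models(tmp_path / "genes.gff3", tmp_path / "genome.fa")
        expected = str(Seq(contig[:99] + contig[200:300]).reverse_complement())
        assert records["g1"].cds_seq == expected

    def test_out_of_bounds_exon_is_hard_error(self, tmp_path):
        self._write(tmp_path, exon_lines=[(1, 100), (201, 400)])
        with pytest.raises(ValueError, match="outside contig"):
            hio.read_gene_models(tmp_path / "genes.gff3", tmp_path / "genome.fa")

    def test_longest_cds_kept_among_transcripts(self, tmp_path):
        contig = self._write(tmp_path)
        extra = (
            "c1\tx\tmRNA\t1\t90\t.\t+\t.\tID=g1.short;Parent=gene:g1;species=sp1\n"
            "c1\tx\tCDS\t1\t90\t.\t+\t0\tID=cds_s;Parent=g1.short\n"
        )
        path = tmp_path / "genes.gff3"
        path.write_text(path.read_text() + extra)
        records = hio.read_gene_models(path, tmp_path / "genome.fa")
        assert set(records) == {"g1"}
        assert records["g1"].cds_length == 200


class TestExpressionReader:
    def test_basic_shape(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_id\tt1\tt2\tt3\tt4\ng1\t0.0\t1.5\t2\t3\ng2\t1\t0\t0\t9.5\n")
        expr = hio.read_expression(path)
        assert expr.frame.shape == (2, 4)
        assert expr.max_fpkm("g2") == 9.5

    def test_empty_body(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_id\tt1\tt2\n")
        expr = hio.read_expression(path)
        assert expr.frame.shape == (0, 2)

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_id\tt1\ng1\t-2.0\n")
        with pytest.raises(ValueError, match="negative"):
            hio.read_expression(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_id\tt1\tt2\ng1\t1.0\toops\n")
        with pytest.raises(ValueError, match="t2"):
            hio.read_expression(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_id\tt1\ng1\t1.0\ng1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            hio.read_expression(path)

    def test_missing_gene_treated_as_zero(self):
        expr = ExpressionMatrix(pd.DataFrame({"t": [1.0]}, index=["g1"]))
        assert expr.max_fpkm("nope") == 0.0


class TestOrthogroupTable:
    def test_duplicate_gene_across_groups_rejected(self):
        with pytest.raises(ValueError, match="appears in both"):
            OrthogroupTable({"og1": {"sp": ["g1"]}, "og2": {"sp": ["g1"]}})

    def test_copy_numbers(self):
        table = OrthogroupTable({"og1": {"a": ["x", "y"], "b": ["z"]}})
        assert table.copy_numbers(["a", "b", "c"]) == {"og1": {"a": 2, "b": 1, "c": 0}}


class TestReport:
    def _calls(self, n_hgt, n_with_introns):
        calls = [
            HgtCall(f"h{i}", f"og{i}", HgtStatus.HGT, expressed=True, functional=True)
            for i in range(n_hgt)
        ]
        introns = {f"h{i}": (2 if i < n_with_introns else 0) for i in range(n_hgt)}
        return calls, introns

    def test_intron_partition_is_consistent(self, tmp_path):
        calls, introns = self._calls(98, 72)
        summary = write_report(ReportBundle(calls=calls, introns_per_gene=introns), tmp_path)
        assert summary["total_hgt"] == 98
        assert summary["hgt_with_introns"] == 72
        assert summary["hgt_without_introns"] == 26
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "hgt_calls.tsv").exists()

    def test_empty_bundle_zero_counts(self, tmp_path):
        summary = write_report(ReportBundle(), tmp_path)
        assert summary["total_hgt"] == 0
        assert summary["n_genes_screened"] == 0

    def test_orphan_ids_rejected(self):
        calls, introns = self._calls(3, 1)
        bundle = ReportBundle(calls=calls, introns_per_gene=introns,
                              known_gene_ids={"h0", "h1"})
        with pytest.raises(ValueError, match="h2"):
            summarize_bundle(bundle)

    def test_functional_requires_expressed_transfer(self):
        with pytest.raises(ValueError):
            HgtCall("g", "og", HgtStatus.VERTICAL, functional=True)
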