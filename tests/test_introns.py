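"""Intron extraction, projection, provenance, and association statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from hgtkit.align import ProteinAlignment
from hgtkit.introns import (
    IntronRecord,
    analogous,
    architecture_stats,
    assign_intron_origin,
    chi_square_2x2,
    conservation_pattern,
    extract_introns,
    flag_long_intron_genes,
    intron_expression_association,
    intron_identity,
    project_intron_positions,
    score_intron_matches,
)
from hgtkit.model import ExonInterval, GeneRecord


def _gene(exons, strand="+", contig_len=300, seed=0):
    rng = np.random.default_rng(seed)
    contig = "".join("ACGT"[i] for i in rng.integers(0, 4, contig_len))
    cds_len = sum(e.end - e.start + 1 for e in exons)
    concat = "".join(contig[e.start - 1 : e.end] for e in sorted(exons))
    cds = str(Seq(concat).reverse_complement()) if strand == "-" else concat
    rec = GeneRecord("g1", "sp", "c1", strand, list(exons), cds,
                     partial=bool(cds_len % 3))
    return rec, contig


def test_two_exon_gene_yields_one_intron():
    rec, contig = _gene([ExonInterval(1, 99), ExonInterval(201, 300)])
    introns = extract_introns(rec, contig)
    assert len(introns) == 1
    intron = introns[0]
    assert (intron.start, intron.end, intron.length) == (100, 200, 101)
    assert intron.seq == contig[99:200]
    assert intron.phase == 99 % 3


def test_single_exon_gene_has_no_introns():
    rec, contig = _gene([ExonInterval(1, 300)])
    assert extract_introns(rec, contig) == []


def test_canonical_splice_flag():
    rec, contig = _gene([ExonInterval(1, 99), ExonInterval(201, 300)])
    contig = contig[:99] + "GT" + contig[101:198] + "AG" + contig[200:]
    intron = extract_introns(rec, contig)[0]
    assert intron.canonical
    contig2 = contig[:99] + "GC" + contig[101:]
    assert not extract_introns(rec, contig2)[0].canonical


def test_strand_invariance_of_transcript_oriented_introns():
    """The same gene read from the reverse-complemented contig gives identical
    transcript-oriented intron sequences and phases."""
    rec, contig = _gene([ExonInterval(1, 99), ExonInterval(201, 300)])
    fwd = extract_introns(rec, contig)
    n = len(contig)
    flipped_exons = sorted(
        ExonInterval(n - e.end + 1, n - e.start + 1) for e in rec.exons
    )
    rc_contig = str(Seq(contig).reverse_complement())
    rec_rc = GeneRecord("g1", "sp", "c1", "-", flipped_exons, rec.cds_seq)
    rev = extract_introns(rec_rc, rc_contig)
    assert [i.seq for i in fwd] == [i.seq for i in rev]
    assert [i.phase for i in fwd] == [i.phase for i in rev]


def test_exon_plus_intron_lengths_equal_gene_span(small_dataset):
    ds = small_dataset
    for gid, rec in ds.records.items():
        introns = extract_introns(rec, ds.genome[rec.contig])
        total = sum(len(e) for e in rec.exons) + sum(i.length for i in introns)
        assert total == rec.gene_length


def test_long_intron_flags_strict_threshold():
    def rec_with(length):
        return [IntronRecord("g", 1, 1, length, "G" * length, 0, 1)]

    flags = flag_long_intron_genes(
        {"a": rec_with(1500), "b": rec_with(1000), "c": []}
    )
    assert flags == {"a": True, "b": False, "c": False}


class TestProjection:
    def test_identical_genes_are_analogous(self):
        aln = ProteinAlignment(["x", "y"], ["M" * 20, "M" * 20])
        ix = [IntronRecord("x", 1, 1, 100, "G" * 100, 0, 10)]
        iy = [IntronRecord("y", 1, 1, 100, "G" * 100, 0, 10)]
        project_intron_positions(aln, {"x": ix, "y": iy})
        assert ix[0].aligned_column == iy[0].aligned_column == 9
        assert analogous(ix[0], iy[0])

    def test_phase_mismatch_not_analogous(self):
        a = IntronRecord("x", 1, 1, 100, "G" * 100, 0, 10, aligned_column=9)
        b = IntronRecord("y", 1, 1, 100, "G" * 100, 1, 10, aligned_column=9)
        assert not analogous(a, b)

    def test_trimmed_host_column_is_undefined(self):
        aln = ProteinAlignment(["x", "y"], ["MKV", "M-V"])
        ix = [IntronRecord("x", 1, 1, 100, "G" * 100, 0, 2)]
        project_intron_positions(aln, {"x": ix}, kept_columns=[0, 2])
        assert ix[0].aligned_column is None

    def test_conservation_pattern_matches_planted_donor_intron_case(self):
        """Transferred copy carries the donor's intron; the vertical focal copy
        is intronless — the donor+transfer positions coincide."""
        from hgtkit.simulate import IntronModel, SimulationConfig, simulate
        from hgtkit.introns import extract_introns

        cfg = SimulationConfig(
            seed=8, n_families=6, n_transfer_families=3, rate_dup=0, rate_loss=0,
            intron_model=IntronModel(mean_count=2.0, loss_prob_focal_vertical=1.0),
        )
        ds = simulate(cfg)
        seen = 0
        for og in ds.orthogroups:
            by_sp = ds.orthogroups[og]
            hgt = [g for g in by_sp.get("Shim", []) if ds.true_labels[g] == "hgt"]
            vert = [g for g in by_sp.get("Shim", []) if ds.true_labels[g] == "vertical"]
            if not hgt:
                continue
            intr = {
                g: extract_introns(ds.records[g], ds.genome[ds.records[g].contig])
                for g in hgt + vert + by_sp["Vvin"]
            }
            if not intr[hgt[0]]:
                continue
            assert all(not intr[g] for g in vert)
            donor = intr[by_sp["Vvin"][0]]
            assert [i.host_codon_index for i in intr[hgt[0]]] == [
                i.host_codon_index for i in donor
            ]
            seen += 1
        assert seen >= 1


class TestIdentity:
    def test_identical_sequences(self):
        seq = "GT" + "ACGT" * 30 + "AG"
        assert intron_identity(seq, seq) == 100.0

    def test_thirty_substitutions_in_120bp(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        mutated = list(seq)
        pos = rng.choice(120, size=30, replace=False)
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        ident = intron_identity(seq, "".join(mutated))
        assert ident == pytest.approx(75.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 140))
        assert intron_identity(a, b) == intron_identity(b, a)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            intron_identity("", "ACGT")

    def test_short_intron_skipped(self):
        q = IntronRecord("q", 1, 1, 80, "G" * 80, 0, 3, aligned_column=1)
        s = IntronRecord("s", 1, 1, 120, "G" * 120, 0, 3, aligned_column=1)
        assert score_intron_matches(q, {"donor": [s]}) == []
        assert score_intron_matches(s, {"donor": [q]}) == []


class TestOrigin:
    def _match(self, group, ident):
        from hgtkit.introns import IntronMatch

        return IntronMatch("q", "s", ident, group)

    def test_argmax_group(self):
        res = assign_intron_origin([self._match("donor", 95), self._match("relative", 70)])
        assert res.origin == "donor"
        assert res.mean_identity_by_group == {"donor": 95.0, "relative": 70.0}

    def test_tie_is_uncertain(self):
        res = assign_intron_origin([self._match("donor", 80), self._match("relative", 80)])
        assert res.origin == "uncertain"

    def test_no_matches(self):
        assert assign_intron_origin([]).origin == "uncertain"


def test_bed_export_uses_zero_based_half_open(tmp_path):
    rec, contig = _gene([ExonInterval(1, 99), ExonInterval(201, 300)])
    from hgtkit.introns import write_intron_bed

    introns = {"g1": extract_introns(rec, contig)}
    path = tmp_path / "introns.bed"
    write_intron_bed({"g1": rec}, introns, path)
    fields = path.read_text().strip().split("\t")
    assert fields[:3] == ["c1", "99", "200"]  # 1-based (100, 200) -> BED
    assert fields[4] == "101" and fields[5] == "+"


def test_architecture_stats_means():
    genes = {
        "grp": [
            GeneRecord("a", "sp", "c", "+", [ExonInterval(1, 30), ExonInterval(61, 90)],
                       "A" * 60),
            GeneRecord("b", "sp", "c", "+", [ExonInterval(1, 60)], "A" * 60),
        ],
        "empty": [],
    }
    introns = {
        "a": [IntronRecord("a", 1, 31, 60, "G" * 30, 0, 10)],
        "b": [],
    }
    stats = architecture_stats(genes, introns)
    assert set(stats) == {"grp"}
    s = stats["grp"]
    assert s.mean_intron_count == 0.5
    assert s.mean_total_intron_length == 15.0
    assert s.mean_cds_length == 60.0
    assert s.mean_gene_length == 75.0


def test_architecture_ordering_transferred_vs_vertical(small_dataset):
    """Transferred genes keep compact donor-derived introns while the focal
    vertical genes carry elongated ones; group means preserve that ordering."""
    ds = small_dataset
    groups = {"hgt_focal": [], "vertical_focal": []}
    for gid, label in ds.true_labels.items():
        groups["hgt_focal" if label == "hgt" else "vertical_focal"].append(ds.records[gid])
    introns = {
        gid: extract_introns(rec, ds.genome[rec.contig]) for gid, rec in ds.records.items()
    }
    stats = architecture_stats(groups, introns)
    assert (
        stats["hgt_focal"].mean_total_intron_length
        < stats["vertical_focal"].mean_total_intron_length
    )


def test_intronless_group_zero_total_length():
    genes = {"g": [GeneRecord("b", "sp", "c", "+", [ExonInterval(1, 60)], "A" * 60)]}
    assert architecture_stats(genes, {"b": []})["g"].mean_total_intron_length == 0.0


class TestChiSquare:
    def test_independence_table(self):
        chi2, p, yates = chi_square_2x2([[25, 25], [25, 25]])
        assert chi2 == 0.0 and p == 1.0 and not yates

    def test_closed_form_uncorrected(self):
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 30, 10, 10, 30
        expected = (a + b + c + d) * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        chi2, p, yates = chi_square_2x2([[a, b], [c, d]])
        assert not yates
        assert chi2 == pytest.approx(expected)
        assert expected == pytest.approx(20.0)

    def test_small_counts_get_yates(self):
        _, _, yates = chi_square_2x2([[2, 8], [3, 7]])
        assert yates

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2([[0, 0], [10, 10]])

    def test_association_wrapper(self):
        has_intron = {f"g{i}": i < 40 for i in range(80)}
        expressed = {f"g{i}": (i % 2 == 0) for i in range(80)}
        out = intron_expression_association(has_intron, expressed)
        assert out["n"] == 80
        assert out["p_value"] == pytest.approx(1.0)

    def test_type_one_error_calibration(self):
        """Under independence (n=80), rejection rate at alpha=0.05 stays near 0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            rows = rng.random(80) < 0.5
            cols = rng.random(80) < 0.5
            table = np.array(
                [
                    [np.sum(rows & cols), np.sum(rows & ~cols)],
                    [np.sum(~rows & cols), np.sum(~rows & ~cols)],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, p, _ = chi_square_2x2(table)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07
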