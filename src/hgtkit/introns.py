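"""Intron extraction, positional projection, provenance scoring, and
architecture statistics.

Introns are the gaps between consecutive CDS-defining exons, reported in
transcript orientation (minus-strand introns are reverse-complemented and
re-ordered 5'->3').  An intron is canonical when it starts with GT and ends
with AG on the transcript strand.  Intron *phase* is the cumulative CDS
length before the intron modulo 3; two introns from different genes are
"analogous" when they sit at the same protein-alignment column with the
same phase — the operational definition used for positional conservation
and for choosing which intron pairs to align globally.

Provenance: each focal intron is globally aligned against candidate introns
from donor-clade and relative-clade species at analogous positions; its
origin is the group of the best-identity subject (ties -> uncertain).  This
replaces a remote-database best-hit search with a self-contained candidate
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from scipy import stats

from .align import ProteinAlignment
from .model import GeneRecord

log = logging.getLogger(__name__)


@dataclass
class IntronRecord:
    gene_id: str
    ordinal: int
    """1-based, 5'->3' in transcript orientation."""
    start: int
    end: int
    seq: str
    phase: int
    host_codon_index: int
    """1-based codon immediately 5' of (or interrupted by) the intron."""
    aligned_column: int | None = None

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError(f"{self.gene_id} intron {self.ordinal}: length/sequence mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def splice_donor(self) -> str:
        return self.seq[:2]

    @property
    def splice_acceptor(self) -> str:
        return self.seq[-2:]

    @property
    def canonical(self) -> bool:
        return self.splice_donor == "GT" and self.splice_acceptor == "AG"


def extract_introns(gene: GeneRecord, contig_seq: str) -> list[IntronRecord]:
    """Introns of one gene, transcript-oriented; single-exon genes yield none."""
    exons = sorted(gene.exons)
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            raise ValueError(f"{gene.gene_id}: overlapping exons")
    exon_order = list(reversed(exons)) if gene.strand == "-" else exons
    records = []
    cum = 0
    gap_after = {}
    # map: transcript-order exon index -> genomic gap following it
    for k in range(len(exon_order) - 1):
        pair = (
            (exon_order[k], exon_order[k + 1])
            if gene.strand == "+"
            else (exon_order[k + 1], exon_order[k])
        )
        if pair[1].start - pair[0].end > 1:
            gap_after[k] = (pair[0].end + 1, pair[1].start - 1)
    for k, exon in enumerate(exon_order):
        cum += len(exon)
        if k not in gap_after:
            continue
        start, end = gap_after[k]
        raw = contig_seq[start - 1 : end]
        seq = str(Seq(raw).reverse_complement()) if gene.strand == "-" else raw
        phase = cum % 3
        host = cum // 3 if phase == 0 else cum // 3 + 1
        rec = IntronRecord(gene.gene_id, len(records) + 1, start, end, seq, phase, host)
        if not rec.canonical:
            log.debug("%s intron %d: non-canonical termini %s..%s",
                      gene.gene_id, rec.ordinal, rec.splice_donor, rec.splice_acceptor)
        records.append(rec)
    return records


def flag_long_intron_genes(
    introns_by_gene: Mapping[str, list[IntronRecord]], threshold_bp: int = 1000
) -> dict[str, bool]:
    """Flag genes harboring at least one intron strictly longer than the threshold."""
    return {
        gene: any(i.length > threshold_bp for i in introns)
        for gene, introns in introns_by_gene.items()
    }


def project_intron_positions(
    aln: ProteinAlignment,
    introns_by_gene: Mapping[str, list[IntronRecord]],
    kept_columns: list[int] | None = None,
) -> None:
    """Set ``aligned_column`` on each intron from its host codon's alignment column.

    When a trimmed alignment's kept-column map is supplied, columns removed
    by trimming leave the position undefined (and logged); the recorded
    index is then the trimmed-alignment column.
    """
    kept_index = {c: k for k, c in enumerate(kept_columns)} if kept_columns is not None else None
    for gene, introns in introns_by_gene.items():
        if gene not in aln.ids:
            continue
        n_res = len(aln.degapped(gene))
        for intron in introns:
            if intron.host_codon_index > n_res:
                intron.aligned_column = None
                continue
            col = aln.column_of_residue(gene, intron.host_codon_index)
            if kept_index is None:
                intron.aligned_column = col
            elif col in kept_index:
                intron.aligned_column = kept_index[col]
            else:
                log.info("%s intron %d: host codon column trimmed; position undefined",
                         gene, intron.ordinal)
                intron.aligned_column = None


def analogous(a: IntronRecord, b: IntronRecord) -> bool:
    """Same projected alignment column and same phase (both defined)."""
    return (
        a.aligned_column is not None
        and a.aligned_column == b.aligned_column
        and a.phase == b.phase
    )


def conservation_pattern(
    introns_by_gene: Mapping[str, list[IntronRecord]]
) -> dict[tuple[int, int], set[str]]:
    """(aligned_column, phase) -> genes carrying an intron at that position."""
    pattern: dict[tuple[int, int], set[str]] = {}
    for gene, introns in introns_by_gene.items():
        for intron in introns:
            if intron.aligned_column is None:
                continue
            pattern.setdefault((intron.aligned_column, intron.phase), set()).add(gene)
    return pattern


def write_intron_bed(
    records: Mapping[str, GeneRecord],
    introns_by_gene: Mapping[str, list[IntronRecord]],
    path,
) -> None:
    """Export intron intervals as BED6.

    Internally everything is 1-based closed; the 0-based half-open BED
    convention is applied here, at the format boundary only.  The score
    column carries the intron length.
    """
    with open(path, "w") as fh:
        for gene_id, introns in introns_by_gene.items():
            rec = records[gene_id]
            for intron in introns:
                fh.write(
                    f"{rec.contig}\t{intron.start - 1}\t{intron.end}\t"
                    f"{gene_id}.i{intron.ordinal}\t{intron.length}\t{rec.strand}\n"
                )


# ---------------------------------------------------------------------------
# Identity / provenance


@dataclass
class IntronMatch:
    query_id: str
    subject_id: str
    identity: float
    """Global-alignment identity %, matches / alignment columns x 100."""
    subject_group: str


def intron_identity(
    query_seq: str,
    subject_seq: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 2.0,
    gap_extend: float = 0.5,
) -> float:
    """Global nucleotide alignment identity in percent (gap columns count)."""
    if not query_seq or not subject_seq:
        raise ValueError("cannot align an empty intron sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    alignment = next(iter(aligner.align(query_seq.upper(), subject_seq.upper())))
    row_q, row_s = str(alignment[0]), str(alignment[1])
    matches = sum(a == b and a != "-" for a, b in zip(row_q, row_s))
    return 100.0 * matches / len(row_q)


def score_intron_matches(
    query: IntronRecord,
    subjects_by_group: Mapping[str, Iterable[IntronRecord]],
    min_len_bp: int = 100,
    require_analogous: bool = True,
) -> list[IntronMatch]:
    """Identity of a query intron against grouped candidate introns.

    Pairs where either sequence is shorter than ``min_len_bp`` are skipped
    (mirroring the >= 100 bp intron filter), as are non-analogous pairs
    unless ``require_analogous`` is off.
    """
    matches = []
    if query.length < min_len_bp:
        log.info("%s intron %d: below %d bp, skipped", query.gene_id, query.ordinal, min_len_bp)
        return matches
    for group, subjects in subjects_by_group.items():
        for subj in subjects:
            if subj.length < min_len_bp:
                continue
            if require_analogous and not analogous(query, subj):
                continue
            ident = intron_identity(query.seq, subj.seq)
            matches.append(
                IntronMatch(
                    f"{query.gene_id}.i{query.ordinal}",
                    f"{subj.gene_id}.i{subj.ordinal}",
                    ident,
                    group,
                )
            )
    return matches


@dataclass
class OriginAssignment:
    origin: str
    """Group of the max-identity subject, or 'uncertain' on a tie / no match."""
    best_identity: float | None
    mean_identity_by_group: dict[str, float]


def assign_intron_origin(matches: list[IntronMatch]) -> OriginAssignment:
    if not matches:
        return OriginAssignment("uncertain", None, {})
    by_group: dict[str, list[float]] = {}
    for m in matches:
        by_group.setdefault(m.subject_group, []).append(m.identity)
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    best = max(m.identity for m in matches)
    top_groups = {m.subject_group for m in matches if m.identity == best}
    origin = top_groups.pop() if len(top_groups) == 1 else "uncertain"
    return OriginAssignment(origin, best, means)


# ---------------------------------------------------------------------------
# Architecture statistics


@dataclass
class ArchitectureSummary:
    group: str
    n_genes: int
    mean_intron_count: float
    mean_total_intron_length: float
    mean_cds_length: float
    mean_gene_length: float


def architecture_stats(
    gene_groups: Mapping[str, list[GeneRecord]],
    introns_by_gene: Mapping[str, list[IntronRecord]],
) -> dict[str, ArchitectureSummary]:
    """Per-group means of intron count, total intron length, CDS and gene length."""
    out = {}
    for label, genes in gene_groups.items():
        if not genes:
            log.warning("architecture group %s is empty; omitted", label)
            continue
        counts = [len(introns_by_gene.get(g.gene_id, [])) for g in genes]
        total_len = [
            sum(i.length for i in introns_by_gene.get(g.gene_id, [])) for g in genes
        ]
        out[label] = ArchitectureSummary(
            label,
            len(genes),
            float(np.mean(counts)),
            float(np.mean(total_len)),
            float(np.mean([g.cds_length for g in genes])),
            float(np.mean([g.gene_length for g in genes])),
        )
    return out


# ---------------------------------------------------------------------------
# Expression association


def chi_square_2x2(
    table, correction: str = "auto"
) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df, two-sided) on a 2x2 table.

    ``correction`` is "auto" (Yates applied when any expected cell < 5),
    "always", or "never".  A zero marginal is a degenerate table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    expected = stats.contingency.expected_freq(t)
    if correction == "auto":
        yates = bool((expected < 5).any())
    elif correction == "always":
        yates = True
    elif correction == "never":
        yates = False
    else:
        raise ValueError("correction must be auto|always|never")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p), yates


def intron_expression_association(
    has_intron: Mapping[str, bool],
    expressed: Mapping[str, bool],
    correction: str = "auto",
) -> dict:
    """Test whether expression of transferred genes depends on intron presence."""
    genes = sorted(set(has_intron) & set(expressed))
    table = np.zeros((2, 2))
    for g in genes:
        table[0 if has_intron[g] else 1, 0 if expressed[g] else 1] += 1
    chi2, p, yates = chi_square_2x2(table, correction=correction)
    return {
        "table": table.astype(int).tolist(),
        "chi2": chi2,
        "p_value": p,
        "yates": yates,
        "n": len(genes),
    }
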