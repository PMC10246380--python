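"""Protein multiple alignment, gap-occupancy trimming, and codon back-translation.

The multiple aligner is a deterministic progressive aligner: pairwise global
Needleman-Wunsch scores (BLOSUM62, affine gaps) feed a UPGMA guide tree, and
profiles are merged with an affine profile-profile dynamic program.  The gap
convention throughout is that a gap of length k costs ``open + k * extend``
(default 10 + k).  Externally computed alignments (e.g. from MAFFT) are
accepted unchanged via :func:`ProteinAlignment.from_fasta`.

Column trimming keeps a column iff its fraction of non-gap residues is at
least the occupancy threshold (default 0.6, with >= semantics at the
boundary), and records the kept-column index map so intron positions can be
projected onto trimmed coordinates afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from numba import njit
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

GAP = "-"
_STOPS = set(standard_dna_table.stop_codons)

_AA = "ARNDCQEGHILKMFPSTWYVBZX"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def _blosum62_dense() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            m[i, j] = b62[a, b]
    return m


_B62 = _blosum62_dense()


@dataclass
class ProteinAlignment:
    """Ordered rows of equal-length gapped protein sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column_of_residue(self, seq_id: str, residue_index: int) -> int:
        """Alignment column (0-based) holding the 1-based residue of a sequence."""
        row = self.row(seq_id)
        seen = 0
        for col, ch in enumerate(row):
            if ch != GAP:
                seen += 1
                if seen == residue_index:
                    return col
        raise IndexError(f"{seq_id} has fewer than {residue_index} residues")

    def occupancy(self) -> np.ndarray:
        arr = np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            len(self.rows), self.n_columns
        )
        return (arr != b"-").mean(axis=0)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])


@dataclass
class CodonAlignment:
    """Codon-resolution alignment: 3 nucleotide columns per protein column."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1 or any(l % 3 for l in lens):
            raise ValueError("codon alignment rows must share a length divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


def _protein_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    # Biopython charges open_gap_score for the first gap position; with the
    # package convention (gap of length k costs open + k*extend) the first
    # position carries open + extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(
    seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> tuple[str, str, float]:
    """Global Needleman-Wunsch protein alignment; returns gapped rows and score."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _protein_aligner(gap_open, gap_extend)
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


@njit(cache=True)
def _affine_profile_dp(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap columns inserted into profile B
    Y = np.full((n + 1, m + 1), NEG)  # gap columns inserted into profile A
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
        PX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
        PY[0, j] = 2
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: consume one column from each profile
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = ptr
            # X: consume column i of A against a gap
            best = M[i - 1, j] - go
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
                ptr = 2
            X[i, j] = best
            PX[i, j] = ptr
            # Y: consume column j of B against a gap
            best = M[i, j - 1] - go
            ptr = 0
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            PY[i, j] = ptr
    # traceback
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        moves[k] = state
        if state == 0:
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = PX[i, j]
            i -= 1
        else:
            state = PY[i, j]
            j -= 1
        k += 1
    return moves[:k][::-1].copy()


def _profile_counts(rows: list[str]) -> np.ndarray:
    counts = np.zeros((len(rows[0]), len(_AA)))
    for row in rows:
        for col, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[col, idx] += 1
    return counts


def _merge_profiles(
    a_rows: list[str], b_rows: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    ca, cb = _profile_counts(a_rows), _profile_counts(b_rows)
    S = (ca @ _B62 @ cb.T) / (len(a_rows) * len(b_rows))
    moves = _affine_profile_dp(S, gap_open, gap_extend)
    out_a = [[] for _ in a_rows]
    out_b = [[] for _ in b_rows]
    i = j = 0
    for mv in moves:
        if mv == 0:
            for r, row in zip(out_a, a_rows):
                r.append(row[i])
            for r, row in zip(out_b, b_rows):
                r.append(row[j])
            i += 1
            j += 1
        elif mv == 1:
            for r, row in zip(out_a, a_rows):
                r.append(row[i])
            for r in out_b:
                r.append(GAP)
            i += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, b_rows):
                r.append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_proteins(
    seqs: dict[str, str], gap_open: float = 10.0, gap_extend: float = 1.0
) -> ProteinAlignment:
    """Deterministic progressive multiple alignment over a UPGMA guide tree."""
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    for sid in ids:
        if not seqs[sid]:
            raise ValueError(f"empty sequence: {sid}")
    upper = {sid: seqs[sid].upper() for sid in ids}
    if len(ids) == 2:
        r0, r1, _ = pairwise_align(upper[ids[0]], upper[ids[1]], gap_open, gap_extend)
        return ProteinAlignment(ids, [r0, r1])
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r0, r1, _ = pairwise_align(upper[ids[i]], upper[ids[j]], gap_open, gap_extend)
            matches = sum(a == b and a != GAP for a, b in zip(r0, r1))
            dist[i, j] = dist[j, i] = 1.0 - matches / len(r0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [upper[ids[i]]]) for i in range(n)
    }
    for k, (a, b, _d, _c) in enumerate(linkage):
        ia, ib = clusters.pop(int(a)), clusters.pop(int(b))
        rows_a, rows_b = _merge_profiles(ia[1], ib[1], gap_open, gap_extend)
        clusters[n + k] = (ia[0] + ib[0], rows_a + rows_b)
    merged_ids, merged_rows = clusters.popitem()[1]
    order = {sid: merged_rows[i] for i, sid in enumerate(merged_ids)}
    return ProteinAlignment(ids, [order[sid] for sid in ids])


@dataclass
class TrimResult:
    alignment: ProteinAlignment
    kept_columns: list[int]
    """Original-alignment column index of each retained column."""


def trim_columns(aln: ProteinAlignment, occupancy_threshold: float = 0.6) -> TrimResult:
    """Drop columns whose non-gap occupancy falls below the threshold.

    A column at exactly the threshold is kept (>= semantics); the returned
    kept-column map lets downstream positional analyses (intron projection)
    translate trimmed coordinates back to original columns.
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy threshold must be in (0, 1]")
    occ = aln.occupancy()
    kept = [c for c in range(aln.n_columns) if occ[c] >= occupancy_threshold]
    rows = ["".join(row[c] for c in kept) for row in aln.rows]
    return TrimResult(ProteinAlignment(list(aln.ids), rows), kept)


def back_translate(aln: ProteinAlignment, cds_by_id: dict[str, str]) -> CodonAlignment:
    """Thread each CDS back through its aligned protein row ('-' becomes '---').

    A terminal stop codon on the CDS is trimmed (and logged); any other
    translation discordance is an error naming the gene and the first
    discordant codon.
    """
    rows = []
    for sid in aln.ids:
        cds = cds_by_id[sid].upper()
        if len(cds) % 3:
            raise ValueError(f"{sid}: CDS length {len(cds)} not divisible by 3")
        if cds[-3:] in _STOPS:
            log.info("%s: trimming terminal stop codon before back-translation", sid)
            cds = cds[:-3]
        protein = aln.degapped(sid)
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{sid}: CDS has {len(cds) // 3} codons but protein row has {len(protein)}"
            )
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        for idx, (codon, res) in enumerate(zip(codons, protein)):
            trans = str(Seq(codon).translate())
            if trans != res and trans != "X" and res != "X":
                raise ValueError(
                    f"{sid}: codon {idx + 1} ({codon} -> {trans}) does not encode residue {res}"
                )
        out = []
        k = 0
        for ch in aln.row(sid):
            if ch == GAP:
                out.append(GAP * 3)
            else:
                out.append(codons[k])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(list(aln.ids), rows)
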