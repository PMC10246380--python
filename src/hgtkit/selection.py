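"""Counting-method (Nei-Gojobori 1986) dN/dS estimation and regime calls.

The estimator counts synonymous and nonsynonymous *sites* from the
single-nucleotide mutational neighborhood of each codon under the standard
genetic code (mutations to stop codons are excluded from the neighborhood),
and synonymous and nonsynonymous *differences* by averaging over all
substitution pathways between a codon pair that avoid stop codons, with
equal pathway weights.  Proportions are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p).

Interpretation follows the standard convention: omega < 1 purifying,
omega = 1 neutral, omega > 1 positive selection.  Estimates carry a
configurable neutrality band (default +/- 0.1) because a point estimate is
never exactly 1.  For lineage contrasts the foreground set is the
horizontally transferred genes and the background set everything else; an
adapter accepting externally computed branch-model omega tables
(:func:`read_external_omega`) lets likelihood-based workflows plug in.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

_TABLE = dict(standard_dna_table.forward_table)
_STOPS = frozenset(standard_dna_table.stop_codons)
_NTS = "ACGT"
_SENSE = [a + b + c for a in _NTS for b in _NTS for c in _NTS if a + b + c not in _STOPS]


def synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites of a sense codon (0..3) from its mutational neighborhood.

    Each position contributes one site, apportioned by the fraction of
    non-stop single-nucleotide changes at that position that are synonymous.
    """
    codon = codon.upper()
    aa = _TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = non_stop = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            non_stop += 1
            if _TABLE[alt] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


_SITE_FRACTIONS = {c: synonymous_site_fraction(c) for c in _SENSE}


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over stop-free pathways.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded (if every pathway is blocked,
    all are kept — the classic fallback for the rare fully-blocked pairs).
    """
    a, b = codon_a.upper(), codon_b.upper()
    diff_pos = [k for k in range(3) if a[k] != b[k]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        steps = []
        cur = a
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:
        for order in itertools.permutations(diff_pos):
            steps = []
            cur = a
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            pathways.append(steps)
    syn = nonsyn = 0.0
    for steps in pathways:
        for pre, post in steps:
            pre_aa = _TABLE.get(pre)
            post_aa = _TABLE.get(post)
            if pre_aa is not None and pre_aa == post_aa:
                syn += 1
            else:
                nonsyn += 1
    k = len(pathways)
    return syn / k, nonsyn / k


@dataclass
class CodonPairCounts:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    codons_compared: int
    codons_skipped: int


class RegimeFlag(str, Enum):
    DS_ZERO = "dS_zero"
    SATURATED_DS = "saturated_dS"
    SATURATED_DN = "saturated_dN"
    TOO_FEW_CODONS = "too_few_codons"


@dataclass
class DnDsEstimate:
    dN: float | None
    dS: float | None
    omega: float | None
    flags: set[RegimeFlag] = field(default_factory=set)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _usable(codon: str) -> bool:
    return all(nt in _NTS for nt in codon) and codon not in _STOPS


def ng86_pair(
    codon_seq_a: str, codon_seq_b: str, min_codons: int = 10
) -> tuple[CodonPairCounts, DnDsEstimate]:
    """NG86 site/difference counts and JC-corrected dN, dS for one sequence pair.

    Sequences must be equal-length and frame-aligned; codons containing gaps,
    ambiguity codes, or stops in either sequence are skipped and tallied as
    ``codons_skipped``.
    """
    a, b = codon_seq_a.upper(), codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("codon sequences differ in length")
    if len(a) % 3:
        raise ValueError("codon sequence length not divisible by 3")
    S_a = S_b = Sd = Nd = 0.0
    compared = skipped = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if not (_usable(ca) and _usable(cb)):
            skipped += 1
            continue
        compared += 1
        S_a += _SITE_FRACTIONS[ca]
        S_b += _SITE_FRACTIONS[cb]
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    S_sites = 0.5 * (S_a + S_b)
    N_sites = 3.0 * compared - S_sites
    counts = CodonPairCounts(S_sites, N_sites, Sd, Nd, compared, skipped)

    flags: set[RegimeFlag] = set()
    if compared < min_codons:
        flags.add(RegimeFlag.TOO_FEW_CODONS)
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if dS is None:
        flags.add(RegimeFlag.SATURATED_DS)
    if dN is None:
        flags.add(RegimeFlag.SATURATED_DN)
    omega = None
    if dS is not None and dN is not None:
        if dS == 0.0:
            flags.add(RegimeFlag.DS_ZERO)
        elif not flags & {RegimeFlag.TOO_FEW_CODONS}:
            omega = dN / dS
    return counts, DnDsEstimate(dN, dS, omega, flags)


class Regime(str, Enum):
    PURIFYING = "purifying"
    NEUTRAL = "neutral"
    POSITIVE = "positive"
    UNDEFINED = "undefined"


def classify_regime(omega: float | None, epsilon: float = 0.1) -> Regime:
    """Map an omega estimate to a selection regime with a neutral band of +/- epsilon."""
    if omega is None:
        return Regime.UNDEFINED
    if omega < 1.0 - epsilon:
        return Regime.PURIFYING
    if omega > 1.0 + epsilon:
        return Regime.POSITIVE
    return Regime.NEUTRAL


@dataclass
class SetOmega:
    omega: float | None
    dN: float | None
    dS: float | None
    n_pairs: int
    flags: set[RegimeFlag] = field(default_factory=set)


def pairs_omega(pairs: list[tuple[str, str]], min_codons: int = 10) -> SetOmega:
    """Set-level omega from a list of codon-sequence pairs.

    dN and dS are averaged over informative pairs weighted by the number of
    compared codons; omega = mean(dN) / mean(dS).
    """
    num_dn = num_ds = wsum = 0.0
    n_used = 0
    flags: set[RegimeFlag] = set()
    for sa, sb in pairs:
        counts, est = ng86_pair(sa, sb, min_codons=min_codons)
        if est.dN is None or est.dS is None:
            flags |= est.flags
            continue
        if RegimeFlag.TOO_FEW_CODONS in est.flags:
            flags.add(RegimeFlag.TOO_FEW_CODONS)
            continue
        w = counts.codons_compared
        num_dn += w * est.dN
        num_ds += w * est.dS
        wsum += w
        n_used += 1
    if n_used == 0 or wsum == 0:
        return SetOmega(None, None, None, 0, flags or {RegimeFlag.TOO_FEW_CODONS})
    dN, dS = num_dn / wsum, num_ds / wsum
    if dS == 0.0:
        return SetOmega(None, dN, dS, n_used, flags | {RegimeFlag.DS_ZERO})
    return SetOmega(dN / dS, dN, dS, n_used, flags)


@dataclass
class LineageSelectionCall:
    orthogroup_id: str
    foreground_genes: list[str]
    background_genes: list[str]
    omega_fg: float | None
    omega_bg: float | None
    regime_fg: Regime
    regime_bg: Regime
    epsilon: float = 0.1


def _p_distance(a: str, b: str) -> float:
    valid = [(x, y) for x, y in zip(a, b) if x in _NTS and y in _NTS]
    if not valid:
        return 1.0
    return sum(x != y for x, y in valid) / len(valid)


def lineage_omega(
    codon_rows: dict[str, str],
    orthogroup_id: str,
    foreground: list[str],
    donor_partners: list[str],
    background: list[str],
    epsilon: float = 0.1,
    min_codons: int = 10,
) -> LineageSelectionCall:
    """Foreground/background omega contrast from pairwise NG86 estimates.

    Foreground pairs are each transferred gene with its closest donor-clade
    partner (smallest raw nucleotide p-distance on the codon alignment), a
    desk-scale surrogate for the post-transfer branch; background pairs are
    all pairs among the background (vertically inherited) genes.
    """
    fg_pairs = []
    for gene in foreground:
        partners = [p for p in donor_partners if p != gene]
        if not partners:
            continue
        best = min(partners, key=lambda p: (_p_distance(codon_rows[gene], codon_rows[p]), p))
        fg_pairs.append((codon_rows[gene], codon_rows[best]))
    bg_pairs = [
        (codon_rows[a], codon_rows[b]) for a, b in itertools.combinations(sorted(background), 2)
    ]
    fg = pairs_omega(fg_pairs, min_codons=min_codons)
    bg = pairs_omega(bg_pairs, min_codons=min_codons)
    return LineageSelectionCall(
        orthogroup_id,
        list(foreground),
        list(background),
        fg.omega,
        bg.omega,
        classify_regime(fg.omega, epsilon),
        classify_regime(bg.omega, epsilon),
        epsilon,
    )


def read_external_omega(path) -> pd.DataFrame:
    """Adapter for externally computed branch-model omega tables.

    Expects a TSV with columns ``orthogroup_id``, ``omega_fg``, ``omega_bg``;
    regimes are re-derived with :func:`classify_regime` so the decision logic
    stays identical regardless of the estimator that produced the table.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"orthogroup_id", "omega_fg", "omega_bg"}
    if not required <= set(df.columns):
        raise ValueError(f"external omega table must have columns {sorted(required)}")
    df["regime_fg"] = [classify_regime(v).value for v in df["omega_fg"]]
    df["regime_bg"] = [classify_regime(v).value for v in df["omega_bg"]]
    return df
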