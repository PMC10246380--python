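"""Copy-number classification of orthogroups and category enrichment.

An orthogroup's copy-number vector (focal species vs each other species) is
assigned exactly one category by a fixed precedence order:

1. all counts zero                          -> unclassified
2. focal > 0, all others 0                  -> focal_specific
3. focal == 0, all others exactly 1         -> lost_exact_0_1
4. focal == 0, all others >= 1, some > 1    -> lost_0_n
5. focal == 1, all others exactly 1         -> single_copy_1_1
6. focal == 2, all others exactly 1         -> dup_exact_2_1
7. focal >= 2 * c_s for every other s,
   every other count >= 2                   -> dup_2n_n
8. anything else                            -> unclassified

The "at least 2n:n (n > 1)" duplication reading requires the focal count to
be at least twice every other species' count with all other counts >= 2; a
``strict`` mode additionally requires all non-focal counts to be equal, for
sensitivity analysis against the literal 2n:n phrasing.

Enrichment of annotation categories in a gene set against a background uses
the two-sided Fisher exact test (hypergeometric 2x2) with
Benjamini-Hochberg q-values across categories; raw p-values are preserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from scipy import stats


class OrthogroupCategory(str, Enum):
    SINGLE_COPY_1_1 = "single_copy_1_1"
    LOST_EXACT_0_1 = "lost_exact_0_1"
    LOST_0_N = "lost_0_n"
    DUP_EXACT_2_1 = "dup_exact_2_1"
    DUP_2N_N = "dup_2n_n"
    FOCAL_SPECIFIC = "focal_specific"
    UNCLASSIFIED = "unclassified"


LOST_CATEGORIES = {OrthogroupCategory.LOST_EXACT_0_1, OrthogroupCategory.LOST_0_N}
DUP_CATEGORIES = {OrthogroupCategory.DUP_EXACT_2_1, OrthogroupCategory.DUP_2N_N}


def classify_orthogroup(
    counts: Mapping[str, int], focal: str, strict_2n_n: bool = False
) -> OrthogroupCategory:
    """Assign one category to a copy-number vector (first precedence match wins)."""
    if focal not in counts:
        raise KeyError(f"focal species {focal!r} absent from copy-number vector")
    f = counts[focal]
    others = [counts[s] for s in counts if s != focal]
    if f < 0 or any(c < 0 for c in others):
        raise ValueError("copy numbers must be non-negative")
    if f == 0 and all(c == 0 for c in others):
        return OrthogroupCategory.UNCLASSIFIED
    if f > 0 and all(c == 0 for c in others):
        return OrthogroupCategory.FOCAL_SPECIFIC
    if f == 0 and all(c == 1 for c in others):
        return OrthogroupCategory.LOST_EXACT_0_1
    if f == 0 and all(c >= 1 for c in others) and any(c > 1 for c in others):
        return OrthogroupCategory.LOST_0_N
    if f == 1 and all(c == 1 for c in others):
        return OrthogroupCategory.SINGLE_COPY_1_1
    if f == 2 and all(c == 1 for c in others):
        return OrthogroupCategory.DUP_EXACT_2_1
    if (
        others
        and all(c >= 2 for c in others)
        and all(f >= 2 * c for c in others)
        and (not strict_2n_n or len(set(others)) == 1)
    ):
        return OrthogroupCategory.DUP_2N_N
    return OrthogroupCategory.UNCLASSIFIED


@dataclass
class CategorySummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_total: int
    fraction_lost_conserved_denominator: float | None
    """lost / orthogroups with >= 1 copy in every non-focal species."""
    fraction_lost_any_denominator: float | None
    """lost / orthogroups with >= 1 copy in at least one non-focal species."""


def summarize_categories(
    vectors: Mapping[str, Mapping[str, int]], focal: str, strict_2n_n: bool = False
) -> tuple[dict[str, OrthogroupCategory], CategorySummary]:
    """Classify every vector and tabulate counts, fractions, and loss rates.

    Two loss denominators are reported because "conserved among the other
    species" can mean present in *all* of them or in *at least one*; the
    first is the headline fraction.
    """
    labels: dict[str, OrthogroupCategory] = {}
    conserved_all = conserved_any = lost_all = lost_any = 0
    for og, counts in vectors.items():
        cat = classify_orthogroup(counts, focal, strict_2n_n=strict_2n_n)
        labels[og] = cat
        others = [counts[s] for s in counts if s != focal]
        in_all = bool(others) and all(c >= 1 for c in others)
        in_any = any(c >= 1 for c in others)
        conserved_all += in_all
        conserved_any += in_any
        if cat in LOST_CATEGORIES:
            lost_all += in_all
            lost_any += in_any
    tally = Counter(cat.value for cat in labels.values())
    counts_out = {cat.value: tally.get(cat.value, 0) for cat in OrthogroupCategory}
    n = len(labels)
    summary = CategorySummary(
        counts=counts_out,
        fractions={k: (v / n if n else 0.0) for k, v in counts_out.items()},
        n_total=n,
        fraction_lost_conserved_denominator=(lost_all / conserved_all if conserved_all else None),
        fraction_lost_any_denominator=(lost_any / conserved_any if conserved_any else None),
    )
    return labels, summary


@dataclass
class EnrichmentResult:
    annotation_category: str
    k_in_set: int
    n_set: int
    K_in_background: int
    N_background: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None

    def __post_init__(self):
        if not (
            self.k_in_set <= self.n_set
            and self.K_in_background <= self.N_background
            and self.k_in_set <= self.K_in_background
        ):
            raise ValueError("inconsistent enrichment table counts")


def fisher_enrichment(
    gene_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of annotation categories in a gene set.

    The background defaults to all annotated genes.  Benjamini-Hochberg
    q-values are computed across categories; raw p-values are kept alongside.
    """
    background = set(background) if background is not None else set(annotations)
    if not background:
        raise ValueError("empty background")
    genes = set(gene_set) & background
    categories = sorted({c for g in background for c in annotations.get(g, [])})
    results = []
    for cat in categories:
        in_cat = {g for g in background if cat in annotations.get(g, [])}
        k = len(genes & in_cat)
        table = [
            [k, len(genes) - k],
            [len(in_cat) - k, len(background) - len(genes) - (len(in_cat) - k)],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(cat, k, len(genes), len(in_cat), len(background), float(odds), float(p))
        )
    if results:
        qs = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results
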