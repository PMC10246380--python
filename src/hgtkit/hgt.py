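"""Clade-placement screen for host-to-parasite horizontal gene transfer.

A focal-species gene is called a transfer when the smallest rooted clade
containing it and at least one donor-clade leaf excludes every
relative-clade leaf, the stem support of that clade passes the gate
(default 50%), and the encoded protein exceeds the length filter
(> 150 aa).  The symmetric condition — smallest clade containing the focal
gene and a relative-clade leaf excluding all donor leaves — yields a
vertical call under the same support gate.  Anything else is unresolved;
in particular a tree lacking donor-clade (or relative-clade) homologs
altogether cannot support either verdict: absence of evidence is not
placement.  Intervening leaves from other taxa inside the defining clade
are tolerated (only relative-clade leaves disqualify a transfer clade) and
logged.  The same classifier serves nuclear and mitochondrial gene sets.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping

import pandas as pd

from .model import ExpressionMatrix, HgtCall, HgtStatus, Role, RoleMap
from .phylo import Clade, GeneTree

log = logging.getLogger(__name__)


def classify_gene(
    tree: GeneTree,
    focal_gene: str,
    species_of: Callable[[str], str] | Mapping[str, str],
    roles: RoleMap,
    support_threshold: float = 50.0,
    protein_len_aa: int | None = None,
    min_protein_aa: int = 150,
    orthogroup_id: str = "",
    compartment: str = "nuclear",
) -> HgtCall:
    """Classify one focal gene on a rooted, support-annotated gene tree.

    Multiple focal paralogs in an orthogroup are classified independently
    (post-transfer duplications yield several transfer calls in one group).
    """
    lookup = species_of if callable(species_of) else species_of.__getitem__
    leaves = tree.leaf_names
    if focal_gene not in leaves:
        raise KeyError(f"focal gene {focal_gene} absent from tree")
    donor = {l for l in leaves if roles.role_of(lookup(l)) is Role.DONOR}
    relative = {l for l in leaves if roles.role_of(lookup(l)) is Role.RELATIVE}
    if not donor and not relative:
        raise ValueError("uninformative tree: no donor-clade or relative-clade leaves")

    if protein_len_aa is not None and protein_len_aa <= min_protein_aa:
        return HgtCall(focal_gene, orthogroup_id, HgtStatus.EXCLUDED_SHORT,
                       compartment=compartment)

    chain = tree.ancestor_clades(focal_gene)

    def first_containing(targets: set[str]) -> Clade | None:
        for clade in chain:
            if clade.leaves & targets:
                return clade
        return None

    def gate(clade: Clade) -> bool:
        return clade.support is not None and clade.support >= support_threshold

    c_donor = first_containing(donor) if donor else None
    c_rel = first_containing(relative) if relative else None

    if donor and relative and c_donor is not None and not (c_donor.leaves & relative):
        if gate(c_donor):
            extra = {
                l for l in c_donor.leaves
                if l != focal_gene and roles.role_of(lookup(l)) not in (Role.DONOR, Role.FOCAL)
            }
            if extra:
                log.info("%s: transfer clade contains non-donor leaves %s",
                         focal_gene, sorted(extra))
            return HgtCall(
                focal_gene, orthogroup_id, HgtStatus.HGT,
                clade_support=c_donor.support,
                donor_clade_members=sorted(c_donor.leaves & donor),
                compartment=compartment,
            )
        return HgtCall(focal_gene, orthogroup_id, HgtStatus.UNRESOLVED,
                       clade_support=c_donor.support, compartment=compartment,
                       note="transfer topology below support gate")
    if donor and relative and c_rel is not None and not (c_rel.leaves & donor):
        if gate(c_rel):
            return HgtCall(focal_gene, orthogroup_id, HgtStatus.VERTICAL,
                           clade_support=c_rel.support, compartment=compartment)
        return HgtCall(focal_gene, orthogroup_id, HgtStatus.UNRESOLVED,
                       clade_support=c_rel.support, compartment=compartment,
                       note="vertical topology below support gate")
    return HgtCall(focal_gene, orthogroup_id, HgtStatus.UNRESOLVED,
                   compartment=compartment,
                   note="" if donor and relative else "missing donor or relative homologs")


def flag_functional(
    calls: Iterable[HgtCall], expr: ExpressionMatrix, fpkm_threshold: float = 1.0
) -> list[HgtCall]:
    """Set expressed (max FPKM across tissues > threshold) and functional flags.

    A gene absent from the matrix is unexpressed; functional means an
    expressed transfer call.
    """
    out = []
    for call in calls:
        call.expressed = expr.max_fpkm(call.gene_id) > fpkm_threshold
        call.functional = call.expressed and call.status is HgtStatus.HGT
        out.append(call)
    return out


def gene_content_matrix(
    per_taxon_genes: Mapping[str, Iterable[str]],
    focal_taxon: str,
    focal_status: Mapping[str, Iterable[HgtStatus]],
    pseudogenes: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Native/foreign/absent gene-content matrix (genes x taxa).

    Focal-taxon cells are driven by the screen: a gene with both a transfer
    and a vertical copy is native+foreign, transfer-only is foreign,
    otherwise native.  Pseudogene annotations override.
    """
    pseudogenes = {t: set(v) for t, v in (pseudogenes or {}).items()}
    gene_names = sorted(
        {g for genes in per_taxon_genes.values() for g in genes} | set(focal_status)
    )
    taxa = list(per_taxon_genes)
    data = {}
    for taxon in taxa:
        present = set(per_taxon_genes[taxon])
        col = []
        for gene in gene_names:
            if gene in pseudogenes.get(taxon, ()):
                col.append("pseudogene")
            elif taxon == focal_taxon and gene in focal_status:
                statuses = set(focal_status[gene])
                has_hgt = HgtStatus.HGT in statuses
                has_native = bool(statuses - {HgtStatus.HGT, HgtStatus.EXCLUDED_SHORT})
                if has_hgt and has_native:
                    col.append("native+foreign")
                elif has_hgt:
                    col.append("foreign")
                elif gene in present or has_native:
                    col.append("native")
                else:
                    col.append("absent")
            elif gene in present:
                col.append("native")
            else:
                col.append("absent")
        data[taxon] = col
    return pd.DataFrame(data, index=gene_names)


def convergence_report(
    categories_by_lineage: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, set[str]]:
    """Presence matrix of annotation categories across parasite lineages.

    Returns the boolean table (category x lineage) and the subset of
    categories shared by every lineage — the convergent-transfer functions.
    """
    lineages = list(categories_by_lineage)
    cats = sorted({c for v in categories_by_lineage.values() for c in v})
    table = pd.DataFrame(
        {lin: [c in set(categories_by_lineage[lin]) for c in cats] for lin in lineages},
        index=cats,
    )
    shared = set(table.index[table.all(axis=1)]) if lineages else set()
    return table, shared
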