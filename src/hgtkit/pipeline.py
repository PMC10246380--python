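"""End-to-end orchestration: families -> trees -> transfer calls -> introns ->
selection -> report.

`run_hgt_screen` is the per-family engine: align proteins, trim at 0.6
occupancy, build an NJ tree with bootstrap supports, root at the outgroup
and classify every focal gene.  Families whose trees cannot be built (too
few homologs, no outgroup leaf) yield unresolved calls with a note rather
than silently disappearing.  `run_pipeline` strings every stage together on
a synthetic dataset and writes the standard report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import ProteinAlignment, TrimResult, align_proteins, back_translate, trim_columns
from .hgt import classify_gene, flag_functional
from .introns import (
    IntronRecord,
    assign_intron_origin,
    extract_introns,
    flag_long_intron_genes,
    intron_expression_association,
    project_intron_positions,
    score_intron_matches,
)
from .io import ReportBundle, summarize_bundle, write_report
from .model import GeneRecord, HgtCall, HgtStatus, OrthogroupTable, Role, RoleMap
from .phylo import GeneTree, bootstrap_support
from .selection import LineageSelectionCall, lineage_omega
from .simulate import SimulationConfig, SyntheticDataset, simulate

log = logging.getLogger(__name__)


@dataclass
class FamilyAnalysis:
    orthogroup_id: str
    calls: list[HgtCall] = field(default_factory=list)
    alignment: ProteinAlignment | None = None
    trim: TrimResult | None = None
    tree: GeneTree | None = None


def _unresolved(gene: str, og: str, note: str) -> HgtCall:
    return HgtCall(gene, og, HgtStatus.UNRESOLVED, note=note)


def run_hgt_screen(
    records: dict[str, GeneRecord],
    orthogroups: OrthogroupTable,
    roles: RoleMap,
    species_of: dict[str, str],
    support_threshold: float = 50.0,
    min_protein_aa: int = 150,
    n_bootstrap: int = 100,
    seed: int = 0,
    trim_threshold: float = 0.6,
    external_trees: dict[str, GeneTree] | None = None,
    compartment: str = "nuclear",
) -> list[FamilyAnalysis]:
    """Screen every focal gene of every orthogroup for transfer placement.

    External (e.g. maximum-likelihood) trees bypass the internal engine per
    orthogroup; they must carry support values and the same leaf names.
    """
    analyses = []
    focal = roles.focal
    for idx, og in enumerate(sorted(orthogroups)):
        by_sp = orthogroups[og]
        focal_genes = sorted(by_sp.get(focal, []))
        if not focal_genes:
            continue
        analysis = FamilyAnalysis(og)
        analyses.append(analysis)
        genes = sorted(g for gl in by_sp.values() for g in gl)
        outgroup_leaves = [g for g in genes if roles.role_of(species_of[g]) is Role.OUTGROUP]
        tree = (external_trees or {}).get(og)
        if tree is None:
            informative = [
                g for g in genes
                if roles.role_of(species_of[g]) in (Role.DONOR, Role.RELATIVE)
            ]
            if len(genes) < 4 or not informative:
                analysis.calls = [_unresolved(g, og, "too few informative homologs")
                                  for g in focal_genes]
                continue
            if not outgroup_leaves:
                analysis.calls = [_unresolved(g, og, "no outgroup leaf; cannot root")
                                  for g in focal_genes]
                continue
            aln = align_proteins({g: records[g].protein_seq for g in genes})
            trim = trim_columns(aln, trim_threshold)
            boot_seed = (seed * 1_000_003 + idx) % 2**31
            tree = bootstrap_support(trim.alignment, n_reps=n_bootstrap, seed=boot_seed)
            analysis.alignment = aln
            analysis.trim = trim
        if not set(outgroup_leaves) & set(tree.leaf_names):
            analysis.calls = [_unresolved(g, og, "no outgroup leaf; cannot root")
                              for g in focal_genes]
            continue
        rooted = tree.root_at_outgroup(set(outgroup_leaves), focal=focal_genes[0])
        analysis.tree = rooted
        for gene in focal_genes:
            try:
                call = classify_gene(
                    rooted, gene, species_of, roles,
                    support_threshold=support_threshold,
                    protein_len_aa=records[gene].protein_len_aa,
                    min_protein_aa=min_protein_aa,
                    orthogroup_id=og,
                    compartment=compartment,
                )
            except ValueError as exc:
                call = _unresolved(gene, og, str(exc))
            analysis.calls.append(call)
    return analyses


def recovery_metrics(
    true_labels: dict[str, str], calls: list[HgtCall]
) -> dict[str, float | int]:
    """Sensitivity and false-discovery proportion of transfer calls vs truth."""
    called_hgt = {c.gene_id for c in calls if c.status is HgtStatus.HGT}
    truth_hgt = {g for g, lab in true_labels.items() if lab == "hgt"}
    screened = {c.gene_id for c in calls}
    truth_hgt_screened = truth_hgt & screened
    tp = len(called_hgt & truth_hgt)
    fp = len(called_hgt - truth_hgt)
    return {
        "n_true_transfers": len(truth_hgt_screened),
        "n_called": len(called_hgt),
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": tp / len(truth_hgt_screened) if truth_hgt_screened else float("nan"),
        "false_discovery_proportion": fp / len(called_hgt) if called_hgt else 0.0,
    }


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    support_threshold: float = 50.0,
    n_bootstrap: int = 100,
    fpkm_threshold: float = 1.0,
    intron_min_len: int = 100,
    write_outputs: bool = True,
) -> dict:
    """Simulate, screen, analyze introns and selection, and write the report."""
    dataset = simulate(config)
    return analyze_dataset(
        dataset, out_dir,
        support_threshold=support_threshold,
        n_bootstrap=n_bootstrap,
        fpkm_threshold=fpkm_threshold,
        intron_min_len=intron_min_len,
        write_outputs=write_outputs,
    )


def analyze_dataset(
    dataset: SyntheticDataset,
    out_dir,
    support_threshold: float = 50.0,
    n_bootstrap: int = 100,
    fpkm_threshold: float = 1.0,
    intron_min_len: int = 100,
    write_outputs: bool = True,
) -> dict:
    from .orthogroups import summarize_categories

    roles = dataset.roles
    if write_outputs:
        dataset.write(f"{out_dir}/data")

    # orthogroup copy-number categories
    vectors = dataset.orthogroups.copy_numbers(roles.species)
    labels, cat_summary = summarize_categories(vectors, roles.focal)

    # transfer screen
    analyses = run_hgt_screen(
        dataset.records, dataset.orthogroups, roles, dataset.species_of,
        support_threshold=support_threshold,
        n_bootstrap=n_bootstrap,
        seed=dataset.config.seed,
    )
    calls = [c for a in analyses for c in a.calls]
    flag_functional(calls, dataset.expression, fpkm_threshold)

    # introns
    introns_by_gene: dict[str, list[IntronRecord]] = {
        gid: extract_introns(rec, dataset.genome[rec.contig])
        for gid, rec in dataset.records.items()
    }
    long_flags = flag_long_intron_genes(introns_by_gene)
    introns_per_gene = {
        gid: sum(1 for i in recs if i.length >= intron_min_len)
        for gid, recs in introns_by_gene.items()
    }
    origin_counts = {"donor": 0, "relative": 0, "uncertain": 0}
    for a in analyses:
        if a.alignment is None:
            continue
        fam_introns = {g: introns_by_gene.get(g, []) for g in a.alignment.ids}
        project_intron_positions(a.alignment, fam_introns, None)
        hgt_genes = {c.gene_id for c in a.calls if c.status is HgtStatus.HGT}
        subjects = {
            "donor": [
                i for g in a.alignment.ids
                if roles.role_of(dataset.species_of[g]) is Role.DONOR
                for i in fam_introns[g]
            ],
            "relative": [
                i for g in a.alignment.ids
                if roles.role_of(dataset.species_of[g]) is Role.RELATIVE
                for i in fam_introns[g]
            ],
        }
        for gene in hgt_genes:
            for intron in fam_introns.get(gene, []):
                matches = score_intron_matches(intron, subjects, min_len_bp=intron_min_len)
                if not matches:
                    continue
                origin = assign_intron_origin(matches).origin
                origin_counts[origin] = origin_counts.get(origin, 0) + 1

    hgt_calls = [c for c in calls if c.status is HgtStatus.HGT]
    association = None
    if hgt_calls:
        has_intron = {c.gene_id: introns_per_gene.get(c.gene_id, 0) > 0 for c in hgt_calls}
        expressed = {c.gene_id: c.expressed for c in hgt_calls}
        try:
            association = intron_expression_association(has_intron, expressed)
        except ValueError as exc:
            log.info("intron/expression association skipped: %s", exc)

    # selection on families with at least one transfer call
    selection_calls: list[LineageSelectionCall] = []
    for a in analyses:
        fg = [c.gene_id for c in a.calls if c.status is HgtStatus.HGT]
        if not fg or a.alignment is None:
            continue
        codon_aln = back_translate(
            a.alignment, {g: dataset.records[g].cds_seq for g in a.alignment.ids}
        )
        rows = dict(zip(codon_aln.ids, codon_aln.rows))
        donors = [g for g in codon_aln.ids
                  if roles.role_of(dataset.species_of[g]) is Role.DONOR]
        background = [
            g for g in codon_aln.ids
            if g not in fg
            and roles.role_of(dataset.species_of[g]) in (Role.RELATIVE, Role.FOCAL)
        ]
        if not donors or len(background) < 2:
            continue
        selection_calls.append(
            lineage_omega(rows, a.orthogroup_id, fg, donors, background)
        )

    regime_counts: dict[str, int] = {}
    for sc in selection_calls:
        regime_counts[sc.regime_fg.value] = regime_counts.get(sc.regime_fg.value, 0) + 1

    bundle = ReportBundle(
        calls=calls,
        introns_per_gene=introns_per_gene,
        category_counts=cat_summary.counts,
        selection_regimes=regime_counts,
        known_gene_ids=set(dataset.records),
        extra={
            "n_long_intron_genes": sum(long_flags.values()),
            "hgt_intron_origin_counts": origin_counts,
            "intron_expression_association": association,
            "fraction_lost": cat_summary.fraction_lost_conserved_denominator,
        },
    )
    summary = (
        write_report(bundle, f"{out_dir}/report")
        if write_outputs
        else summarize_bundle(bundle)
    )
    return {
        "dataset": dataset,
        "analyses": analyses,
        "calls": calls,
        "category_labels": labels,
        "category_summary": cat_summary,
        "selection": selection_calls,
        "summary": summary,
        "recovery": recovery_metrics(dataset.true_labels, calls),
    }
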