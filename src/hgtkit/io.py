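"""Readers and writers for the pipeline's standard formats.

Coordinates follow the GFF3 convention (1-based, closed intervals)
everywhere; conversions to other conventions happen only at format
boundaries.  Gene structures come from GFF3 (gene/mRNA/CDS features) plus a
genome FASTA; expression is a TSV of replicate-averaged FPKM with tissues
as columns; orthogroups use the wide OrthoFinder-style TSV (one column per
species, comma-separated gene ids).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    ExonInterval,
    ExpressionMatrix,
    GeneRecord,
    HgtCall,
    HgtStatus,
    OrthogroupTable,
    RoleMap,
)

log = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")


def read_roles(path) -> RoleMap:
    df = pd.read_csv(path, sep="\t")
    if not {"species_id", "role"} <= set(df.columns):
        raise ValueError("roles table needs columns species_id, role")
    return RoleMap.from_dict(dict(zip(df["species_id"], df["role"])))


def write_roles(roles: RoleMap, path) -> None:
    pd.DataFrame(
        {"species_id": list(roles.to_dict()), "role": list(roles.to_dict().values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(
    gff3_path,
    genome_fasta_path,
    cds_fasta_path=None,
    species_from_attribute: str = "species",
    default_species: str = "unknown",
) -> dict[str, GeneRecord]:
    """Build one GeneRecord per mRNA from GFF3 + genome FASTA.

    The CDS-defining exon intervals come from the CDS features of each mRNA;
    minus-strand CDS are reconstructed by reverse-complementing the
    concatenated exon sequence.  When a gene carries several transcripts the
    longest CDS is kept ("primary transcript" convention) and the rest are
    dropped with a log line.  A CDS whose length is not a multiple of 3 is
    flagged partial.  If a CDS FASTA is given, reconstructed sequences are
    checked against it.
    """
    genome = read_fasta(genome_fasta_path)
    cds_ref = read_fasta(cds_fasta_path) if cds_fasta_path else None
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, list[GeneRecord]] = {}
    for mrna in db.features_of_type("mRNA"):
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue
        contig = mrna.seqid
        if contig not in genome:
            raise ValueError(f"mRNA {mrna.id}: contig {contig} absent from genome FASTA")
        contig_seq = genome[contig]
        exons = []
        for feat in cds_feats:
            if feat.end > len(contig_seq) or feat.start < 1:
                raise ValueError(
                    f"feature {feat.id or mrna.id}: interval ({feat.start}, {feat.end}) "
                    f"outside contig {contig} of length {len(contig_seq)}"
                )
            exons.append(ExonInterval(feat.start, feat.end))
        concat = "".join(contig_seq[e.start - 1 : e.end] for e in sorted(exons))
        cds_seq = str(Seq(concat).reverse_complement()) if mrna.strand == "-" else concat
        species = mrna.attributes.get(species_from_attribute, [default_species])[0]
        rec = GeneRecord(
            gene_id=mrna.id,
            species_id=species,
            contig=contig,
            strand=mrna.strand,
            exons=exons,
            cds_seq=cds_seq,
        )
        if rec.partial:
            log.warning("%s: partial CDS, excluded from codon analyses", rec.gene_id)
        if cds_ref is not None and rec.gene_id in cds_ref and cds_ref[rec.gene_id] != cds_seq:
            raise ValueError(f"{rec.gene_id}: reconstructed CDS disagrees with CDS FASTA")
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_key = parents[0].id if parents else mrna.id
        by_gene.setdefault(gene_key, []).append(rec)
    records: dict[str, GeneRecord] = {}
    for gene_key, recs in by_gene.items():
        recs.sort(key=lambda r: (-r.cds_length, r.gene_id))
        keep = recs[0]
        for other in recs[1:]:
            log.info("%s: dropping non-primary transcript %s", gene_key, other.gene_id)
        records[keep.gene_id] = keep
    return records


def write_gene_models(
    records: Iterable[GeneRecord],
    genome: Mapping[str, str],
    gff3_path,
    genome_fasta_path,
    cds_fasta_path=None,
) -> None:
    """Emit GFF3 (gene/mRNA/CDS features) plus genome and optional CDS FASTA."""
    records = list(records)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            start, end = rec.exon_span
            attrs = f"ID=gene:{rec.gene_id};species={rec.species_id}"
            fh.write(
                f"{rec.contig}\thgtkit\tgene\t{start}\t{end}\t.\t{rec.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{rec.contig}\thgtkit\tmRNA\t{start}\t{end}\t.\t{rec.strand}\t.\t"
                f"ID={rec.gene_id};Parent=gene:{rec.gene_id};species={rec.species_id}\n"
            )
            exons = rec.exons if rec.strand == "+" else list(reversed(rec.exons))
            phases = {}
            cum = 0
            for e in exons:
                phases[e] = (3 - cum % 3) % 3
                cum += len(e)
            for k, e in enumerate(sorted(rec.exons), 1):
                fh.write(
                    f"{rec.contig}\thgtkit\tCDS\t{e.start}\t{e.end}\t.\t{rec.strand}\t"
                    f"{phases[e]}\tID=cds:{rec.gene_id}.{k};Parent={rec.gene_id}\n"
                )
    write_fasta(genome, genome_fasta_path)
    if cds_fasta_path:
        write_fasta({r.gene_id: r.cds_seq for r in records}, cds_fasta_path)


# ---------------------------------------------------------------------------
# Tables


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x tissue FPKM TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and len(df.columns) == 0:
        log.warning("expression table %s has no body", path)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[(coerced.isna() & df[col].notna()).argmax()]
            raise ValueError(f"non-numeric FPKM at gene {row!r}, tissue {col!r}") from None
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_orthogroups(path) -> OrthogroupTable:
    """Wide orthogroup TSV: first column orthogroup id, one column per species."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    groups: dict[str, dict[str, list[str]]] = {}
    for og, row in df.iterrows():
        groups[og] = {
            sp: [] if pd.isna(val) or not str(val).strip() else str(val).split(", ")
            for sp, val in row.items()
        }
    return OrthogroupTable(groups)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    species = sorted(table.species())
    rows = {
        og: {sp: ", ".join(table[og].get(sp, [])) for sp in species} for og in table
    }
    pd.DataFrame.from_dict(rows, orient="index", columns=species).to_csv(
        path, sep="\t", index_label="orthogroup_id"
    )


# ---------------------------------------------------------------------------
# Report


@dataclass
class ReportBundle:
    """Everything a finished (or explicitly skipped) run can report."""

    calls: list[HgtCall] = field(default_factory=list)
    introns_per_gene: Mapping[str, int] = field(default_factory=dict)
    category_counts: Mapping[str, int] = field(default_factory=dict)
    selection_regimes: Mapping[str, str] = field(default_factory=dict)
    known_gene_ids: set[str] | None = None
    extra: Mapping[str, object] = field(default_factory=dict)


def summarize_bundle(bundle: ReportBundle) -> dict:
    """Internally consistent JSON-ready counts for a results bundle."""
    if bundle.known_gene_ids is not None:
        orphans = sorted(
            {c.gene_id for c in bundle.calls} - set(bundle.known_gene_ids)
        ) + sorted(set(bundle.introns_per_gene) - set(bundle.known_gene_ids))
        if orphans:
            raise ValueError(f"ids not present in gene records: {orphans}")
    hgt = [c for c in bundle.calls if c.status is HgtStatus.HGT]
    with_introns = sum(1 for c in hgt if bundle.introns_per_gene.get(c.gene_id, 0) > 0)
    summary = {
        "n_genes_screened": len(bundle.calls),
        "total_hgt": len(hgt),
        "hgt_with_introns": with_introns,
        "hgt_without_introns": len(hgt) - with_introns,
        "n_expressed_hgt": sum(1 for c in hgt if c.expressed),
        "n_functional_hgt": sum(1 for c in hgt if c.functional),
        "n_vertical": sum(1 for c in bundle.calls if c.status is HgtStatus.VERTICAL),
        "n_unresolved": sum(1 for c in bundle.calls if c.status is HgtStatus.UNRESOLVED),
        "n_excluded_short": sum(
            1 for c in bundle.calls if c.status is HgtStatus.EXCLUDED_SHORT
        ),
        "orthogroup_categories": dict(bundle.category_counts),
        "selection_regimes": dict(bundle.selection_regimes),
    }
    summary.update(bundle.extra)
    return summary


def write_report(bundle: ReportBundle, out_dir) -> dict:
    """Write hgt_calls.tsv + summary.json; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize_bundle(bundle)
    if bundle.calls:
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "orthogroup_id": c.orthogroup_id,
                    "status": c.status.value,
                    "clade_support": c.clade_support,
                    "donor_clade_members": ",".join(c.donor_clade_members),
                    "expressed": c.expressed,
                    "functional": c.functional,
                    "compartment": c.compartment,
                    "n_introns": bundle.introns_per_gene.get(c.gene_id, 0),
                }
                for c in bundle.calls
            ]
        ).to_csv(out / "hgt_calls.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
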