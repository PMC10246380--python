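"""Synthetic gene families with ground-truth duplication/loss/transfer events.

The generator evolves gene families over a fixed rooted species tree whose
tips carry the screen's roles (one focal parasite, a donor clade standing
for the host's family, a relative clade, an outgroup).  Within a family:

* gene content changes by a per-lineage duplication/loss process along each
  branch (Gillespie within the branch), plus host-to-parasite transfers —
  either at a Poisson rate on allowed donor->focal edges or planted as an
  exact number of events for deterministic recovery experiments;
* codon sequences evolve by an HKY-biased proposal process filtered by an
  omega-weighted acceptance step (synonymous proposals always accepted,
  nonsynonymous with probability omega; proposals creating stops rejected),
  so the nonsynonymous/synonymous substitution ratio recoverable by a
  counting estimator tracks the planted omega;
* intron architectures are decided once per family at the root (count ~
  Poisson, length = minimum + geometric, phase-0 junctions) and the intron
  sequences then evolve neutrally along the species tree, so a transferred
  gene carries donor-derived intron sequence;
* focal-gene expression is log-normal FPKM with a silent fraction.

Every event is recorded in an EventLog; per-species gene counts are exactly
1 + duplications + transfers - losses along the root-to-tip path, which the
tests replay.  Identical config + seed reproduces identical datasets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .model import ExonInterval, ExpressionMatrix, GeneRecord, OrthogroupTable, RoleMap
from . import io as hio

_TABLE = dict(standard_dna_table.forward_table)
_STOPS = frozenset(standard_dna_table.stop_codons)
_NTS = "ACGT"
_SENSE = sorted(_TABLE)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_SPECIES_TREE = (
    "(((Shim:0.25,(Mesc:0.10,Ptri:0.10)malpighiales:0.12)shim_clade:0.08,"
    "(Vvin:0.06,Tpla:0.06)vitaceae:0.21)ingroup:0.10,Osat:0.35)root;"
)

DEFAULT_ROLES = {
    "Shim": "focal",
    "Vvin": "donor_clade",
    "Tpla": "donor_clade",
    "Mesc": "relative_clade",
    "Ptri": "relative_clade",
    "Osat": "outgroup",
}


@dataclass
class CodonModel:
    kappa: float = 2.0
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {"vertical": 0.2, "hgt": 0.2}
    )


@dataclass
class IntronModel:
    mean_count: float = 3.0
    min_length: int = 60
    mean_extra_length: float = 140.0
    fraction_canonical: float = 1.0
    rate_scale: float = 1.0
    """Intron substitutions/site per unit species-tree branch length."""
    loss_prob_focal_vertical: float = 0.0
    """Per-intron loss probability in the focal species' vertical genes."""
    focal_vertical_length_factor: float = 3.0
    """Intron elongation in the focal species' vertically inherited genes
    (repeat expansion in the bloated parasite genome); transferred genes
    keep their compact donor-derived introns."""


@dataclass
class ExpressionModel:
    log_mean: float = 1.0
    log_sigma: float = 1.0
    silent_fraction: float = 0.3
    tissues: tuple[str, ...] = ("bract", "sepal", "petal", "disk")


@dataclass
class SimulationConfig:
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    n_families: int = 200
    n_codons: int = 350
    rate_dup: float = 0.1
    rate_loss: float = 0.1
    rate_transfer: float = 0.0
    n_transfer_families: int | None = None
    """Fixed-number planting: exactly this many families get one transfer each."""
    transfer_mode: str = "coexist"  # or "replace"
    post_transfer_branch: float = 0.4
    """Extra branch length the transferred copy evolves inside the parasite
    after the transfer point (endoparasite lineages are rate-accelerated;
    comparable to the focal terminal branch)."""
    codon_model: CodonModel = field(default_factory=CodonModel)
    intron_model: IntronModel = field(default_factory=IntronModel)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)

    def __post_init__(self):
        if min(self.rate_dup, self.rate_loss, self.rate_transfer) < 0:
            raise ValueError("event rates must be non-negative")
        if self.transfer_mode not in ("coexist", "replace"):
            raise ValueError("transfer_mode must be coexist|replace")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("codon_model", CodonModel),
            ("intron_model", IntronModel),
            ("expression_model", ExpressionModel),
        ):
            if key in raw:
                raw[key] = sub(**raw[key])
        return cls(**raw)


@dataclass
class Event:
    family_id: str
    event: str  # duplication | loss | transfer
    branch: str
    """Label of the species-tree branch (its child node) carrying the event;
    transfers are recorded on the recipient (focal) branch."""
    gene_lineage_id: str
    donor_branch: str | None = None


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    roles: RoleMap
    records: dict[str, GeneRecord]
    genome: dict[str, str]
    orthogroups: OrthogroupTable
    expression: ExpressionMatrix
    true_labels: dict[str, str]
    events: list[Event]
    species_of: dict[str, str]

    def family_genes(self, orthogroup_id: str) -> dict[str, list[str]]:
        return self.orthogroups[orthogroup_id]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "families").mkdir(parents=True, exist_ok=True)
        hio.write_gene_models(
            self.records.values(), self.genome, out / "genes.gff3", out / "genome.fa",
            out / "cds.fa",
        )
        hio.write_orthogroups(self.orthogroups, out / "orthogroups.tsv")
        hio.write_expression(self.expression, out / "expression.tsv")
        hio.write_roles(self.roles, out / "roles.tsv")
        for og in self.orthogroups:
            genes = [g for gl in self.orthogroups[og].values() for g in gl]
            hio.write_fasta(
                {g: self.records[g].cds_seq for g in genes}, out / "families" / f"{og}.cds.fa"
            )
            hio.write_fasta(
                {g: self.records[g].protein_seq for g in genes},
                out / "families" / f"{og}.protein.fa",
            )
        pd.DataFrame(
            [
                {
                    "family_id": e.family_id,
                    "event": e.event,
                    "branch": e.branch,
                    "gene_lineage_id": e.gene_lineage_id,
                    "donor_branch": e.donor_branch or "",
                }
                for e in self.events
            ],
            columns=["family_id", "event", "branch", "gene_lineage_id", "donor_branch"],
        ).to_csv(out / "truth_events.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": list(self.true_labels), "label": list(self.true_labels.values())}
        ).to_csv(out / "truth_labels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence evolution


def random_sense_codons(n_codons: int, rng: np.random.Generator) -> str:
    codons = [_SENSE[i] for i in rng.integers(0, len(_SENSE), n_codons)]
    codons[0] = "ATG"
    return "".join(codons)


def _propose_nt(nt: str, kappa: float, rng: np.random.Generator) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[nt]
    return _TRANSVERSIONS[nt][rng.integers(0, 2)]


def evolve_codon_sequence(
    codon_seq: str,
    branch_length: float,
    kappa: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a stop-free codon sequence along a branch.

    Point mutations are proposed at a rate of ``branch_length`` per
    nucleotide site with an HKY transition bias ``kappa``; proposals to stop
    codons are rejected, synonymous proposals always accepted, and
    nonsynonymous proposals accepted with probability omega (for omega > 1
    the synonymous acceptance is scaled by 1/omega instead).
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if branch_length == 0:
        return codon_seq
    seq = list(codon_seq)
    n_prop = rng.poisson(len(seq) * branch_length)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    for _ in range(n_prop):
        pos = int(rng.integers(0, len(seq)))
        new_nt = _propose_nt(seq[pos], kappa, rng)
        c0 = pos - pos % 3
        old_codon = "".join(seq[c0 : c0 + 3])
        new_codon = old_codon[: pos - c0] + new_nt + old_codon[pos - c0 + 1 :]
        if new_codon in _STOPS:
            continue
        accept = p_syn if _TABLE[new_codon] == _TABLE[old_codon] else p_non
        if accept >= 1.0 or rng.random() < accept:
            seq[pos] = new_nt
    return "".join(seq)


def _elongate(intron: str, factor: float, rng: np.random.Generator) -> str:
    """Insert random sequence mid-intron to scale its length by ``factor``."""
    extra = int(round(len(intron) * (factor - 1.0)))
    if extra <= 0:
        return intron
    insert = "".join(_NTS[i] for i in rng.integers(0, 4, extra))
    mid = len(intron) // 2
    return intron[:mid] + insert + intron[mid:]


def _jc_p(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def mutate_neutral(seq: str, distance: float, rng: np.random.Generator,
                   preserve_termini: int = 2) -> str:
    """JC-style neutral mutation of a nucleotide sequence.

    The first/last ``preserve_termini`` positions (splice sites) are kept
    fixed, modeling their strong constraint.
    """
    if distance <= 0 or len(seq) <= 2 * preserve_termini:
        return seq
    p = _jc_p(distance)
    out = list(seq)
    for k in range(preserve_termini, len(seq) - preserve_termini):
        if rng.random() < p:
            choices = [nt for nt in _NTS if nt != out[k]]
            out[k] = choices[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Intron architecture


@dataclass
class IntronArchitecture:
    positions: list[int]
    """Codon junctions (intron follows this 1-based codon; phase 0)."""
    templates: list[str]


def sample_intron_architecture(
    n_codons: int, model: IntronModel, rng: np.random.Generator
) -> IntronArchitecture:
    n = int(rng.poisson(model.mean_count))
    n = min(n, n_codons - 1)
    positions = sorted(rng.choice(np.arange(1, n_codons), size=n, replace=False).tolist())
    templates = []
    for _ in positions:
        extra = int(rng.geometric(1.0 / (model.mean_extra_length + 1.0))) - 1
        length = model.min_length + extra
        body = "".join(_NTS[i] for i in rng.integers(0, 4, length - 4))
        if rng.random() < model.fraction_canonical:
            templates.append("GT" + body + "AG")
        else:
            ends = "".join(_NTS[i] for i in rng.integers(0, 4, 4))
            templates.append(ends[:2] + body + ends[2:])
    return IntronArchitecture(positions, templates)


def build_gene_record(
    gene_id: str,
    species_id: str,
    cds: str,
    architecture: IntronArchitecture,
    intron_seqs: list[str],
    strand: str,
    rng: np.random.Generator,
    flank: int = 30,
) -> tuple[GeneRecord, str]:
    """Assemble a one-gene contig (flank + exons/introns + flank) and its record."""
    pieces = []
    exons = []
    cursor = flank
    prev = 0
    boundaries = architecture.positions + [len(cds) // 3]
    for junction, intron in itertools.zip_longest(boundaries[:-1], intron_seqs):
        exon_seq = cds[3 * prev : 3 * junction]
        pieces.append(exon_seq)
        exons.append(ExonInterval(cursor + 1, cursor + len(exon_seq)))
        cursor += len(exon_seq)
        pieces.append(intron)
        cursor += len(intron)
        prev = junction
    last = cds[3 * prev :]
    pieces.append(last)
    exons.append(ExonInterval(cursor + 1, cursor + len(last)))
    cursor += len(last)
    left = "".join(_NTS[i] for i in rng.integers(0, 4, flank))
    right = "".join(_NTS[i] for i in rng.integers(0, 4, flank))
    contig_plus = left + "".join(pieces) + right
    if strand == "-":
        contig = str(Seq(contig_plus).reverse_complement())
        n = len(contig_plus)
        exons = sorted(ExonInterval(n - e.end + 1, n - e.start + 1) for e in exons)
    else:
        contig = contig_plus
    record = GeneRecord(
        gene_id=gene_id,
        species_id=species_id,
        contig=f"ctg_{gene_id}",
        strand=strand,
        exons=exons,
        cds_seq=cds,
    )
    return record, contig


def plant_intron_architecture(
    gene_id: str,
    species_id: str,
    cds: str,
    model: IntronModel,
    rng: np.random.Generator,
    strand: str = "+",
) -> tuple[GeneRecord, str]:
    """Sample an intron architecture for a CDS and build the gene + contig."""
    arch = sample_intron_architecture(len(cds) // 3, model, rng)
    return build_gene_record(gene_id, species_id, cds, arch, list(arch.templates), strand, rng)


# ---------------------------------------------------------------------------
# Family simulation


@dataclass
class _Lineage:
    lid: int
    codons: str
    introns: list[str]
    hgt: bool
    primary: bool


class _FamilySim:
    def __init__(self, config: SimulationConfig, tree: dendropy.Tree, fam_idx: int,
                 planted: tuple[str, float] | None, rng: np.random.Generator):
        self.cfg = config
        self.tree = tree
        self.fam = f"OG{fam_idx:04d}"
        self.planted = planted
        self.rng = rng
        self.events: list[Event] = []
        self.leaves: dict[str, list[_Lineage]] = {}
        self.transfers_in: list[_Lineage] = []
        self._counter = 0

    def _next_lid(self) -> int:
        self._counter += 1
        return self._counter

    def run(self) -> None:
        root_codons = random_sense_codons(self.cfg.n_codons, self.rng)
        arch = sample_intron_architecture(self.cfg.n_codons, self.cfg.intron_model, self.rng)
        self.arch = arch
        root = _Lineage(self._next_lid(), root_codons, list(arch.templates), False, True)
        self._descend(self.tree.seed_node, [root])
        focal = self.cfg_focal
        extra = []
        for lin in self.transfers_in:
            extra.append(lin)
            if self.cfg.transfer_mode == "replace":
                verticals = [l for l in self.leaves.get(focal, []) if not l.hgt]
                if verticals:
                    removed = verticals[0]
                    self.leaves[focal].remove(removed)
                    self.events.append(
                        Event(self.fam, "loss", focal, f"g{removed.lid}")
                    )
        self.leaves.setdefault(focal, []).extend(extra)

    @property
    def cfg_focal(self) -> str:
        return next(s for s, r in self.cfg.roles.items() if r == "focal")

    def _branch_label(self, node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label or "internal"

    def _descend(self, node, lineages: list[_Lineage]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            label = self._branch_label(child)
            survivors = self._branch_dup_loss(lineages, t, label)
            evolved = [self._evolve_lineage(lin, t) for lin in survivors]
            if (
                self.planted is not None
                and child.is_leaf()
                and child.taxon.label == self.planted[0]
                and survivors
            ):
                self._plant_transfer(survivors, t)
            if self.cfg.rate_transfer > 0 and child.is_leaf():
                self._rate_transfers(child.taxon.label, survivors, t)
            if child.is_leaf():
                self.leaves[child.taxon.label] = evolved
            else:
                self._descend(child, evolved)

    def _branch_dup_loss(self, lineages: list[_Lineage], t: float, label: str) -> list[_Lineage]:
        cur = [replace(lin, introns=list(lin.introns)) for lin in lineages]
        rd, rl = self.cfg.rate_dup, self.cfg.rate_loss
        if rd + rl <= 0 or t <= 0:
            return cur
        protect_primary = self.planted is not None
        time = 0.0
        while cur:
            rate = len(cur) * (rd + rl)
            time += self.rng.exponential(1.0 / rate)
            if time >= t:
                break
            lin = cur[int(self.rng.integers(0, len(cur)))]
            if self.rng.random() < rd / (rd + rl):
                new = _Lineage(self._next_lid(), lin.codons, list(lin.introns), lin.hgt, False)
                cur.append(new)
                self.events.append(Event(self.fam, "duplication", label, f"g{new.lid}"))
            else:
                if protect_primary and lin.primary:
                    continue
                cur.remove(lin)
                self.events.append(Event(self.fam, "loss", label, f"g{lin.lid}"))
        return cur

    def _evolve_lineage(self, lin: _Lineage, t: float) -> _Lineage:
        cm, im = self.cfg.codon_model, self.cfg.intron_model
        omega = cm.omega_by_class["hgt" if lin.hgt else "vertical"]
        codons = evolve_codon_sequence(lin.codons, t, cm.kappa, omega, self.rng)
        introns = [mutate_neutral(s, t * im.rate_scale, self.rng) for s in lin.introns]
        return _Lineage(lin.lid, codons, introns, lin.hgt, lin.primary)

    def _make_transfer(self, source: _Lineage, t: float, u: float, donor_label: str) -> None:
        cm, im = self.cfg.codon_model, self.cfg.intron_model
        seq_u = evolve_codon_sequence(source.codons, u * t, cm.kappa,
                                      cm.omega_by_class["vertical"], self.rng)
        introns_u = [mutate_neutral(s, u * t * im.rate_scale, self.rng) for s in source.introns]
        rest = (1.0 - u) * t + self.cfg.post_transfer_branch
        final = evolve_codon_sequence(seq_u, rest, cm.kappa, cm.omega_by_class["hgt"], self.rng)
        introns_f = [mutate_neutral(s, rest * im.rate_scale, self.rng) for s in introns_u]
        new = _Lineage(self._next_lid(), final, introns_f, True, False)
        self.transfers_in.append(new)
        self.events.append(
            Event(self.fam, "transfer", self.cfg_focal, f"g{new.lid}", donor_branch=donor_label)
        )

    def _plant_transfer(self, survivors: list[_Lineage], t: float) -> None:
        source = next((l for l in survivors if l.primary), survivors[0])
        self._make_transfer(source, t, self.planted[1], self.planted[0])

    def _rate_transfers(self, species: str, survivors: list[_Lineage], t: float) -> None:
        if self.cfg.roles.get(species) != "donor_clade" or not survivors:
            return
        for lin in list(survivors):
            for _ in range(int(self.rng.poisson(self.cfg.rate_transfer * t))):
                self._make_transfer(lin, t, float(self.rng.random()), species)


def _parse_species_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    return tree


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with ground-truth event log."""
    tree = _parse_species_tree(config.species_tree)
    roles = RoleMap.from_dict(config.roles)
    tip_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(roles.species) - tip_names
    if missing:
        raise ValueError(f"role-mapped species absent from species tree: {sorted(missing)}")
    master = np.random.default_rng([config.seed, 999_983])
    planted_families: dict[int, tuple[str, float]] = {}
    if config.n_transfer_families:
        donors = roles.donor_species
        if not donors:
            raise ValueError("transfer requested but no donor-clade species in tree")
        k = config.n_transfer_families
        if k > config.n_families:
            raise ValueError("more transfer families than families")
        chosen = sorted(master.choice(config.n_families, size=k, replace=False).tolist())
        for fam in chosen:
            donor = donors[int(master.integers(0, len(donors)))]
            planted_families[fam] = (donor, float(master.uniform(0.1, 0.9)))

    records: dict[str, GeneRecord] = {}
    genome: dict[str, str] = {}
    groups: dict[str, dict[str, list[str]]] = {}
    labels: dict[str, str] = {}
    species_of: dict[str, str] = {}
    events: list[Event] = []
    focal = roles.focal
    expr_rows = {}
    em = config.expression_model

    for fam_idx in range(config.n_families):
        rng = np.random.default_rng([config.seed, fam_idx])
        sim = _FamilySim(config, tree, fam_idx, planted_families.get(fam_idx), rng)
        sim.run()
        events.extend(sim.events)
        og = sim.fam
        groups[og] = {}
        for sp in sorted(tip_names):
            lineages = sim.leaves.get(sp, [])
            gene_ids = []
            for lin in lineages:
                gid = f"{sp}_F{fam_idx:04d}_g{lin.lid}"
                intron_seqs = list(lin.introns)
                arch = sim.arch
                if sp == focal and not lin.hgt:
                    im = config.intron_model
                    keep_idx = [
                        k
                        for k in range(len(intron_seqs))
                        if im.loss_prob_focal_vertical <= 0
                        or rng.random() >= im.loss_prob_focal_vertical
                    ]
                    intron_seqs = [
                        _elongate(intron_seqs[k], im.focal_vertical_length_factor, rng)
                        for k in keep_idx
                    ]
                    arch = IntronArchitecture(
                        [sim.arch.positions[k] for k in keep_idx], list(intron_seqs)
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                rec, contig = build_gene_record(
                    gid, sp, lin.codons, arch, intron_seqs, strand, rng
                )
                records[gid] = rec
                genome[rec.contig] = contig
                species_of[gid] = sp
                gene_ids.append(gid)
                if sp == focal:
                    labels[gid] = "hgt" if lin.hgt else "vertical"
                    if rng.random() < em.silent_fraction:
                        expr_rows[gid] = [0.0] * len(em.tissues)
                    else:
                        expr_rows[gid] = rng.lognormal(
                            em.log_mean, em.log_sigma, len(em.tissues)
                        ).tolist()
            groups[og][sp] = gene_ids

    expression = ExpressionMatrix(
        pd.DataFrame.from_dict(expr_rows, orient="index", columns=list(em.tissues))
    )
    return SyntheticDataset(
        config=config,
        roles=roles,
        records=records,
        genome=genome,
        orthogroups=OrthogroupTable(groups),
        expression=expression,
        true_labels=labels,
        events=events,
        species_of=species_of,
    )


def replay_expected_counts(
    events: list[Event], tree_newick: str, family_id: str
) -> dict[str, int]:
    """Per-species gene count implied by the event log (1 + dups + transfers - losses
    along the root-to-tip branch path)."""
    tree = _parse_species_tree(tree_newick)
    counts = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(leaf.taxon.label if node.is_leaf() else (node.label or "internal"))
            node = node.parent_node
        on_path = set(path)
        n = 1
        for e in events:
            if e.family_id != family_id or e.branch not in on_path:
                continue
            if e.event in ("duplication", "transfer"):
                n += 1
            elif e.event == "loss":
                n -= 1
        counts[leaf.taxon.label] = n
    return counts
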