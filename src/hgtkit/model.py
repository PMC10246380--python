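"""Domain types shared by every analysis stage.

The pipeline reasons about four clades: a single *focal* parasite species,
the *donor* clade (the host's family, the expected source of horizontal
transfers), the *relative* clade (the parasite's true phylogenetic
relatives, the expected placement of vertically inherited genes), and one
or more *outgroup* species used only for rooting.  All genomic coordinates
are 1-based inclusive (GFF3 convention) everywhere in the package;
conversions to other conventions happen only inside readers/writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class Role(str, Enum):
    """Phylogenetic role of a species in the screen."""

    FOCAL = "focal"
    DONOR = "donor_clade"
    RELATIVE = "relative_clade"
    OUTGROUP = "outgroup"
    OTHER = "other"


@dataclass(frozen=True)
class SpeciesProfile:
    species_id: str
    role: Role


class RoleMap:
    """Species → role assignment driving every clade test.

    Invariants: exactly one focal species; at least one donor-clade,
    one relative-clade and (for rooted analyses) one outgroup species.
    """

    def __init__(self, profiles: Iterable[SpeciesProfile], require_outgroup: bool = True):
        self._role: dict[str, Role] = {}
        for p in profiles:
            if p.species_id in self._role:
                raise ValueError(f"duplicate species id in role map: {p.species_id}")
            self._role[p.species_id] = Role(p.role)
        focal = [s for s, r in self._role.items() if r is Role.FOCAL]
        if len(focal) != 1:
            raise ValueError(f"role map must contain exactly one focal species, got {focal}")
        for role, name in ((Role.DONOR, "donor_clade"), (Role.RELATIVE, "relative_clade")):
            if not any(r is role for r in self._role.values()):
                raise ValueError(f"role map needs at least one {name} species")
        if require_outgroup and not any(r is Role.OUTGROUP for r in self._role.values()):
            raise ValueError("role map needs at least one outgroup species for rooted analyses")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str], **kw) -> "RoleMap":
        return cls([SpeciesProfile(s, Role(r)) for s, r in mapping.items()], **kw)

    def role_of(self, species_id: str) -> Role:
        return self._role[species_id]

    @property
    def species(self) -> list[str]:
        return list(self._role)

    @property
    def focal(self) -> str:
        return next(s for s, r in self._role.items() if r is Role.FOCAL)

    def with_role(self, role: Role) -> list[str]:
        return [s for s, r in self._role.items() if r is role]

    @property
    def donor_species(self) -> list[str]:
        return self.with_role(Role.DONOR)

    @property
    def relative_species(self) -> list[str]:
        return self.with_role(Role.RELATIVE)

    @property
    def outgroup_species(self) -> list[str]:
        return self.with_role(Role.OUTGROUP)

    def swapped_donor_relative(self) -> "RoleMap":
        """Role map with donor and relative clades exchanged (used by symmetry checks)."""
        swap = {Role.DONOR: Role.RELATIVE, Role.RELATIVE: Role.DONOR}
        return RoleMap(
            [SpeciesProfile(s, swap.get(r, r)) for s, r in self._role.items()],
            require_outgroup=False,
        )

    def to_dict(self) -> dict[str, str]:
        return {s: r.value for s, r in self._role.items()}


@dataclass(frozen=True, order=True)
class ExonInterval:
    """1-based inclusive genomic interval of a CDS-defining exon."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid exon interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneRecord:
    """A protein-coding gene: coordinates, strand, CDS and protein length.

    ``exons`` are the CDS-defining exon intervals on the gene's contig,
    non-overlapping and sorted by start regardless of strand.  ``partial``
    marks a CDS whose length is not divisible by 3; partial records are
    excluded from codon-level analyses.
    """

    gene_id: str
    species_id: str
    contig: str
    strand: str
    exons: list[ExonInterval]
    cds_seq: str
    partial: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} and {b}")
        if len(self.cds_seq) % 3 != 0 and not self.partial:
            self.partial = True
            log.warning("%s: CDS length %d not divisible by 3; flagged partial",
                        self.gene_id, len(self.cds_seq))

    @property
    def exon_span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def gene_length(self) -> int:
        """Span of the CDS-defining exons including introns (UTRs excluded by convention)."""
        s, e = self.exon_span
        return e - s + 1

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def protein_len_aa(self) -> int:
        n = len(self.cds_seq) // 3
        if n and self.cds_seq[-3:].upper() in ("TAA", "TAG", "TGA"):
            n -= 1
        return n

    @property
    def protein_seq(self) -> str:
        from Bio.Seq import Seq

        aa = str(Seq(self.cds_seq[: 3 * (len(self.cds_seq) // 3)]).translate())
        return aa[:-1] if aa.endswith("*") else aa


class OrthogroupTable:
    """orthogroup_id → species_id → list of gene ids; gene ids unique table-wide."""

    def __init__(self, groups: Mapping[str, Mapping[str, list[str]]]):
        self.groups: dict[str, dict[str, list[str]]] = {
            og: {sp: list(genes) for sp, genes in by_sp.items()} for og, by_sp in groups.items()
        }
        seen: dict[str, str] = {}
        for og, by_sp in self.groups.items():
            for sp, genes in by_sp.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene id {g} appears in both {seen[g]} and {og}")
                    seen[g] = og
        self._og_of_gene = seen

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    def __getitem__(self, og: str) -> dict[str, list[str]]:
        return self.groups[og]

    def orthogroup_of(self, gene_id: str) -> str | None:
        return self._og_of_gene.get(gene_id)

    def species(self) -> set[str]:
        return {sp for by_sp in self.groups.values() for sp in by_sp}

    def copy_numbers(self, species: Iterable[str]) -> dict[str, dict[str, int]]:
        """Per-orthogroup copy-number vectors over the given species set."""
        species = list(species)
        return {
            og: {sp: len(self.groups[og].get(sp, [])) for sp in species} for og in self.groups
        }


class ExpressionMatrix:
    """Replicate-averaged FPKM per gene × tissue.

    Missing genes are treated as unexpressed (0 in all tissues) and the
    lookup is logged so silent drops are visible.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
        values = frame.to_numpy()
        if values.size and (~np.isfinite(values) | (values < 0)).any():
            raise ValueError("expression matrix contains negative or non-finite FPKM values")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    def fpkm(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.frame.index:
            log.debug("gene %s missing from expression matrix; treated as 0 FPKM", gene_id)
            return np.zeros(len(self.frame.columns))
        return self.frame.loc[gene_id].to_numpy()

    def max_fpkm(self, gene_id: str) -> float:
        values = self.fpkm(gene_id)
        return float(values.max()) if values.size else 0.0


class HgtStatus(str, Enum):
    HGT = "hgt"
    VERTICAL = "vertical"
    UNRESOLVED = "unresolved"
    EXCLUDED_SHORT = "excluded_short"


@dataclass
class HgtCall:
    """Per-gene verdict of the clade-placement screen."""

    gene_id: str
    orthogroup_id: str
    status: HgtStatus
    clade_support: float | None = None
    donor_clade_members: list[str] = field(default_factory=list)
    expressed: bool = False
    functional: bool = False
    compartment: str = "nuclear"
    note: str = ""

    def __post_init__(self):
        if self.functional and not (self.status is HgtStatus.HGT and self.expressed):
            raise ValueError("functional implies status == hgt and expressed")
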