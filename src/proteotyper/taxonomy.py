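"""NCBI-style taxonomy and assembly-metadata handling.

Parses taxdump ``nodes.dmp``/``names.dmp`` files into a lineage-resolving
:class:`Taxonomy`, reads assembly-summary tables into
:class:`AssemblyRecord` lists, and applies the reference-database selection
rules: one quality-checked representative proteome per species for the
species-level database, and all complete-genome strains of a genus (with
genus aliasing, e.g. Escherichia/Shigella) for the strain-level database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical rank order from most to least general.
RANK_ORDER = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

#: Genus taxids treated as a single genus when scoping the strain-level
#: database.  NCBI taxids: Escherichia (561) / Shigella (620), and
#: Rhizobium (379) / Agrobacterium (357).
DEFAULT_GENUS_ALIAS_GROUPS: tuple[frozenset[int], ...] = (
    frozenset({561, 620}),
    frozenset({379, 357}),
)

#: Second name tokens that mark an organism name as not a proper binomial.
_PLACEHOLDER_EPITHETS = {"sp.", "bacterium", "uncultured", "unidentified"}


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies (missing parents, cycles)."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""


class Taxonomy:
    """Lineage lookup over a set of :class:`TaxonNode`.

    The root node is the unique node whose parent is itself (NCBI
    convention for taxid 1).
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        self._validate()

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent_taxid not in self._nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} references missing parent "
                    f"{node.parent_taxid}"
                )
        # Walk each node to the root; a revisit within one walk is a cycle.
        for taxid in self._nodes:
            seen = set()
            cur = taxid
            while True:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
                seen.add(cur)
                parent = self._nodes[cur].parent_taxid
                if parent == cur:
                    break
                cur = parent

    @classmethod
    def from_taxdump(cls, nodes_path: str | Path, names_path: str | Path) -> "Taxonomy":
        """Read NCBI taxdump ``nodes.dmp`` and ``names.dmp``.

        Fields are delimited by ``\\t|\\t`` with a trailing ``\\t|``; only
        scientific names are attached to nodes.
        """
        names: dict[int, str] = {}
        for row in _iter_dmp(names_path):
            taxid, name_txt = int(row[0]), row[1]
            name_class = row[3] if len(row) > 3 else "scientific name"
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = name_txt
        nodes = []
        for row in _iter_dmp(nodes_path):
            taxid = int(row[0])
            nodes.append(
                TaxonNode(
                    taxid=taxid,
                    parent_taxid=int(row[1]),
                    rank=row[2],
                    name=names.get(taxid, ""),
                )
            )
        return cls(nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: int) -> TaxonNode:
        return self._nodes[taxid]

    def name(self, taxid: int) -> str:
        return self._nodes[taxid].name

    def lineage(self, taxid: int) -> list[int]:
        """Ordered taxid list from the root down to ``taxid`` (inclusive)."""
        if taxid not in self._nodes:
            raise KeyError(f"unknown taxid {taxid}")
        out = [taxid]
        cur = taxid
        while True:
            parent = self._nodes[cur].parent_taxid
            if parent == cur:
                break
            out.append(parent)
            cur = parent
        out.reverse()
        return out

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """Ancestor of ``taxid`` (or itself) carrying ``rank``, else None."""
        for anc in reversed(self.lineage(taxid)):
            if self._nodes[anc].rank == rank:
                return anc
        return None

    def taxids(self) -> list[int]:
        return sorted(self._nodes)


def _iter_dmp(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield [f.strip() for f in line.split("\t|\t")]


# ---------------------------------------------------------------------------
# Assembly metadata


@dataclass(frozen=True)
class AssemblyRecord:
    assembly_accession: str
    taxid: int
    species_taxid: int
    organism_name: str
    strain_label: str = ""
    ani_status: str = "OK"
    refseq_category: str = "na"
    assembly_level: str = "Complete Genome"
    is_type_strain: bool = False
    fasta_path: str = ""


#: Maps AssemblyRecord field -> column name in NCBI assembly_summary.txt.
NCBI_COLUMN_MAP: Mapping[str, str] = {
    "assembly_accession": "assembly_accession",
    "taxid": "taxid",
    "species_taxid": "species_taxid",
    "organism_name": "organism_name",
    "strain_label": "infraspecific_name",
    "ani_status": "ani_status",
    "refseq_category": "refseq_category",
    "assembly_level": "assembly_level",
    "is_type_strain": "relation_to_type_material",
    "fasta_path": "fasta_path",
}


def read_assembly_summary(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[AssemblyRecord]:
    """Read a tab-separated assembly metadata table.

    NCBI ``assembly_summary.txt`` prefixes the header with ``#``; the last
    ``#``-prefixed line is taken as the header.  ``column_map`` remaps
    AssemblyRecord field names to table columns (default: NCBI dialect);
    fields whose columns are absent fall back to their defaults.
    """
    column_map = dict(column_map or NCBI_COLUMN_MAP)
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("# ").split("\t")
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        return []
    idx = {name: i for i, name in enumerate(header)}
    records = []
    for row in rows:
        def get(fieldname: str, default: str = "") -> str:
            col = column_map.get(fieldname)
            if col is None or col not in idx or idx[col] >= len(row):
                return default
            return row[idx[col]]

        type_raw = get("is_type_strain").strip().lower()
        records.append(
            AssemblyRecord(
                assembly_accession=get("assembly_accession"),
                taxid=int(get("taxid", "0") or 0),
                species_taxid=int(get("species_taxid", "0") or 0),
                organism_name=get("organism_name"),
                strain_label=get("strain_label"),
                ani_status=get("ani_status", "OK") or "OK",
                refseq_category=get("refseq_category", "na") or "na",
                assembly_level=get("assembly_level", "Complete Genome"),
                is_type_strain=type_raw not in ("", "na", "false", "0", "none"),
                fasta_path=get("fasta_path"),
            )
        )
    return records


def species_name_known(organism_name: str) -> bool:
    """True when the organism name looks like a proper binomial.

    Requires at least two whitespace tokens with the second token not a
    placeholder epithet (``sp.``, ``bacterium``, ...).
    """
    tokens = organism_name.split()
    if len(tokens) < 2:
        return False
    return tokens[1].lower() not in _PLACEHOLDER_EPITHETS


_CATEGORY_PREF = {"reference genome": 0, "representative genome": 1}


def _preference_key(rec: AssemblyRecord) -> tuple:
    return (
        _CATEGORY_PREF.get(rec.refseq_category, 9),
        0 if rec.is_type_strain else 1,
        rec.assembly_accession,
    )


def select_species_representatives(
    records: Sequence[AssemblyRecord],
) -> list[AssemblyRecord]:
    """Pick at most one representative assembly per species.

    A record survives when its ANI quality check passed, its species name
    is a known binomial, and it is an NCBI reference or representative
    genome.  Among survivors of a species the preference order is
    reference genome > representative genome, then type strain, then the
    lexicographically smallest accession.  Species with no surviving
    record are omitted (and logged).
    """
    by_species: dict[int, list[AssemblyRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_taxid, []).append(rec)

    selected = []
    for species_taxid in sorted(by_species):
        survivors = [
            r
            for r in by_species[species_taxid]
            if r.ani_status == "OK"
            and species_name_known(r.organism_name)
            and r.refseq_category in _CATEGORY_PREF
        ]
        if not survivors:
            logger.info(
                "species %d omitted: no assembly passes the selection criteria",
                species_taxid,
            )
            continue
        n_reference = sum(
            1 for r in survivors if r.refseq_category == "reference genome"
        )
        if n_reference > 1:
            logger.warning(
                "species %d has %d reference genomes; tie broken "
                "deterministically (type strain, then accession)",
                species_taxid,
                n_reference,
            )
        selected.append(min(survivors, key=_preference_key))
    return selected


def select_strain_assemblies(
    records: Sequence[AssemblyRecord],
    genus_taxid: int,
    taxonomy: Taxonomy,
    aliases: Iterable[int] | None = None,
    alias_groups: Sequence[frozenset[int]] = DEFAULT_GENUS_ALIAS_GROUPS,
) -> list[AssemblyRecord]:
    """All complete-genome strains of a genus (plus aliased genera).

    When ``aliases`` is None, any alias group containing ``genus_taxid``
    is applied (default pairs: Escherichia/Shigella,
    Rhizobium/Agrobacterium).  No per-species deduplication: every strain
    is kept, since each strain is treated as a distinct organism.
    """
    if aliases is None:
        aliases = set()
        for group in alias_groups:
            if genus_taxid in group:
                aliases |= set(group)
    scope = set(aliases) | {genus_taxid}

    out = []
    for rec in sorted(records, key=lambda r: r.assembly_accession):
        if rec.ani_status != "OK":
            continue
        if rec.assembly_level != "Complete Genome":
            continue
        if rec.taxid not in taxonomy:
            continue
        genus = taxonomy.rank_ancestor(rec.taxid, "genus")
        if genus in scope:
            out.append(rec)
    if not out:
        raise ValueError(
            f"no Complete Genome strain assemblies found for genus "
            f"{genus_taxid} (aliases {sorted(scope)}); update the assembly "
            "metadata / reference database"
        )
    return out
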