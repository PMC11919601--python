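"""Peptide → taxon reference index: build, persist, chunk.

The index maps every de-duplicated tryptic peptide of the reference
proteomes to the set of taxa whose proteome contains it.  At species
level the mapping target is the species taxid (one representative
proteome per species); at strain level it is the strain taxid, since each
strain is a distinct organism.

The serialized format is a gzip-compressed text file: a JSON header line
(magic + version), a JSON manifest line (level, digest parameters, taxa,
counts, provenance), then one sorted line per peptide with a
comma-separated taxid postings list — diffable and streamable.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .digestion import (
    DigestParams,
    PeptideSet,
    ProteinRecord,
    build_peptide_set,
    read_fasta,
    write_fasta,
)
from .taxonomy import AssemblyRecord, Taxonomy

logger = logging.getLogger(__name__)

_MAGIC = "proteotyper-index"
_VERSION = 1


class IndexFormatError(ValueError):
    """Raised when a serialized index cannot be understood."""


@dataclass
class ReferenceIndex:
    level: str  # species | strain | custom
    peptide_to_taxa: dict[str, frozenset[int]]
    taxa: list[tuple[int, str, tuple[int, ...]]]  # (taxid, name, lineage)
    digest_params: DigestParams
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        known = {t for t, _, _ in self.taxa}
        for pep, taxids in self.peptide_to_taxa.items():
            if not taxids <= known:
                raise ValueError(
                    f"peptide {pep!r} maps to taxa outside the taxa table"
                )

    @property
    def taxids(self) -> list[int]:
        return [t for t, _, _ in self.taxa]

    def display_name(self, taxid: int) -> str:
        for t, name, _ in self.taxa:
            if t == taxid:
                return name
        return str(taxid)

    def peptides_of(self, taxid: int) -> frozenset[str]:
        return frozenset(
            p for p, ts in self.peptide_to_taxa.items() if taxid in ts
        )

    def __len__(self) -> int:
        return len(self.peptide_to_taxa)


def index_from_peptide_sets(
    peptide_sets: Sequence[PeptideSet],
    params: DigestParams,
    taxonomy: Taxonomy | None = None,
    level: str = "custom",
    names: Mapping[int, str] | None = None,
    manifest: dict | None = None,
) -> ReferenceIndex:
    """Assemble an index from pre-digested per-taxon peptide sets."""
    taxids = [ps.taxid for ps in peptide_sets]
    if len(set(taxids)) != len(taxids):
        raise ValueError("duplicate taxids across peptide sets")
    peptide_to_taxa: dict[str, set[int]] = {}
    for ps in peptide_sets:
        for pep in ps.peptides:
            peptide_to_taxa.setdefault(pep, set()).add(ps.taxid)
    taxa = []
    for ps in sorted(peptide_sets, key=lambda s: s.taxid):
        name = (names or {}).get(ps.taxid) or (
            taxonomy.name(ps.taxid) if taxonomy and ps.taxid in taxonomy else str(ps.taxid)
        )
        lineage = (
            tuple(taxonomy.lineage(ps.taxid))
            if taxonomy and ps.taxid in taxonomy
            else (ps.taxid,)
        )
        taxa.append((ps.taxid, name, lineage))
    man = dict(manifest or {})
    man.setdefault("n_taxa", len(taxa))
    man["n_peptides"] = len(peptide_to_taxa)
    return ReferenceIndex(
        level=level,
        peptide_to_taxa={p: frozenset(ts) for p, ts in peptide_to_taxa.items()},
        taxa=taxa,
        digest_params=params,
        manifest=man,
    )


def build_reference_index(
    assemblies: Sequence[AssemblyRecord],
    params: DigestParams,
    taxonomy: Taxonomy,
    level: str = "species",
) -> ReferenceIndex:
    """Digest assembly FASTA files and build the peptide → taxon index.

    At species level the mapping target is ``species_taxid`` and a
    duplicate species across assemblies is a hard error (one
    representative per species); at strain level the target is the
    assembly's own taxid.
    """
    skip_log: Counter = Counter()
    peptide_sets = []
    names: dict[int, str] = {}
    seen: set[int] = set()
    for rec in sorted(assemblies, key=lambda r: r.assembly_accession):
        target = rec.species_taxid if level == "species" else rec.taxid
        if target in seen:
            if level == "species":
                raise ValueError(
                    f"duplicate species taxid {target} across assemblies; "
                    "the species-level database takes one representative "
                    "per species"
                )
            logger.warning("duplicate strain taxid %d; keeping first", target)
            continue
        seen.add(target)
        proteome = read_fasta(rec.fasta_path, source_taxid=target)
        peptide_sets.append(
            build_peptide_set(proteome, params, taxid=target, skip_log=skip_log)
        )
        names[target] = rec.organism_name
    manifest = {
        "sources": [str(r.fasta_path) for r in
                    sorted(assemblies, key=lambda r: r.assembly_accession)],
        "skipped_fragments": dict(skip_log),
    }
    return index_from_peptide_sets(
        peptide_sets, params, taxonomy=taxonomy, level=level,
        names=names, manifest=manifest,
    )


def split_fasta_for_search(
    assemblies: Sequence[AssemblyRecord],
    n_chunks: int,
    out_dir: str | Path,
    prefix: str = "chunk",
) -> list[Path]:
    """Split reference proteins into ``n_chunks`` FASTA files.

    Records are ordered by assembly accession (then file order) and
    assigned round-robin, so every protein lands in exactly one chunk and
    the concatenation of chunks is a permutation of the input.  Chunked
    reference files let a search engine with memory limits cover a
    peptide space too large for a single search.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[ProteinRecord] = []
    for rec in sorted(assemblies, key=lambda r: r.assembly_accession):
        records.extend(read_fasta(rec.fasta_path, source_taxid=rec.taxid))
    if n_chunks > len(records):
        logger.warning(
            "n_chunks (%d) exceeds record count (%d); some chunks are empty",
            n_chunks, len(records),
        )
    chunks: list[list[ProteinRecord]] = [[] for _ in range(n_chunks)]
    for i, record in enumerate(records):
        chunks[i % n_chunks].append(record)
    paths = []
    for i, chunk in enumerate(chunks):
        path = out_dir / f"{prefix}_{i}.fasta"
        write_fasta(chunk, path)
        paths.append(path)
    return paths


def write_index(index: ReferenceIndex, path: str | Path) -> None:
    """Serialize the index (gzip text; header, manifest, postings lines)."""
    header = {"magic": _MAGIC, "version": _VERSION}
    meta = {
        "level": index.level,
        "digest_params": asdict(index.digest_params),
        "taxa": [[t, name, list(lineage)] for t, name, lineage in index.taxa],
        "manifest": index.manifest,
    }
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        fh.write(json.dumps(meta, sort_keys=True) + "\n")
        for pep in sorted(index.peptide_to_taxa):
            taxa = ",".join(str(t) for t in sorted(index.peptide_to_taxa[pep]))
            fh.write(f"{pep}\t{taxa}\n")


def read_index(path: str | Path) -> ReferenceIndex:
    """Read an index written by :func:`write_index`."""
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        try:
            header = json.loads(fh.readline())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise IndexFormatError(f"not a proteotyper index: {path}") from exc
        if not isinstance(header, dict) or header.get("magic") != _MAGIC:
            raise IndexFormatError(f"not a proteotyper index: {path}")
        if header.get("version") != _VERSION:
            raise IndexFormatError(
                f"index version {header.get('version')} unsupported "
                f"(expected {_VERSION})"
            )
        meta = json.loads(fh.readline())
        peptide_to_taxa = {}
        for line in fh:
            pep, _, taxa = line.rstrip("\n").partition("\t")
            peptide_to_taxa[pep] = frozenset(
                int(t) for t in taxa.split(",") if t
            )
    return ReferenceIndex(
        level=meta["level"],
        peptide_to_taxa=peptide_to_taxa,
        taxa=[(t, name, tuple(lineage)) for t, name, lineage in meta["taxa"]],
        digest_params=DigestParams(**meta["digest_params"]),
        manifest=meta["manifest"],
    )
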