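"""In-silico proteolytic digestion into I/L-collapsed tryptic peptide sets.

Implements fully tryptic digestion under two cleavage rules — trypsin/P
(cut after K/R regardless of the next residue) and classical trypsin (no
cut before proline) — with configurable missed cleavages and length
bounds.  Because MS cannot distinguish isoleucine from leucine (identical
mass), peptide sets are optionally I/L-collapsed, with 'L' as the
canonical representative so sequences stay valid.

Fragments containing non-canonical residues (X, B, Z, U, O, J, *) are
excluded: such peptides cannot be matched by a mass-based search and
would only inflate reference set sizes.  Exclusions are tallied in a skip
counter when one is supplied.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    description: str
    sequence: str
    source_taxid: int = 0


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings.

    Defaults (trypsin/P, up to two missed cleavages, length 7–50,
    I/L collapse on) follow common search-engine defaults for fully
    tryptic reference digests.
    """

    enzyme: str = "trypsin_p"
    max_missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 50
    collapse_il: bool = True

    def __post_init__(self):
        if self.enzyme not in ("trypsin_p", "trypsin"):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")


#: Evidence-mapping digest variant: up to two missed cleavages, length 7-30.
EVIDENCE_DIGEST_PARAMS = DigestParams(
    enzyme="trypsin_p", max_missed_cleavages=2, min_len=7, max_len=30,
    collapse_il=True,
)


@dataclass(frozen=True)
class PeptideSet:
    taxid: int
    peptides: frozenset[str]
    n_source_proteins: int = 0


def normalize_il(sequence: str) -> str:
    """Replace every isoleucine by leucine (mass-degenerate residues)."""
    return sequence.replace("I", "L")


def cleavage_positions(sequence: str, enzyme: str) -> list[int]:
    """Internal cut positions: index i means a cut between i-1 and i.

    Trypsin cuts C-terminal to K/R; classical trypsin suppresses the cut
    when the next residue is proline, trypsin/P does not.
    """
    cuts = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if enzyme == "trypsin" and sequence[i + 1] == "P":
                continue
            cuts.append(i + 1)
    return cuts


def digest_protein(
    sequence: str,
    params: DigestParams = DigestParams(),
    skip_log: Counter | None = None,
) -> list[str]:
    """Fully tryptic peptides of one protein, de-duplicated.

    Returns fragments bounded by cleavage sites or protein termini, with
    at most ``max_missed_cleavages`` internal sites, filtered to the
    configured length window, in order of first occurrence.  Fragments
    with non-canonical residues are dropped and tallied in ``skip_log``.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    boundaries = [0] + cleavage_positions(sequence, params.enzyme) + [len(sequence)]
    segments = [
        sequence[boundaries[i] : boundaries[i + 1]]
        for i in range(len(boundaries) - 1)
    ]
    seen: set[str] = set()
    out: list[str] = []
    for start in range(len(segments)):
        for stop in range(
            start + 1, min(start + 2 + params.max_missed_cleavages, len(segments) + 1)
        ):
            pep = "".join(segments[start:stop])
            if not (params.min_len <= len(pep) <= params.max_len):
                continue
            if not set(pep) <= CANONICAL_AA:
                if skip_log is not None:
                    skip_log["non_canonical_fragments"] += 1
                continue
            if params.collapse_il:
                pep = normalize_il(pep)
            if pep not in seen:
                seen.add(pep)
                out.append(pep)
    return out


def build_peptide_set(
    proteome: Sequence[ProteinRecord],
    params: DigestParams = DigestParams(),
    taxid: int | None = None,
    skip_log: Counter | None = None,
) -> PeptideSet:
    """Union of tryptic peptides over all proteins of one proteome."""
    if taxid is None:
        taxids = {p.source_taxid for p in proteome}
        if len(taxids) > 1:
            raise ValueError(f"proteome spans multiple taxids: {sorted(taxids)}")
        taxid = taxids.pop() if taxids else 0
    if not proteome:
        logger.warning("empty proteome for taxid %s", taxid)
        return PeptideSet(taxid=taxid, peptides=frozenset(), n_source_proteins=0)
    peptides: set[str] = set()
    for record in proteome:
        peptides.update(digest_protein(record.sequence, params, skip_log=skip_log))
    return PeptideSet(
        taxid=taxid, peptides=frozenset(peptides), n_source_proteins=len(proteome)
    )


def read_fasta(path: str | Path, source_taxid: int = 0) -> list[ProteinRecord]:
    """Read protein records from a (possibly gzipped) FASTA file.

    Tolerates NCBI headers ``>accession description [Organism name]`` and
    arbitrary line wrapping.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                ProteinRecord(
                    protein_id=rec.id,
                    description=rec.description,
                    sequence=str(rec.seq).upper(),
                    source_taxid=source_taxid,
                )
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (60-column wrap, stable order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.protein_id
            if not header.startswith(rec.protein_id):
                header = f"{rec.protein_id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
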