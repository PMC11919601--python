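"""Parsing and merging of 100%-FDR search-engine PSM output.

Consumes MSFragger-style TSV and pepXML tables without any FDR filtering
— every best-per-spectrum match is kept — and combines chunked searches
of a split reference database by retaining, per MS2 spectrum, the PSM
with the highest hyperscore across chunks.

Spectrum identifiers of the form ``<run>.<scan>.<scan>.<charge>`` are
normalized to ``<run>:<scan>``: charge is excluded from the key so one
spectrum yields one PSM even if searched at several charge states.
"""

from __future__ import annotations

import gzip
import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .digestion import normalize_il

logger = logging.getLogger(__name__)

REQUIRED_TSV_COLUMNS = ("spectrum", "peptide", "charge", "hyperscore")

_MOD_ANNOTATION = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Z]")


@dataclass(frozen=True)
class Psm:
    spectrum_key: str
    peptide: str
    charge: int
    hyperscore: float
    chunk_id: int = 0


@dataclass(frozen=True)
class PsmTable:
    psms: tuple[Psm, ...]
    run_id: str = ""

    @property
    def n_spectra(self) -> int:
        return len({p.spectrum_key for p in self.psms})

    def __len__(self) -> int:
        return len(self.psms)


def strip_modifications(peptide: str) -> str:
    """Reduce an annotated peptide to its bare upper-case sequence.

    Removes bracketed mass/modification annotations (``AAM[147]R``,
    ``AAM(ox)R``) and any non-letter characters.
    """
    return _MOD_ANNOTATION.sub("", peptide)


def normalize_spectrum_key(spectrum: str) -> str:
    """Normalize a spectrum identifier to ``<run>:<scan>``."""
    if ":" in spectrum:
        return spectrum
    parts = spectrum.split(".")
    if len(parts) >= 3 and parts[-2] == parts[-3]:
        run = ".".join(parts[:-3])
        return f"{run}:{parts[-2].lstrip('0') or '0'}"
    return spectrum


def _make_psm(spectrum, peptide, charge, hyperscore, chunk_id) -> Psm | None:
    bare = normalize_il(strip_modifications(str(peptide)))
    if not bare:
        return None
    return Psm(
        spectrum_key=normalize_spectrum_key(str(spectrum)),
        peptide=bare,
        charge=int(charge),
        hyperscore=float(hyperscore),
        chunk_id=int(chunk_id),
    )


def parse_psm_file(
    path: str | Path, dialect: str = "tsv", chunk_id: int = 0
) -> PsmTable:
    """Parse a search-engine PSM table (no score or FDR filtering).

    ``dialect`` is ``tsv`` (columns: spectrum, peptide, charge,
    hyperscore; case-insensitive) or ``pepxml``.  Peptides are
    I/L-collapsed and stripped of modification annotations on ingestion;
    rows with an empty peptide are dropped and counted.
    """
    path = Path(path)
    if dialect == "tsv":
        psms, n_dropped = _parse_tsv(path, chunk_id)
    elif dialect == "pepxml":
        psms, n_dropped = _parse_pepxml(path, chunk_id)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if n_dropped:
        logger.warning("%s: dropped %d rows with empty peptide", path, n_dropped)
    run_id = path.name.split(".")[0]
    return PsmTable(psms=tuple(psms), run_id=run_id)


def _parse_tsv(path: Path, chunk_id: int):
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lower = [h.strip().lower() for h in header]
        missing = [c for c in REQUIRED_TSV_COLUMNS if c not in lower]
        if missing:
            raise ValueError(
                f"{path}: missing required columns {missing}; "
                f"found {header}"
            )
        col = {c: lower.index(c) for c in REQUIRED_TSV_COLUMNS}
        psms, n_dropped = [], 0
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            psm = _make_psm(
                row[col["spectrum"]], row[col["peptide"]],
                row[col["charge"]], row[col["hyperscore"]], chunk_id,
            )
            if psm is None:
                n_dropped += 1
            else:
                psms.append(psm)
    return psms, n_dropped


def _parse_pepxml(path: Path, chunk_id: int):
    from pyteomics import pepxml

    psms, n_dropped = [], 0
    with pepxml.read(str(path)) as reader:
        for query in reader:
            hits = query.get("search_hit") or []
            if not hits:
                continue
            hit = min(hits, key=lambda h: h.get("hit_rank", 1))
            scores = hit.get("search_score", {})
            psm = _make_psm(
                query["spectrum"],
                hit["peptide"],
                query.get("assumed_charge", 0),
                scores.get("hyperscore", hit.get("hyperscore", float("nan"))),
                chunk_id,
            )
            if psm is None or math.isnan(psm.hyperscore):
                n_dropped += 1
            else:
                psms.append(psm)
    return psms, n_dropped


def write_psm_tsv(table: PsmTable, path: str | Path) -> None:
    """Write a PSM table in the plain TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("spectrum\tpeptide\tcharge\thyperscore\n")
        for p in table.psms:
            fh.write(f"{p.spectrum_key}\t{p.peptide}\t{p.charge}\t{p.hyperscore}\n")


def _better(a: Psm, b: Psm) -> Psm:
    """Deterministic best-of-two: higher hyperscore, then lexicographically
    smaller peptide, then lower chunk id."""
    ka = (-a.hyperscore, a.peptide, a.chunk_id)
    kb = (-b.hyperscore, b.peptide, b.chunk_id)
    return a if ka <= kb else b


def combine_chunked_searches(tables: Sequence[PsmTable]) -> PsmTable:
    """Merge chunked 100%-FDR searches into one best-PSM-per-spectrum table.

    For every spectrum the PSM with the highest hyperscore across all
    chunks is kept (ties: lexicographically smallest peptide, then lowest
    chunk id).  Duplicate spectra within a single chunk are first reduced
    to their chunk-internal best, with a warning.
    """
    if not tables:
        raise ValueError("no PSM tables to combine")
    best: dict[str, Psm] = {}
    for table in tables:
        chunk_seen: set[str] = set()
        dup_warned = False
        for psm in table.psms:
            if psm.spectrum_key in chunk_seen and not dup_warned:
                logger.warning(
                    "duplicate spectrum key within one chunk (run %s); "
                    "keeping chunk-internal best", table.run_id,
                )
                dup_warned = True
            chunk_seen.add(psm.spectrum_key)
            cur = best.get(psm.spectrum_key)
            best[psm.spectrum_key] = psm if cur is None else _better(cur, psm)
    run_id = tables[0].run_id
    psms = tuple(best[k] for k in sorted(best))
    return PsmTable(psms=psms, run_id=run_id)
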