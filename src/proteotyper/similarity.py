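"""Comparative analytics over tryptic peptidomes.

Jaccard similarity matrices quantify how much of their theoretical
peptide space two organisms share; the directional overlap fraction
|A∩B| / |A| expresses how much of one strain's peptidome is contained in
another's (useful for misidentification post-mortems); unique-peptide
fractions measure taxon-discriminating capacity; and novelty flagging
marks observed peptides absent from a digest of proteins with prior
protein-level evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import (
    EVIDENCE_DIGEST_PARAMS,
    DigestParams,
    PeptideSet,
    ProteinRecord,
    build_peptide_set,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityMatrix:
    taxids: tuple[int, ...]
    values: np.ndarray  # values[i, j] in [0, 1]
    metric: str  # jaccard | overlap_fraction

    def value(self, taxid_a: int, taxid_b: int) -> float:
        i = self.taxids.index(taxid_a)
        j = self.taxids.index(taxid_b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxid\t" + "\t".join(str(t) for t in self.taxids) + "\n")
            for i, t in enumerate(self.taxids):
                row = "\t".join(f"{v:.6g}" for v in self.values[i])
                fh.write(f"{t}\t{row}\n")

    def to_long(self) -> list[tuple[int, int, float]]:
        """(taxid_a, taxid_b, value) triples for plotting."""
        out = []
        for i, a in enumerate(self.taxids):
            for j, b in enumerate(self.taxids):
                out.append((a, b, float(self.values[i, j])))
        return out


def _peps(s) -> frozenset[str]:
    return s.peptides if isinstance(s, PeptideSet) else frozenset(s)


def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B| of two peptide sets (error when both are empty)."""
    a, b = _peps(set_a), _peps(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined: both peptide sets are empty")
    return len(a & b) / len(union)


def overlap_fraction(set_a, set_b) -> float:
    """Fraction of A's peptides that also occur in B (directional)."""
    a, b = _peps(set_a), _peps(set_b)
    if not a:
        raise ValueError("overlap fraction undefined: first set is empty")
    return len(a & b) / len(a)


_METRICS = {"jaccard": jaccard, "overlap_fraction": overlap_fraction}


def pairwise_similarity(
    sets: Sequence[PeptideSet], metric: str = "jaccard"
) -> SimilarityMatrix:
    """Full pairwise similarity matrix, rows/columns ordered by taxid.

    ``jaccard`` yields a symmetric matrix with unit diagonal;
    ``overlap_fraction`` is directional (row taxon's peptides found in
    the column taxon) and generally asymmetric.
    """
    if len(sets) < 2:
        raise ValueError("need at least two peptide sets")
    taxids = [s.taxid for s in sets]
    if len(set(taxids)) != len(taxids):
        raise ValueError("duplicate taxids in peptide sets")
    fn = _METRICS[metric]
    ordered = sorted(sets, key=lambda s: s.taxid)
    n = len(ordered)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            values[i, j] = fn(ordered[i], ordered[j])
    return SimilarityMatrix(
        taxids=tuple(s.taxid for s in ordered), values=values, metric=metric
    )


def unique_fraction(
    sets: Sequence[PeptideSet],
) -> tuple[dict[int, float], float]:
    """Per-taxon and global fractions of single-taxon ("unique") peptides.

    Per taxon: the fraction of its peptides found in no other set.
    Global: the fraction of the peptide union that is private to exactly
    one taxon.
    """
    if len(sets) < 2:
        raise ValueError("need at least two peptide sets")
    counts: dict[str, int] = {}
    for s in sets:
        for pep in _peps(s):
            counts[pep] = counts.get(pep, 0) + 1
    per_taxon = {}
    for s in sets:
        peps = _peps(s)
        if not peps:
            per_taxon[s.taxid] = 0.0
            continue
        per_taxon[s.taxid] = sum(1 for p in peps if counts[p] == 1) / len(peps)
    n_union = len(counts)
    global_fraction = (
        sum(1 for c in counts.values() if c == 1) / n_union if n_union else 0.0
    )
    return per_taxon, global_fraction


def flag_novel_peptides(
    observed_peptides: Sequence[str],
    evidence_proteins: Sequence[ProteinRecord],
    params: DigestParams = EVIDENCE_DIGEST_PARAMS,
) -> dict[str, bool]:
    """Flag observed peptides absent from the evidence-protein digest.

    Evidence proteins (those with prior protein-level evidence) are
    digested with up to two missed cleavages at length 7–30 under the
    same I/L convention; a peptide maps to True ("novel") iff it does not
    occur in that digest.
    """
    if not evidence_proteins:
        logger.warning("empty evidence set: every observed peptide flagged novel")
        evidence = frozenset()
    else:
        evidence = build_peptide_set(
            evidence_proteins, params, taxid=0
        ).peptides
    return {pep: pep not in evidence for pep in observed_peptides}
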