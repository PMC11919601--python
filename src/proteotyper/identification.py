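"""Core proteotyping logic: PSM → taxon counting, ranking, QC, iterations.

Every PSM whose peptide occurs in the reference index increments the
count of *each* taxon containing that peptide by exactly one — a shared
peptide is counted once per taxon, never more, regardless of how many
paralogous proteins of the taxon contain it.  No FDR control is applied:
false-positive matches scatter near-uniformly across the reference taxa
(which act as mutual decoys) while true matches accumulate on the
correct organism, so the taxon with the most mapped PSMs is reported as
the identification.

The optional second iteration re-runs the counting against a strain-level
database scoped to the genus identified first, giving sub-species
resolution and the chance to correct a first-pass misidentification when
the species-level database's single representative strain is a poor
proxy for the sample.  A fallback database (e.g. fungal proteomes) can be
consulted when the primary identification fails the mapped-PSM QC rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .psm_io import PsmTable
from .reference import ReferenceIndex

logger = logging.getLogger(__name__)

#: Minimum mapped PSMs for a trustworthy identification (clinical QC rule).
DEFAULT_QC_THRESHOLD = 500


@dataclass(frozen=True)
class TaxonCount:
    taxid: int
    display_name: str
    psm_count: int
    distinct_peptides: int

    def __post_init__(self):
        assert self.distinct_peptides <= self.psm_count


@dataclass(frozen=True)
class IdentificationResult:
    ranked: tuple[TaxonCount, ...]
    total_psms_mapped: int
    total_psms_input: int
    qc_pass: bool
    qc_reason: str
    iteration: str  # species | strain
    tie_at_rank1: bool
    source_db: str = "primary"

    @property
    def top(self) -> TaxonCount | None:
        return self.ranked[0] if self.ranked else None

    def rank_of(self, taxid: int) -> int | None:
        """1-based rank of a taxon in the result (benchmark reporting)."""
        for i, tc in enumerate(self.ranked, start=1):
            if tc.taxid == taxid:
                return i
        return None


def map_psms_to_taxa(
    psm_table: PsmTable, index: ReferenceIndex
) -> list[TaxonCount]:
    """Count mapped PSMs per taxon (shared peptides once per taxon).

    Returns one :class:`TaxonCount` for every taxon in the index,
    including zero-count taxa, ordered by taxid.
    """
    if len(index) == 0:
        raise ValueError("empty reference index")
    if len(psm_table) == 0:
        logger.warning("empty PSM table; all taxon counts are zero")
    counts: dict[int, int] = {t: 0 for t in index.taxids}
    peptides_seen: dict[int, set[str]] = {t: set() for t in index.taxids}
    for psm in psm_table.psms:
        taxa = index.peptide_to_taxa.get(psm.peptide)
        if not taxa:
            continue
        for t in taxa:
            counts[t] += 1
            peptides_seen[t].add(psm.peptide)
    return [
        TaxonCount(
            taxid=t,
            display_name=index.display_name(t),
            psm_count=counts[t],
            distinct_peptides=len(peptides_seen[t]),
        )
        for t in sorted(counts)
    ]


def count_mapped_psms(psm_table: PsmTable, index: ReferenceIndex) -> int:
    """Number of PSMs whose peptide occurs anywhere in the index."""
    return sum(1 for p in psm_table.psms if p.peptide in index.peptide_to_taxa)


def rank_taxa(
    counts: Sequence[TaxonCount],
    qc_threshold: int = DEFAULT_QC_THRESHOLD,
    total_psms_mapped: int | None = None,
    total_psms_input: int | None = None,
    iteration: str = "species",
    source_db: str = "primary",
) -> IdentificationResult:
    """Rank taxa by mapped-PSM count and apply the QC rule.

    Ties in psm_count are broken by distinct contributing peptides, then
    by ascending taxid; an unbroken rank-1 count tie is flagged so
    ambiguous pairs (e.g. Shigella/E. coli-like) are visible.
    """
    ranked = tuple(
        sorted(counts, key=lambda c: (-c.psm_count, -c.distinct_peptides, c.taxid))
    )
    if total_psms_mapped is None:
        # Upper bound when the caller did not supply the mapped total.
        total_psms_mapped = max((c.psm_count for c in ranked), default=0)
    if total_psms_input is None:
        total_psms_input = total_psms_mapped
    # only an unbroken tie (same counts AND same distinct peptides) is flagged
    tie = (
        len(ranked) > 1
        and ranked[0].psm_count == ranked[1].psm_count
        and ranked[0].distinct_peptides == ranked[1].distinct_peptides
    )
    qc_pass = total_psms_mapped >= qc_threshold
    return IdentificationResult(
        ranked=ranked,
        total_psms_mapped=total_psms_mapped,
        total_psms_input=total_psms_input,
        qc_pass=qc_pass,
        qc_reason="" if qc_pass else f"PSMs<{qc_threshold}",
        iteration=iteration,
        tie_at_rank1=tie,
        source_db=source_db,
    )


def identify(
    psm_table: PsmTable,
    species_index: ReferenceIndex,
    qc_threshold: int = DEFAULT_QC_THRESHOLD,
) -> IdentificationResult:
    """First iteration: identification against the species-level database."""
    counts = map_psms_to_taxa(psm_table, species_index)
    return rank_taxa(
        counts,
        qc_threshold=qc_threshold,
        total_psms_mapped=count_mapped_psms(psm_table, species_index),
        total_psms_input=len(psm_table),
        iteration="species",
    )


def identify_strain(
    psm_table: PsmTable,
    strain_index: ReferenceIndex,
    qc_threshold: int = DEFAULT_QC_THRESHOLD,
) -> IdentificationResult:
    """Second iteration: identification against a genus-scoped strain database."""
    if len(strain_index) == 0 or not strain_index.taxa:
        raise ValueError("empty strain-level index")
    counts = map_psms_to_taxa(psm_table, strain_index)
    return rank_taxa(
        counts,
        qc_threshold=qc_threshold,
        total_psms_mapped=count_mapped_psms(psm_table, strain_index),
        total_psms_input=len(psm_table),
        iteration="strain",
    )


def identify_with_fallback(
    psm_table: PsmTable,
    primary_index: ReferenceIndex,
    fallback_index: ReferenceIndex | None = None,
    qc_threshold: int = DEFAULT_QC_THRESHOLD,
) -> IdentificationResult:
    """Identify; on QC failure retry against an alternate-kingdom database.

    When the primary result fails the mapped-PSM QC rule and a fallback
    database (e.g. fungal proteomes) is configured, the result with the
    larger mapped-PSM total is returned, labeled with its source.  When
    both fail QC, the primary result is returned with ``qc_pass`` False.
    """
    primary = identify(psm_table, primary_index, qc_threshold=qc_threshold)
    if primary.qc_pass or fallback_index is None:
        return primary
    counts = map_psms_to_taxa(psm_table, fallback_index)
    fallback = rank_taxa(
        counts,
        qc_threshold=qc_threshold,
        total_psms_mapped=count_mapped_psms(psm_table, fallback_index),
        total_psms_input=len(psm_table),
        iteration="species",
        source_db="fallback",
    )
    if fallback.total_psms_mapped > primary.total_psms_mapped and fallback.qc_pass:
        return fallback
    return primary


def write_report(
    result: IdentificationResult, out_dir: str | Path, basename: str = "identification"
) -> dict[str, Path]:
    """Write the ranking TSV and a single-page PDF report.

    The TSV lists the full ranking (taxid, name, psm_count,
    distinct_peptides, rank) and is bit-stable for fixed input; the PDF
    shows the mapped-PSM count distribution with the rank-1 taxon
    highlighted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{basename}.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("taxid\tname\tpsm_count\tdistinct_peptides\trank\n")
        for rank, tc in enumerate(result.ranked, start=1):
            fh.write(
                f"{tc.taxid}\t{tc.display_name}\t{tc.psm_count}\t"
                f"{tc.distinct_peptides}\t{rank}\n"
            )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pdf_path = out_dir / f"{basename}.pdf"
    fig, ax = plt.subplots(figsize=(7, 4.5))
    counts = [tc.psm_count for tc in result.ranked]
    if counts:
        ax.hist(counts, bins=min(50, max(5, len(counts) // 2)), color="#6699cc")
        ax.axvline(counts[0], color="#cc3333", lw=1.5)
        top = result.ranked[0]
        ax.annotate(
            f"{top.display_name} ({top.psm_count} PSMs)",
            xy=(counts[0], ax.get_ylim()[1] * 0.9),
            ha="right", fontsize=8, color="#cc3333",
        )
    ax.set_xlabel("mapped PSMs per taxon")
    ax.set_ylabel("taxa")
    qc = "pass" if result.qc_pass else f"FAIL ({result.qc_reason})"
    ax.set_title(
        f"{result.iteration}-level identification — mapped "
        f"{result.total_psms_mapped}/{result.total_psms_input} PSMs, QC {qc}"
    )
    fig.tight_layout()
    fig.savefig(pdf_path)
    plt.close(fig)
    return {"tsv": tsv_path, "pdf": pdf_path}
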