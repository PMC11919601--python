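"""Abundance normalization and orthogroup conservation analytics.

iBAQ protein abundances are normalized two ways: *relative* iBAQ (each
protein divided by the per-sample iBAQ total, log10-transformed and
shifted by +10 to stay positive) and *z-scored* iBAQ (per-sample
standardization of log10 iBAQ to mean 0 / SD 1, right-shifted by +5),
which makes abundance distributions comparable across organisms.  iBAQ
zeros are treated as missing data, not true zeros (standard proteomics
convention).

Orthogroup (OG) conservation is classified by comparing each OG's binary
presence vector over the reference taxa against taxon-specific
conservation arrays (TSCAs) — indicator vectors of clade membership at
ranks domain, phylum, class, order, family and genus — and assigning the
class of the TSCA at minimum Hamming distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

#: Conservation-class ranks from most to least general, with class letters.
CONSERVATION_RANKS = (
    ("domain", "D"),
    ("phylum", "P"),
    ("class", "C"),
    ("order", "O"),
    ("family", "F"),
    ("genus", "G"),
)
_RANK_GENERALITY = {rank: i for i, (rank, _) in enumerate(CONSERVATION_RANKS)}
RANK_LETTERS = dict(CONSERVATION_RANKS)


# ---------------------------------------------------------------------------
# Abundance normalization


def relative_ibaq(
    table: pd.DataFrame,
    ibaq_col: str = "ibaq",
    sample_col: str = "sample",
    out_col: str = "rel_ibaq_log10",
) -> pd.DataFrame:
    """Add the relative-iBAQ column: log10(ibaq / per-sample total) + 10.

    Proteins with ibaq == 0 receive a missing value.  A sample whose iBAQ
    total is zero is an error.
    """
    df = table.copy()
    if sample_col not in df.columns:
        df[sample_col] = "sample"
    ibaq = df[ibaq_col].astype(float)
    if (ibaq < 0).any():
        raise ValueError("negative iBAQ values")
    totals = ibaq.groupby(df[sample_col]).transform("sum")
    zero_samples = df.loc[totals == 0, sample_col].unique()
    if len(zero_samples):
        raise ValueError(f"all-zero iBAQ in sample(s) {list(zero_samples)}")
    rel = ibaq / totals
    df[out_col] = np.where(ibaq > 0, np.log10(rel.where(ibaq > 0)) + 10, np.nan)
    return df


def zscore_ibaq(
    table: pd.DataFrame,
    ibaq_col: str = "ibaq",
    sample_col: str = "sample",
    out_col: str = "z_ibaq",
) -> pd.DataFrame:
    """Add the z-scored iBAQ column: standardized log10 iBAQ + 5 per sample.

    Standardization uses the population SD (so two quantified proteins
    map to exactly {4, 6}).  Zeros are missing; a sample needs at least
    two quantified proteins with non-zero log10 variance.
    """
    df = table.copy()
    if sample_col not in df.columns:
        df[sample_col] = "sample"
    ibaq = df[ibaq_col].astype(float)
    log10 = np.where(ibaq > 0, np.log10(ibaq.where(ibaq > 0)), np.nan)
    df["_log10"] = log10
    out = np.full(len(df), np.nan)
    for sample, grp in df.groupby(sample_col):
        vals = grp["_log10"].dropna()
        if len(vals) < 2:
            raise ValueError(
                f"sample {sample!r}: need >=2 quantified proteins to z-score"
            )
        mu, sigma = vals.mean(), vals.std(ddof=0)
        if sigma == 0:
            raise ValueError(f"sample {sample!r}: zero variance of log10 iBAQ")
        idx = grp.index
        out[df.index.get_indexer(idx)] = (grp["_log10"] - mu) / sigma + 5
    df[out_col] = out
    return df.drop(columns=["_log10"])


# ---------------------------------------------------------------------------
# Orthogroup presence and conservation classes


@dataclass(frozen=True)
class Tsca:
    """Taxon-specific conservation array: clade-membership indicator."""

    rank: str
    taxid: int
    array: np.ndarray  # int8 over the taxid ordering of the presence matrix

    @property
    def class_letter(self) -> str:
        return RANK_LETTERS[self.rank]


@dataclass
class OrthogroupMatrix:
    """Binary OG × taxon presence matrix with optional class labels."""

    presence: pd.DataFrame  # index og_id, columns taxid, values {0,1}
    classes: pd.DataFrame | None = None  # og_id -> class, hamming, winner

    @property
    def taxids(self) -> tuple[int, ...]:
        return tuple(self.presence.columns)


def read_orthogroups_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read an OrthoFinder-style Orthogroups.tsv into og → protein-id sets.

    First column is the OG id; remaining columns hold comma-separated
    protein lists per proteome.
    """
    membership: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            og = cells[0]
            proteins = set()
            for cell in cells[1:]:
                proteins.update(p.strip() for p in cell.split(",") if p.strip())
            membership[og] = proteins
    return membership


def og_presence_matrix(
    og_membership: Mapping[str, set[str]],
    proteomes: Mapping[int, Sequence],
) -> OrthogroupMatrix:
    """Binary presence matrix: 1 iff ≥1 OG member is in the taxon's proteome.

    ``proteomes`` maps taxid to protein records or plain protein ids.
    OGs with fewer than two member proteins are rejected (an orthogroup
    always comprises at least two entries); member proteins attributable
    to no proteome are ignored with a warning.
    """
    protein_to_taxid: dict[str, int] = {}
    for taxid, prots in proteomes.items():
        for p in prots:
            pid = getattr(p, "protein_id", p)
            protein_to_taxid[pid] = taxid
    taxids = sorted(proteomes)
    rows = {}
    n_orphans = 0
    for og in sorted(og_membership):
        members = og_membership[og]
        if len(members) < 2:
            logger.info("orthogroup %s rejected: fewer than two members", og)
            continue
        present: set[int] = set()
        for pid in members:
            taxid = protein_to_taxid.get(pid)
            if taxid is None:
                n_orphans += 1
                continue
            present.add(taxid)
        rows[og] = [1 if t in present else 0 for t in taxids]
    if n_orphans:
        logger.warning("%d orthogroup member proteins found in no proteome", n_orphans)
    presence = pd.DataFrame.from_dict(
        rows, orient="index", columns=taxids, dtype=np.int8
    )
    presence.index.name = "og_id"
    return OrthogroupMatrix(presence=presence)


def build_tscas(
    taxonomy: Taxonomy, taxid_order: Sequence[int]
) -> list[Tsca]:
    """One TSCA per (rank, clade) with ≥1 member among ``taxid_order``.

    Ranks domain through genus are covered; the all-ones domain TSCA is
    always emitted even when no node carries an explicit domain rank.
    """
    taxid_order = list(taxid_order)
    tscas: list[Tsca] = []
    domain_emitted = False
    for rank, _letter in CONSERVATION_RANKS:
        ancestors = [taxonomy.rank_ancestor(t, rank) for t in taxid_order]
        for anc in sorted({a for a in ancestors if a is not None}):
            arr = np.fromiter(
                (1 if a == anc else 0 for a in ancestors), dtype=np.int8,
                count=len(taxid_order),
            )
            tscas.append(Tsca(rank=rank, taxid=anc, array=arr))
            if rank == "domain":
                domain_emitted = True
    if not domain_emitted:
        root = taxonomy.lineage(taxid_order[0])[0] if taxid_order else 1
        tscas.insert(
            0,
            Tsca(rank="domain", taxid=root,
                 array=np.ones(len(taxid_order), dtype=np.int8)),
        )
    return tscas


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions where two binary arrays disagree."""
    return int(np.abs(np.asarray(a, dtype=int) - np.asarray(b, dtype=int)).sum())


def classify_og(
    og_row: np.ndarray, tscas: Sequence[Tsca]
) -> tuple[str, int, Tsca]:
    """Conservation class of one OG presence row.

    The winner is the TSCA at minimum Hamming distance; ties are resolved
    toward the most general rank (D over P over C over O over F over G),
    then the lowest clade taxid, so conservation is never overstated as
    lineage-specific.
    """
    og_row = np.asarray(og_row, dtype=np.int8)
    best: tuple[int, int, int] | None = None
    winner: Tsca | None = None
    for tsca in tscas:
        key = (hamming(og_row, tsca.array), _RANK_GENERALITY[tsca.rank], tsca.taxid)
        if best is None or key < best:
            best, winner = key, tsca
    assert winner is not None and best is not None
    return winner.class_letter, best[0], winner


def classify_matrix(
    matrix: OrthogroupMatrix, tscas: Sequence[Tsca]
) -> OrthogroupMatrix:
    """Classify every OG row; attaches a classes table to the matrix."""
    records = []
    for og, row in matrix.presence.iterrows():
        letter, dist, winner = classify_og(row.to_numpy(), tscas)
        records.append((og, letter, dist, winner.rank, winner.taxid))
    classes = pd.DataFrame.from_records(
        records,
        columns=["og_id", "conservation_class", "hamming", "winner_rank",
                 "winner_taxid"],
    ).set_index("og_id")
    return OrthogroupMatrix(presence=matrix.presence, classes=classes)


def expression_conservation_summary(
    matrix: OrthogroupMatrix,
    abundance: pd.DataFrame,
    z_quantile: float = 0.75,
    og_col: str = "og_id",
    taxid_col: str = "taxid",
    z_col: str = "z_ibaq",
) -> pd.DataFrame:
    """Per-OG expression level by conservation class.

    (1) keep OGs whose Hamming distance is at or below the
    ``z_quantile`` quantile of Hamming distances within their class
    (computed over all OGs of the class); (2) summarize paralogs within
    each OG × species by the median z-scored iBAQ; (3) the OG expression
    level is the maximum of those per-species medians.  OGs without any
    quantified protein are dropped and counted.
    """
    if matrix.classes is None:
        raise ValueError("orthogroup matrix is not classified")
    classes = matrix.classes
    # "higher" interpolation guarantees the cutoff is an attained value, so
    # at least a z_quantile share of each class survives the filter
    cutoffs = classes.groupby("conservation_class")["hamming"].quantile(
        z_quantile, interpolation="higher"
    )
    keep = classes[
        classes["hamming"] <= classes["conservation_class"].map(cutoffs)
    ].index
    quant = abundance.dropna(subset=[z_col])
    quant = quant[quant[og_col].isin(keep)]
    n_unquantified = len(set(keep) - set(quant[og_col]))
    if n_unquantified:
        logger.info("%d retained OGs had no quantified protein; dropped",
                    n_unquantified)
    per_species = (
        quant.groupby([og_col, taxid_col])[z_col].median().reset_index()
    )
    summary = (
        per_species.groupby(og_col)[z_col].max().rename("og_expression")
        .to_frame()
    )
    summary["conservation_class"] = classes.loc[
        summary.index, "conservation_class"
    ]
    summary["hamming"] = classes.loc[summary.index, "hamming"]
    return summary.reset_index()


# ---------------------------------------------------------------------------
# Protein-group post-filter

_FILTER_COLUMNS = {
    "reverse": "Reverse",
    "site_only": "Only identified by site",
    "contaminant": "Potential contaminant",
    "peptides": "Peptides",
    "ibaq": "iBAQ",
}


def filter_protein_groups(
    rows: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Drop decoy / site-only / contaminant / weak protein-group rows.

    Removes rows that are decoys ("Reverse"), identified only by a
    modification site, potential contaminants, have fewer than two
    peptides, or an iBAQ of zero — the standard post-filter before
    interpreting a marker-protein search (e.g. for antibiotic-resistance
    proteins).  Flag columns follow the MaxQuant convention ('+' marks a
    flagged row).  Removal counts per criterion are logged and attached
    as ``result.attrs['removal_counts']``.
    """
    cols = {**_FILTER_COLUMNS, **(column_map or {})}
    missing = [c for c in cols.values() if c not in rows.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    def flagged(col: str) -> pd.Series:
        return rows[cols[col]].fillna("").astype(str).str.strip() == "+"

    bad_reverse = flagged("reverse")
    bad_site = flagged("site_only")
    bad_contaminant = flagged("contaminant")
    bad_peptides = rows[cols["peptides"]].astype(float) < 2
    bad_ibaq = rows[cols["ibaq"]].astype(float) == 0
    removal_counts = {
        "reverse": int(bad_reverse.sum()),
        "only_identified_by_site": int(bad_site.sum()),
        "potential_contaminant": int(bad_contaminant.sum()),
        "fewer_than_two_peptides": int(bad_peptides.sum()),
        "zero_ibaq": int(bad_ibaq.sum()),
    }
    logger.info("protein-group filter removal counts: %s", removal_counts)
    keep = ~(bad_reverse | bad_site | bad_contaminant | bad_peptides | bad_ibaq)
    out = rows[keep].copy()
    out.attrs["removal_counts"] = removal_counts
    return out
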