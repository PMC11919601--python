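"""Synthetic taxonomies, proteomes, and noisy 100%-FDR PSM tables.

Generates a hierarchical taxonomy (domain → phylum → genus → species →
strain), evolves proteomes down that tree by per-rank substitution (no
indels — identification depends only on peptide-set overlap structure),
and simulates search-engine PSM tables in which a configurable fraction
of spectra are noise matches drawn uniformly from the whole reference
peptide space, emulating the behavior of an unfiltered (100% FDR)
database search.

Default per-branch substitution probabilities (phylum 0.40, genus 0.15,
species 0.06, strain 0.015) are calibrated so that sibling strains share
roughly 70% of their tryptic peptides and within-genus species roughly
5%, matching the overlap regimes reported for real bacterial peptidomes
(peptide survival ≈ exp(−2·L̄·d) at mean tryptic peptide length L̄ ≈ 12).

Random number streams are per component (taxonomy/sequences vs PSMs), so
changing PSM simulation settings never perturbs the proteomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import DigestParams, PeptideSet, ProteinRecord, write_fasta
from .psm_io import Psm, PsmTable
from .reference import ReferenceIndex, index_from_peptide_sets
from .taxonomy import AssemblyRecord, TaxonNode, Taxonomy
from . import digestion

logger = logging.getLogger(__name__)

_ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_K = _ALPHABET.tolist().index(ord("K"))
_R = _ALPHABET.tolist().index(ord("R"))
_NON_KR = np.array([i for i in range(20) if i not in (_K, _R)])
# Roughly natural K/R frequencies so tryptic peptides average ~12 residues.
_AA_PROBS = np.full(20, (1.0 - 0.115) / 18)
_AA_PROBS[_K] = 0.060
_AA_PROBS[_R] = 0.055


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and divergence of a synthetic bacterial collection."""

    n_phyla: int = 4
    n_genera_per_phylum: int = 3
    n_species_per_genus: int = 5
    n_strains_per_species: int = 2
    proteins_per_proteome: int = 20
    mean_protein_len: int = 250
    divergence: Mapping[str, float] = field(
        default_factory=lambda: {
            "phylum": 0.40, "genus": 0.15, "species": 0.06, "strain": 0.015,
        }
    )
    seed: int = 0

    def __post_init__(self):
        d = self.divergence
        order = [d["phylum"], d["genus"], d["species"], d["strain"]]
        if any(not (0.0 <= v <= 1.0) for v in order):
            raise ValueError("divergence values must lie in [0, 1]")
        if any(a < b for a, b in zip(order, order[1:])):
            raise ValueError("divergence must be non-increasing phylum→strain")
        if self.n_species_per_genus < 1 or self.n_phyla < 1:
            raise ValueError("degenerate fixture spec: need >=1 taxon per rank")


@dataclass(frozen=True)
class PsmSimSpec:
    """Settings for one simulated 100%-FDR PSM table."""

    true_taxid: int
    n_psms: int = 2000
    noise_fraction: float = 0.3
    hyperscore_signal_mean: float = 25.0
    hyperscore_noise_mean: float = 15.0
    seed: int = 0
    run_id: str = "sim"

    def __post_init__(self):
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")


class SyntheticCollection:
    """A generated taxonomy plus per-strain proteomes and ground truth."""

    def __init__(
        self,
        taxonomy: Taxonomy,
        proteomes: dict[int, list[ProteinRecord]],
        truth: pd.DataFrame,
    ):
        self.taxonomy = taxonomy
        self.proteomes = proteomes
        self.truth = truth
        self._peptide_sets: dict[DigestParams, dict[int, PeptideSet]] = {}
        self._species_index: dict[DigestParams, ReferenceIndex] = {}
        self._strain_index: dict[tuple, ReferenceIndex] = {}

    # -- digestion ---------------------------------------------------------

    def peptide_sets(
        self, params: DigestParams = DigestParams()
    ) -> dict[int, PeptideSet]:
        """Per-strain I/L-collapsed tryptic peptide sets (cached)."""
        if params not in self._peptide_sets:
            self._peptide_sets[params] = {
                taxid: digestion.build_peptide_set(records, params, taxid=taxid)
                for taxid, records in self.proteomes.items()
            }
        return self._peptide_sets[params]

    # -- reference indexes -------------------------------------------------

    def species_index(
        self, params: DigestParams = DigestParams()
    ) -> ReferenceIndex:
        """Species-level index over representative strains (cached)."""
        if params not in self._species_index:
            sets = self.peptide_sets(params)
            species_sets, names = [], {}
            for row in self.truth.itertuples():
                if not row.is_representative:
                    continue
                ps = sets[row.strain_taxid]
                species_sets.append(
                    PeptideSet(
                        taxid=row.species_taxid,
                        peptides=ps.peptides,
                        n_source_proteins=ps.n_source_proteins,
                    )
                )
                names[row.species_taxid] = self.taxonomy.name(row.species_taxid)
            self._species_index[params] = index_from_peptide_sets(
                species_sets, params, taxonomy=self.taxonomy,
                level="species", names=names,
            )
        return self._species_index[params]

    def strain_index(
        self,
        genus_taxid: int,
        params: DigestParams = DigestParams(),
        aliases: Sequence[int] = (),
    ) -> ReferenceIndex:
        """Strain-level index over all strains of a genus (cached)."""
        key = (genus_taxid, tuple(sorted(aliases)), params)
        if key not in self._strain_index:
            scope = set(aliases) | {genus_taxid}
            sets = self.peptide_sets(params)
            strain_sets = [
                sets[row.strain_taxid]
                for row in self.truth.itertuples()
                if row.genus_taxid in scope
            ]
            if not strain_sets:
                raise ValueError(f"no strains for genus {genus_taxid}")
            self._strain_index[key] = index_from_peptide_sets(
                strain_sets, params, taxonomy=self.taxonomy, level="strain",
            )
        return self._strain_index[key]

    # -- file emission -----------------------------------------------------

    def assembly_records(self, fasta_dir: str | Path | None = None) -> list[AssemblyRecord]:
        """Assembly metadata for the collection (representatives flagged)."""
        records = []
        for row in self.truth.itertuples():
            fasta = (
                str(Path(fasta_dir) / f"strain_{row.strain_taxid}.fasta")
                if fasta_dir
                else ""
            )
            records.append(
                AssemblyRecord(
                    assembly_accession=f"GCF_{row.strain_taxid:09d}.1",
                    taxid=row.strain_taxid,
                    species_taxid=row.species_taxid,
                    organism_name=self.taxonomy.name(row.species_taxid),
                    strain_label=self.taxonomy.name(row.strain_taxid),
                    ani_status="OK",
                    refseq_category=(
                        "representative genome" if row.is_representative else "na"
                    ),
                    assembly_level="Complete Genome",
                    is_type_strain=bool(row.is_representative),
                    fasta_path=fasta,
                )
            )
        return records

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit taxdump nodes/names, assembly summary, and per-strain FASTA.

        Exactly the dialects the real pipeline ingests, so file-based
        code paths can be exercised on synthetic data.
        """
        out_dir = Path(out_dir)
        fasta_dir = out_dir / "fastas"
        fasta_dir.mkdir(parents=True, exist_ok=True)
        nodes_path = out_dir / "nodes.dmp"
        names_path = out_dir / "names.dmp"
        with open(nodes_path, "w") as nodes_fh, open(names_path, "w") as names_fh:
            for taxid in self.taxonomy.taxids():
                node = self.taxonomy.node(taxid)
                nodes_fh.write(
                    f"{node.taxid}\t|\t{node.parent_taxid}\t|\t{node.rank}\t|\n"
                )
                names_fh.write(
                    f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n"
                )
        for taxid, records in sorted(self.proteomes.items()):
            write_fasta(records, fasta_dir / f"strain_{taxid}.fasta")
        summary_path = out_dir / "assembly_summary.txt"
        fields = [
            "assembly_accession", "taxid", "species_taxid", "organism_name",
            "infraspecific_name", "ani_status", "refseq_category",
            "assembly_level", "relation_to_type_material", "fasta_path",
        ]
        with open(summary_path, "w") as fh:
            fh.write("# synthetic assembly metadata\n")
            fh.write("#" + "\t".join(fields) + "\n")
            for rec in self.assembly_records(fasta_dir):
                fh.write(
                    "\t".join(
                        [
                            rec.assembly_accession,
                            str(rec.taxid),
                            str(rec.species_taxid),
                            rec.organism_name,
                            rec.strain_label,
                            rec.ani_status,
                            rec.refseq_category,
                            rec.assembly_level,
                            "assembly from type material" if rec.is_type_strain else "",
                            rec.fasta_path,
                        ]
                    )
                    + "\n"
                )
        return {
            "nodes": nodes_path,
            "names": names_path,
            "assembly_summary": summary_path,
            "fasta_dir": fasta_dir,
        }


# ---------------------------------------------------------------------------
# Sequence evolution


def _random_proteome(rng: np.random.Generator, n_proteins: int, mean_len: int):
    lengths = rng.integers(
        max(30, int(0.8 * mean_len)), int(1.2 * mean_len) + 1, size=n_proteins
    )
    return [rng.choice(20, size=int(n), p=_AA_PROBS).astype(np.uint8)
            for n in lengths]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute residues at the given per-site probability.

    K/R positions keep a cleavage-competent residue with probability 0.5
    when mutated, so cleavage maps drift rather than collapse.
    """
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit) == 0:
        return out
    for i in hit:
        cur = out[i]
        if cur in (_K, _R):
            if rng.random() < 0.5:
                out[i] = _R if cur == _K else _K
            else:
                out[i] = rng.choice(_NON_KR)
        else:
            new = rng.integers(0, 19)
            if new >= cur:
                new += 1
            out[i] = new
    return out


def _decode(seqs: list[np.ndarray], taxid: int, prefix: str) -> list[ProteinRecord]:
    return [
        ProteinRecord(
            protein_id=f"{prefix}_{taxid}_{i:04d}",
            description=f"{prefix}_{taxid}_{i:04d} synthetic protein",
            sequence=_ALPHABET[seq].tobytes().decode("ascii"),
            source_taxid=taxid,
        )
        for i, seq in enumerate(seqs)
    ]


def generate_proteomes(spec: FixtureSpec) -> SyntheticCollection:
    """Generate a hierarchical collection of synthetic strain proteomes.

    An ancestral proteome is mutated down a domain → phylum → genus →
    species → strain taxonomy with per-rank substitution probabilities.
    Deterministic for a fixed seed; the truth table records the lineage
    and representative status of every strain (the first strain of each
    species is the species representative).
    """
    seq_stream, _ = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(seq_stream)

    nodes = [TaxonNode(taxid=1, parent_taxid=1, rank="domain", name="Domain")]
    proteomes: dict[int, list[ProteinRecord]] = {}
    truth_rows = []
    next_taxid = 2
    ancestral = _random_proteome(rng, spec.proteins_per_proteome, spec.mean_protein_len)
    div = spec.divergence
    for p in range(spec.n_phyla):
        phylum_id, next_taxid = next_taxid, next_taxid + 1
        nodes.append(TaxonNode(phylum_id, 1, "phylum", f"Phylum{phylum_id}"))
        phylum_prot = [_mutate(s, div["phylum"], rng) for s in ancestral]
        for g in range(spec.n_genera_per_phylum):
            genus_id, next_taxid = next_taxid, next_taxid + 1
            genus_name = f"Genus{genus_id}"
            nodes.append(TaxonNode(genus_id, phylum_id, "genus", genus_name))
            genus_prot = [_mutate(s, div["genus"], rng) for s in phylum_prot]
            for s in range(spec.n_species_per_genus):
                species_id, next_taxid = next_taxid, next_taxid + 1
                species_name = f"{genus_name} species{species_id}"
                nodes.append(
                    TaxonNode(species_id, genus_id, "species", species_name)
                )
                species_prot = [_mutate(q, div["species"], rng) for q in genus_prot]
                for k in range(spec.n_strains_per_species):
                    strain_id, next_taxid = next_taxid, next_taxid + 1
                    nodes.append(
                        TaxonNode(
                            strain_id, species_id, "strain",
                            f"{species_name} strain S{k + 1}",
                        )
                    )
                    strain_prot = [
                        _mutate(q, div["strain"], rng) for q in species_prot
                    ]
                    proteomes[strain_id] = _decode(strain_prot, strain_id, "SYN")
                    truth_rows.append(
                        {
                            "strain_taxid": strain_id,
                            "species_taxid": species_id,
                            "genus_taxid": genus_id,
                            "phylum_taxid": phylum_id,
                            "is_representative": k == 0,
                        }
                    )
    taxonomy = Taxonomy(nodes)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCollection(taxonomy=taxonomy, proteomes=proteomes, truth=truth)


# ---------------------------------------------------------------------------
# PSM simulation


def simulate_psm_table(
    spec: PsmSimSpec,
    index: ReferenceIndex,
    signal_peptides: Sequence[str] | None = None,
    n_chunks: int | None = None,
) -> PsmTable | list[PsmTable]:
    """Simulate a best-PSM-per-spectrum table at a given noise fraction.

    ``(1 − noise_fraction) · n_psms`` signal PSMs carry peptides drawn
    uniformly (with replacement) from the true taxon's peptide set —
    or from ``signal_peptides`` when the sample organism is not itself an
    index entry (e.g. a strain searched against a species-level index) —
    with hyperscores ~ Normal(signal_mean, 1).  The remaining noise PSMs
    carry peptides drawn uniformly from the whole index key space with
    hyperscores ~ Normal(noise_mean, 1).  Spectrum keys are unique and
    the table is deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    if signal_peptides is None:
        pool = sorted(index.peptides_of(spec.true_taxid))
    else:
        pool = sorted(signal_peptides)
    if not pool:
        raise ValueError(f"true taxon {spec.true_taxid} has no peptides")
    noise_pool = sorted(index.peptide_to_taxa)
    n_noise = int(round(spec.noise_fraction * spec.n_psms))
    n_signal = spec.n_psms - n_noise

    pool_arr = np.array(pool, dtype=object)
    noise_arr = np.array(noise_pool, dtype=object)
    peptides = np.concatenate(
        [
            pool_arr[rng.integers(0, len(pool_arr), size=n_signal)],
            noise_arr[rng.integers(0, len(noise_arr), size=n_noise)],
        ]
    )
    scores = np.concatenate(
        [
            rng.normal(spec.hyperscore_signal_mean, 1.0, size=n_signal),
            rng.normal(spec.hyperscore_noise_mean, 1.0, size=n_noise),
        ]
    )
    order = rng.permutation(spec.n_psms)
    psms = tuple(
        Psm(
            spectrum_key=f"{spec.run_id}:{i + 1}",
            peptide=str(peptides[j]),
            charge=2,
            hyperscore=float(scores[j]),
            chunk_id=0,
        )
        for i, j in enumerate(order)
    )
    table = PsmTable(psms=psms, run_id=spec.run_id)
    if n_chunks is None:
        return table
    chunks: list[list[Psm]] = [[] for _ in range(n_chunks)]
    for i, psm in enumerate(table.psms):
        chunks[i % n_chunks].append(replace(psm, chunk_id=i % n_chunks))
    return [
        PsmTable(psms=tuple(chunk), run_id=spec.run_id) for chunk in chunks
    ]


# ---------------------------------------------------------------------------
# Constructed misidentification scenario


@dataclass(frozen=True)
class MisidentificationScenario:
    """A sample strain whose species representative is a poor proxy.

    The sample strain's peptidome is closer to a sibling species'
    representative than to its own species' representative, so the first
    (species-level) iteration misidentifies it; the second (strain-level)
    iteration, whose database contains the sample strain itself, corrects
    the call.
    """

    collection: SyntheticCollection
    sample_taxid: int          # the strain actually measured
    true_species: int
    decoy_species: int         # the species the first iteration reports
    genus_taxid: int


def make_misidentification_scenario(seed: int = 0) -> MisidentificationScenario:
    """Construct the divergent-representative scenario deterministically.

    Species A's representative strain (A1) is heavily diverged from the
    species ancestor, while the sample strain (A2) and sibling species
    B's representative (B1) both sit close to the genus core — so A2
    shares more peptides with B1 than with A1.
    """
    rng = np.random.default_rng(seed)
    nodes = [
        TaxonNode(1, 1, "domain", "Domain"),
        TaxonNode(2, 1, "phylum", "Phylum2"),
        TaxonNode(3, 2, "genus", "Genus3"),
        TaxonNode(4, 2, "genus", "Genus4"),
        TaxonNode(10, 3, "species", "Genus3 speciesA"),
        TaxonNode(20, 3, "species", "Genus3 speciesB"),
        TaxonNode(30, 4, "species", "Genus4 speciesC"),
        TaxonNode(11, 10, "strain", "Genus3 speciesA strain A1"),
        TaxonNode(12, 10, "strain", "Genus3 speciesA strain A2"),
        TaxonNode(21, 20, "strain", "Genus3 speciesB strain B1"),
        TaxonNode(31, 30, "strain", "Genus4 speciesC strain C1"),
    ]
    root = _random_proteome(rng, 20, 250)
    genus3 = [_mutate(s, 0.10, rng) for s in root]
    genus4 = [_mutate(s, 0.10, rng) for s in root]
    anc_a = [_mutate(s, 0.02, rng) for s in genus3]
    anc_b = [_mutate(s, 0.01, rng) for s in genus3]
    anc_c = [_mutate(s, 0.02, rng) for s in genus4]
    proteomes = {
        11: _decode([_mutate(s, 0.12, rng) for s in anc_a], 11, "SYN"),
        12: _decode([_mutate(s, 0.005, rng) for s in anc_a], 12, "SYN"),
        21: _decode([_mutate(s, 0.005, rng) for s in anc_b], 21, "SYN"),
        31: _decode([_mutate(s, 0.005, rng) for s in anc_c], 31, "SYN"),
    }
    truth = pd.DataFrame(
        [
            {"strain_taxid": 11, "species_taxid": 10, "genus_taxid": 3,
             "phylum_taxid": 2, "is_representative": True},
            {"strain_taxid": 12, "species_taxid": 10, "genus_taxid": 3,
             "phylum_taxid": 2, "is_representative": False},
            {"strain_taxid": 21, "species_taxid": 20, "genus_taxid": 3,
             "phylum_taxid": 2, "is_representative": True},
            {"strain_taxid": 31, "species_taxid": 30, "genus_taxid": 4,
             "phylum_taxid": 2, "is_representative": True},
        ]
    )
    collection = SyntheticCollection(
        taxonomy=Taxonomy(nodes), proteomes=proteomes, truth=truth
    )
    return MisidentificationScenario(
        collection=collection,
        sample_taxid=12,
        true_species=10,
        decoy_species=20,
        genus_taxid=3,
    )


# ---------------------------------------------------------------------------
# End-to-end benchmark


def run_identification_benchmark(
    collection: SyntheticCollection | None = None,
    fixture_spec: FixtureSpec | None = None,
    n_samples: int = 200,
    n_psms: int = 2000,
    noise_fraction: float = 0.3,
    seed: int = 0,
    params: DigestParams = DigestParams(),
) -> pd.DataFrame:
    """Run the two-iteration identification over simulated samples.

    Per sample a true strain is drawn uniformly; signal peptides come
    from its proteome while noise peptides come from the species-level
    index key space.  Returns one row per sample with the predicted
    species/strain and the rank of the truth in each iteration.
    """
    from . import identification

    if collection is None:
        collection = generate_proteomes(fixture_spec or FixtureSpec(seed=seed))
    species_index = collection.species_index(params)
    strain_sets = collection.peptide_sets(params)
    truth = collection.truth
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    sample_seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    strain_rows = list(truth.itertuples())
    rows = []
    for i in range(n_samples):
        row = strain_rows[int(rng.integers(0, len(strain_rows)))]
        sim = PsmSimSpec(
            true_taxid=row.strain_taxid,
            n_psms=n_psms,
            noise_fraction=noise_fraction,
            seed=int(sample_seeds[i]),
            run_id=f"sample{i}",
        )
        table = simulate_psm_table(
            sim, species_index,
            signal_peptides=strain_sets[row.strain_taxid].peptides,
        )
        species_res = identification.identify(table, species_index)
        pred_species = species_res.top.taxid
        genus = collection.taxonomy.rank_ancestor(pred_species, "genus")
        strain_res = identification.identify_strain(
            table, collection.strain_index(genus, params)
        )
        rows.append(
            {
                "sample": i,
                "true_strain": row.strain_taxid,
                "true_species": row.species_taxid,
                "species_pred": pred_species,
                "species_rank_of_truth": species_res.rank_of(row.species_taxid),
                "strain_pred": strain_res.top.taxid,
                "strain_rank_of_truth": strain_res.rank_of(row.strain_taxid),
            }
        )
    return pd.DataFrame(rows)


def benchmark_accuracies(results: pd.DataFrame) -> dict[str, float]:
    """Rank-1 accuracies of a benchmark result table."""
    return {
        "species_rank1_accuracy": float(
            (results["species_pred"] == results["true_species"]).mean()
        ),
        "strain_rank1_accuracy": float(
            (results["strain_pred"] == results["true_strain"]).mean()
        ),
    }
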