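"""Digest synthetic proteomes and compare their tryptic peptidomes.

Builds a small hierarchical collection of strain proteomes, digests them
in silico (trypsin/P, I/L-collapsed), and summarizes how peptide sharing
tracks taxonomy: strains of one genus share far more of their peptidome
than strains of different genera, and a large fraction of peptides is
private to a single organism — the property that makes PSM-counting
identification work.
"""

import itertools

import numpy as np

from proteotyper.similarity import jaccard, pairwise_similarity, unique_fraction
from proteotyper.simulate import FixtureSpec, generate_proteomes

collection = generate_proteomes(
    FixtureSpec(n_phyla=2, n_genera_per_phylum=2, n_species_per_genus=3,
                n_strains_per_species=2, seed=11)
)
sets = collection.peptide_sets()
truth = collection.truth
genus = dict(zip(truth.strain_taxid, truth.genus_taxid))

matrix = pairwise_similarity(list(sets.values()))
within, across = [], []
for a, b in itertools.combinations(sorted(sets), 2):
    (within if genus[a] == genus[b] else across).append(matrix.value(a, b))

per_taxon, global_unique = unique_fraction(list(sets.values()))

print(f"strains: {len(sets)}, peptides per strain (mean): "
      f"{np.mean([len(s.peptides) for s in sets.values()]):.0f}")
print(f"median Jaccard within a genus : {np.median(within):.3f}")
print(f"median Jaccard across genera  : {np.median(across):.3f}")
print(f"fraction of peptides private to one strain: {global_unique:.2f}")
print("-> peptidomes mirror the taxonomy: high overlap only among close "
      "relatives, and most peptides pinpoint a single organism.")
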