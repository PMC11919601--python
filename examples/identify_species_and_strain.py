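"""Two-iteration identification of a simulated bacterial isolate.

Simulates a 100%-FDR search result (70% of PSMs from the true strain's
peptidome, 30% random noise across the reference space), maps the PSMs
against a species-level reference index, then refines the call with a
strain-level index scoped to the identified genus.  The taxon with the
most mapped PSMs wins; noise spreads thinly over all other taxa.
"""

from proteotyper.identification import identify, identify_strain
from proteotyper.simulate import (
    FixtureSpec,
    PsmSimSpec,
    generate_proteomes,
    simulate_psm_table,
)

collection = generate_proteomes(FixtureSpec(seed=0))
species_index = collection.species_index()

truth = collection.truth.iloc[17]  # an arbitrary non-representative strain
table = simulate_psm_table(
    PsmSimSpec(true_taxid=int(truth.strain_taxid), n_psms=2000,
               noise_fraction=0.3, seed=42),
    species_index,
    signal_peptides=collection.peptide_sets()[int(truth.strain_taxid)].peptides,
)

first = identify(table, species_index)
print(f"iteration 1 (species level, {len(species_index.taxa)} taxa):")
for rank, tc in enumerate(first.ranked[:3], 1):
    print(f"  rank {rank}: {tc.display_name:24s} {tc.psm_count:5d} mapped PSMs")
print(f"  QC: {'pass' if first.qc_pass else first.qc_reason}; "
      f"mapped {first.total_psms_mapped}/{first.total_psms_input} PSMs")

genus = collection.taxonomy.rank_ancestor(first.top.taxid, "genus")
strain_index = collection.strain_index(genus)
second = identify_strain(table, strain_index)
print(f"iteration 2 (strains of genus {genus}, {len(strain_index.taxa)} taxa):")
for rank, tc in enumerate(second.ranked[:3], 1):
    print(f"  rank {rank}: {tc.display_name:32s} {tc.psm_count:5d} mapped PSMs")

ok = second.top.taxid == int(truth.strain_taxid)
print(f"true strain {collection.taxonomy.name(int(truth.strain_taxid))!r} "
      f"identified: {ok}")
print("-> the rank-1 gap over same-genus neighbours is the identification "
      "signal; other genera accumulate only noise-level counts.")
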