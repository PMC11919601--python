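# Methods

## Identification model

The identification statistic is a per-taxon count of mapped PSMs. Let
`P(t)` be the I/L-collapsed tryptic peptide set of taxon `t`'s reference
proteome and `s_1 … s_n` the best-per-spectrum peptide assignments of an
unfiltered (100% FDR) database search. The score of taxon `t` is

```
count(t) = Σ_i 1[ s_i ∈ P(t) ]
```

and the identification is `argmax_t count(t)`. A peptide shared by
several taxa contributes one count to each of them; a peptide carried by
several paralogous proteins of one taxon still contributes exactly one
count to that taxon (set semantics). The model's core assumption is
that incorrect PSMs — low-quality spectra forced to a best match because
no score threshold is applied — hit peptides essentially at random
across the reference, so their counts spread thinly over thousands of
taxa ("decoy species"), while correct PSMs concentrate on one organism.
This holds for pure cultures; mixed cultures violate it and are out of
scope.

Ranking ties in `count(t)` are broken by the number of distinct
contributing peptides, then by ascending taxid. Only a tie unbroken by
distinct peptides is flagged (`tie_at_rank1`), since such pairs
(Shigella/E. coli-like) are genuinely ambiguous at this level.

### Two iterations

Iteration 1 maps against a species-level database with one
representative proteome per species, selected by: ANI status "OK", a
proper binomial species name, and NCBI reference/representative-genome
status, preferring reference > representative, then type strains, then
the smallest accession (a deterministic version of a choice that
otherwise needs manual curation). Iteration 2 rebuilds the database
from **all** complete-genome strains of the rank-1 genus (strain taxids
as targets, no deduplication) and re-maps. Genus alias groups —
Escherichia/Shigella and Rhizobium/Agrobacterium by default — are merged
because they are effectively single genera. The second iteration both
resolves the strain and can correct a first-pass species error when the
species' lone representative poorly represents the sample (see the
constructed scenario below).

### QC and fallback

An identification with fewer than 500 mapped PSMs (configurable) fails
QC — too little signal to trust the argmax. When a fallback database is
configured (e.g. fungal proteomes for clinical isolates that are not
bacteria at all), a QC failure triggers a second mapping; the result
with more mapped PSMs is returned, labeled with its source.

### Chunked searches

A reference peptidome of hundreds of millions of peptides can exceed a
search engine's memory, so the reference FASTA is split round-robin
over protein records (deterministic, accession-ordered) into chunks
searched independently. Merging keeps, per spectrum, the PSM with the
highest hyperscore; ties fall back to the lexicographically smallest
peptide, then the lowest chunk id, making the merge associative and
order-independent. Spectrum keys normalize `run.scan.scan.charge` to
`run:scan`, deliberately excluding charge so one spectrum yields one
PSM.

## Digestion

Fully tryptic digestion with cleavage after K/R; trypsin/P cuts
regardless of a following proline, classical trypsin suppresses that
cut. Defaults: up to 2 missed cleavages, length 7–50, I/L collapse on
(with `L` as the canonical letter so outputs stay valid sequences).
The 7-residue minimum matches common search-engine settings; the missed
cleavage and maximum-length bounds are configurable since different
deployments of the upstream search differ. Fragments containing
non-canonical residues (X, B, Z, U, O, J, `*`) are excluded and tallied:
they cannot be matched by a mass-based search and would only inflate set
sizes. N-terminal methionine is not optionally removed. The
evidence-mapping digest used for novelty flagging uses length 7–30 with
2 missed cleavages.

## Peptidome similarity

Jaccard `|A∩B|/|A∪B|` compares theoretical peptidomes symmetrically
(undefined and an error when both sets are empty). The directional
overlap fraction `|A∩B|/|A|` expresses how much of a sample strain's
peptidome is contained in a reference strain — the right quantity for
misidentification post-mortems — and is intentionally asymmetric, so
the matrix symmetry invariant applies to Jaccard only.
Unique-peptide fractions are computed per taxon (peptides found in no
other set) and globally (fraction of the union private to one taxon).

## Abundance normalization

Relative iBAQ: each protein's iBAQ divided by the per-sample iBAQ total,
log10-transformed, shifted by +10. z-scored iBAQ: per-sample log10 iBAQ
standardized to mean 0 / SD 1 and shifted by +5; the **population** SD
(ddof = 0) is used, which is what makes a two-protein sample map exactly
to {4, 6} and gives the exact per-sample mean-5/SD-1 invariant. iBAQ
zeros are missing data, not true zeros, per standard proteomics
convention; all-zero or zero-variance samples are errors rather than
silently propagated NaNs.

## Orthogroup conservation

Orthogroup (OG) membership is consumed from an OrthoFinder-style table;
an OG must have ≥ 2 member proteins. Its presence vector holds 1 where
at least one member lies in that taxon's reference proteome. For every
clade at ranks domain, phylum, class, order, family and genus with at
least one member among the analyzed taxa, a taxon-specific conservation
array (TSCA) marks clade membership; the all-ones domain TSCA is always
emitted. An OG's conservation class (D/P/C/O/F/G) is the rank of the
TSCA at minimum Hamming distance. Hamming ties are resolved toward the
most general rank, then the lowest clade taxid, so conservation is never
overstated as lineage-specific; the winning clade is reported so users
can see the resolution. (Some summaries of this scheme list five
classes, omitting order; six are implemented.)

Expression-vs-conservation summaries keep OGs with Hamming distance at
or below the 75% quantile within their class — computed over all OGs of
the class, with "higher" quantile interpolation so the cutoff is an
attained value and at least 75% of each class survives — then summarize
paralogs per OG × species by the median z-scored iBAQ and take the
maximum species median as the OG expression level.

The protein-group post-filter (applied before interpreting
marker-protein searches such as antibiotic-resistance panels) removes
decoys, site-only identifications, potential contaminants, groups with
fewer than two peptides, and zero-iBAQ rows, and reports per-criterion
removal counts.

## Synthetic data generator

The generator emulates the hierarchical structure of bacterial
peptidomes, not their biology. An ancestral proteome of random
sequences (K+R frequency ≈ 11.5%, giving mean tryptic peptide length
≈ 12) is mutated down a domain → phylum → genus → species → strain tree
by per-branch substitution; mutated K/R positions keep a
cleavage-competent residue with probability 0.5 so cleavage maps drift
gradually. There are no indels: identification depends only on
peptide-set overlap structure, and substitutions alone control that
structure while keeping digestion oracles simple.

Default divergences (phylum 0.40, genus 0.15, species 0.06, strain
0.015 substitutions/site/branch) were set once from the overlap regimes
observed in real bacterial peptidomes — sibling strains sharing ~70% of
tryptic peptides and within-genus species ~5% — via the survival
approximation `share ≈ exp(−2·L̄·d)` with L̄ ≈ 12. The default
collection (4 phyla × 3 genera × 5 species × 2 strains, 20 proteins of
~250 residues each) keeps index construction and the 200-sample
benchmark inside a few seconds while leaving ~1200–1800 peptides per
strain, enough for the count statistics to behave as they do at scale.

PSM simulation draws `(1−f)·n` signal peptides uniformly from the true
strain's peptide set (hyperscore ~ N(25, 1)) and `f·n` noise peptides
uniformly from the reference index keys (hyperscore ~ N(15, 1)).
Random streams are separated per component, so changing PSM settings
never changes the proteomes.

**What passing benchmarks do and do not show.** They demonstrate the
counting statistic's noise robustness, the decoy-uniformity rationale
and the two-iteration correction mechanism under controlled sharing
structure. They do not demonstrate performance on real spectra: real
noise is not uniform over peptide space (homologous contaminants,
chimeric spectra), real peptide detectability is biased by
physicochemistry, real references contain thousands of taxa with
heavy-tailed sharing (plasmids, horizontal transfer), and the simulator
produces PSM tables directly rather than spectra.

The constructed misidentification scenario places a sample strain's
peptidome closer to a sibling species' representative (Jaccard ≈ 0.33)
than to its own species' heavily diverged representative (≈ 0.06), so
iteration 1 reproducibly picks the sibling species and iteration 2 —
whose genus-wide database contains the sample strain — corrects it.

## Numerical and design choices

- Reference index serialization: gzip text with a JSON magic/version
  header, a JSON manifest line, and sorted peptide/postings lines —
  diffable, streamable, byte-identical for identical inputs.
- Assembly metadata are read through a configurable column map so both
  NCBI `assembly_summary.txt` and hand-built tables work; type-strain
  status is read from an explicit column (non-empty
  `relation_to_type_material`), since metadata sources encode it
  inconsistently.
- "Species name known" is operationalized as ≥ 2 name tokens with the
  second not in {sp., bacterium, uncultured, unidentified}.
- Empty PSM tables, empty proteomes and empty evidence sets are warnings
  with well-defined degenerate outputs; empty indexes, all-zero samples
  and unresolvable taxids are hard errors.
- Contaminant-protein PSMs are mapped like any other PSM; removing them
  is the upstream search's concern.

## Known limitations

- No mixed-culture deconvolution; the argmax statistic assumes one
  dominant organism.
- Exact set semantics only (no suffix automata); memory scales with the
  number of distinct peptides, fine at desk scale but a real
  whole-domain index wants a compressed on-disk layout.
- Whether a reference digest should use 0 or 2 missed cleavages is
  deployment-dependent; both are supported and recorded in the index
  manifest, but results are only comparable across indexes built with
  identical digest parameters.
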