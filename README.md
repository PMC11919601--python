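# proteotyper

Bacterial identification from bottom-up proteomics data by **FDR-free
PSM counting**, with a two-iteration species → strain workflow, plus
companion analytics for tryptic-peptidome similarity, iBAQ abundance
normalization, and orthogroup conservation classes.

## Who this is for

Microbiologists and proteomics bioinformaticians who have LC-MS/MS data
from a pure bacterial isolate (searched with an MSFragger-style engine)
and want to know *which organism it is* — down to the strain — without
maintaining spectral libraries, and researchers studying how protein
conservation and expression relate across bacterial taxa.

## The method

A reference peptidome is built by in-silico tryptic digestion
(trypsin/P, fully tryptic, I/L-collapsed because Ile/Leu are
mass-degenerate) of one quality-checked representative proteome per
species, yielding a mapping *peptide → set of taxa*. The sample's MS2
spectra are searched against this database at **100% FDR** — no
filtering at all — and every peptide-spectrum match (PSM) is mapped onto
the reference:

- a PSM whose peptide occurs in *k* taxa adds **+1 to each** of those
  *k* taxa (once per taxon, regardless of paralogs);
- the identified organism is `argmax_t Σ_PSMs 1[peptide ∈ peptidome(t)]`.

This works because false matches scatter near-uniformly over thousands
of reference taxa — every unrelated species acts as a *decoy* — while
true matches pile up on the correct organism. Skipping FDR control
keeps all true matches even when the search space is enormous.

An optional **second iteration** re-maps the PSMs against all complete
genome strains of the genus identified first (with genus aliasing for
Escherichia/Shigella-like pairs), resolving the isolate to strain level
and correcting first-pass errors that occur when a species'
single representative strain is a poor proxy for the sample. A
mapped-PSM quality-control rule (default: ≥ 500) flags unreliable runs,
optionally triggering a fallback search against an alternate-kingdom
(e.g. fungal) database.

Because a search over hundreds of millions of peptides exceeds typical
search-engine memory, the reference FASTA can be split into chunks
searched independently; chunk results are merged by keeping, per MS2
spectrum, the PSM with the highest hyperscore.

## Worked example

`examples/identify_species_and_strain.py` simulates an isolate (2000
PSMs, 30% noise) against a 60-species synthetic reference and runs both
iterations:

```
iteration 1 (species level, 60 taxa):
  rank 1: Genus19 species29          866 mapped PSMs
  rank 2: Genus19 species23          168 mapped PSMs
  rank 3: Genus19 species26          154 mapped PSMs
  QC: pass; mapped 1506/2000 PSMs
iteration 2 (strains of genus 19, 10 taxa):
  rank 1: Genus19 species29 strain S2       1408 mapped PSMs
  rank 2: Genus19 species29 strain S1        866 mapped PSMs
  rank 3: Genus19 species23 strain S1        168 mapped PSMs
true strain 'Genus19 species29 strain S2' identified: True
```

The numbers tell the whole story: the correct species towers over its
same-genus neighbours (866 vs 168 mapped PSMs), other genera sit at the
noise floor, and the strain-level database — which contains the sample
strain itself — maps nearly all signal PSMs (1408) to the right strain.
The other examples cover peptidome similarity
(`compare_peptidomes.py`) and conservation-class/abundance analytics
(`conservation_and_abundance.py`).

## Command line

```bash
proteotyper build-index --assemblies assembly_summary.txt \
    --nodes nodes.dmp --names names.dmp --level species --out species.idx.gz
proteotyper identify --psm run1.tsv --db species.idx.gz \
    --strain-db genus_561.idx.gz --qc-threshold 500 --out results/
```

`identify` accepts MSFragger-style TSV or pepXML (several `--psm` files
are treated as chunked searches and merged), writes a ranking TSV and a
PDF report per iteration, and exits 0 on QC pass / 3 on QC failure.

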