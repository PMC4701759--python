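# wophage

Spectral-counting analysis of the WO-prophage complement of a *Wolbachia*
proteome.

Arthropod-associated *Wolbachia* genomes carry WO prophages — integrated
phage genomes organized in head / baseplate / tail / replication modules —
and shotgun LC–MS/MS of infected cells can reveal whether those prophages
are expressed.  `wophage` is for researchers who have peptide-evidence
tables from such experiments (or want to simulate them) and need the
downstream analysis: matching peptides onto multi-genome protein databases,
scoring protein abundance, tallying detections by prophage region and
functional class, and comparing syntenic gene arrays between genomes and
plasmids.

## What it computes

**Detection.** Peptides at ≥ 95% confidence are credited to every database
protein containing them as an exact substring; peptides hitting homologs in
several genomes are flagged shared (mosaic detections) and can be collapsed
over homolog groups.  Per (protein, data set) cells report unique-peptide
counts and coverage in the compact `n/cov` notation (`2/5` = 2 peptides,
5% coverage).  A *stringent* filter keeps proteins with ≥ 2 unique peptides
in some single data set; a *relaxed* filter admits single-peptide
detections.  A *refined search* re-scans unmatched peptides against newly
added database entries without ever decreasing existing counts.

**Abundance.** For K MS data sets, a protein's RAL (relative abundance
level) is its mean unique-peptide count over all K sets, zeros included.
Because larger proteins yield more peptides, RAL is size-confounded; the SR
score removes the confound via OLS of log₁₀(count) on log₁₀(mass), optionally
adjusted for functional class and data set:

    log10(count_id) = β0 + β1·log10(mass_i) + class_i + dataset_d + e_id
    t_id = e_id / ( s_(id) · √(1 − h_id) )        (externally studentized)
    SR_i = mean_d t_id

SR = 0 means average abundance for the protein's mass; |SR| is in units of
leave-one-out residual standard deviations.

**Regions.** Locus tags are assigned to prophage regions by inclusive
locus-number ranges (e.g. WOMelB1 = WD0565–0610) and tallied into a
region × class matrix with margins and rounded percentage roll-ups.

**Sequences.** Global/local pairwise identity under BLAST-style scoring
(nucleotide +2/−3, gap 5/2; protein BLOSUM62, gap 11/1; identity counted
over alignment columns including gaps), concatenated syntenic-array
identity, intergenic-gap layout (0 = adjacent, negative = overlap), and a
direct-repeat finder for non-coding regions.

See `docs/methods.md` for the model details, assumptions and limitations.

## Worked example

Simulate a small proteome with known truth, run the full pipeline, and
tally the packaged prophage-proteome roster:

```sh
wophage simulate --seed 1 --n-proteins 60 --out demo/sim
wophage pipeline --db demo/sim/proteome.fasta \
                 --evidence demo/sim/evidence.tsv \
                 --mode relaxed --out demo/run
wophage classify --out demo/cls
```

The pipeline log reports `72 matched proteins, 68 kept (relaxed)` — 60 base
proteins plus 12 homolog variants, of which 4 were never detected.
`demo/run/detection_matrix.tsv` begins:

```
locus_tag  D      E      F      G      total_peptides  coverage_pct
WS0001     10/45  15/69  9/35   13/50  29              85
WS0002     1/4    5/21   3/11   0/0    9               34
```

so WS0001 was seen as 10 unique peptides covering 45% of its sequence in
data set D, 29 distinct peptides overall covering 85%.
`demo/run/abundance_report.tsv` holds one row per protein, e.g.

```
locus_tag  kda   total_peptides  coverage_pct  ral   sr
WM0006     28.1  35              100.0         22.5  1.24
WM0015     17.6  2               21.7          0.5   -1.38
```

WM0006 (22.5 peptides per data set on average) sits 1.24 leave-one-out
standard deviations above the count expected for a 28-kDa protein; WM0015
sits 1.38 below.  Undetected proteins appear with RAL 0 and an empty SR.
`demo/run/model_summary.tsv` shows the fitted log-mass slope (0.71 in this
run).  Finally, `demo/cls/tally.tsv` is the region × class tally of the
packaged roster; its margins put 119 proteins across the MelA/MelB/Pip
regions and orphan categories, with 20 head, 9 baseplate and 10 tail
proteins (33% structural, 16% DNA recombination/replication/modification,
34% unknown function).

Everything is also available as a library:

```python
from wophage import read_fasta, read_evidence, map_peptides
db = read_fasta("demo/sim/proteome.fasta")
matrix = map_peptides(read_evidence("demo/sim/evidence.tsv"), db)
matrix.counts_per_dataset("WS0001")   # [10, 15, 9, 13]
```

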