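# rumenmt

Analysis toolkit for deep metatranscriptome surveys of herbivore-gut
eukaryotes (anaerobic fungi and ciliate protozoa of the rumen), focused on
plant-cell-wall degrading enzymes. It is aimed at microbiologists and
bioinformaticians who have short-read mRNA-seq data from a gut community and
want to go from reads, contigs and search-tool output to carbohydrate-active
enzyme (CAZy) profiles, expression ranks and coverage diagnostics — plus a
synthetic community generator with planted truth so every stage can be
validated without touching external databases.

## What it computes

* **ncRNA filtering.** A read is non-coding RNA iff it has an rRNA-database
  hit with E ≤ 10⁻⁵ and query overlap ≥ 50 bp, or was flagged by an
  rRNA-HMM/tRNA scanner (union of the two routes). From the observed ncRNA
  share *f* and an assumed original ncRNA fraction *c₀* (default 0.95), the
  depletion efficiency is the solution of the retention model with mRNA fully
  retained:  r = 1 − [(1−c₀)·f] / [c₀·(1−f)].
* **Taxonomic binning.** Each query takes the taxon of its best significant
  hit (bit score desc, E-value asc); ties fall to the lowest common ancestor
  of the tied taxa; counts aggregate at any rank with percents over both the
  full universe and the assigned subset.
* **CAZy annotation.** Domain models map to family labels through four
  routes: direct family models (A); a conservative screen that accepts a
  model for a family only when all significant member hits come from that
  family and ≥ 80% of members conform, with combined labels ("CE2/CE3") when
  several families each pass (B); BLAST against representative sequences at
  a 52-bit cutoff (C); and externally built profiles (D). Calls below 52
  bits are dropped, same-label overlaps merge (span union, max score),
  distinct stacked modules (e.g. GH48 + CBM10) survive. Multi-domain
  architecture tallies and top-hit identity bins (<50 / 50–70 / >70 %)
  summarize novelty.
* **Expression and coverage.** Reads per contig, fold coverage
  (reads × mean read length / contig length), ranked reports above a read
  floor, and discovery rates in genes per gigabase.
* **Comparative profiling.** Glycoside-hydrolase family counts per sample are
  row-normalized to percents, compared by Pearson distance d = 1 − r, and
  clustered with UPGMA into an ultrametric dendrogram (newick output).
* **Rarefaction.** Seeded collector's curves of category richness versus
  sequencing effort, with the interpolated effort needed for any richness
  fraction.

## Worked example

Run the full pipeline on a simulated 100,000-read community (2,000 contigs,
18.4% planted ncRNA, zero search noise):

```bash
rumenmt run --seed 7 --outdir demo   # or: rumenmt run --config run.yaml
```

The JSON summary printed at the end (abridged, seed 7):

```json
{
  "n_reads": 100000,
  "ncrna_count": 18055,
  "ncrna_percent": 18.1,
  "gc_percent": {"coding_reads": 37.7, "contigs": 37.8, "ncrna_reads": 50.9},
  "taxon_percents": {"Eukaryota": 91.9, "Bacteria": 7.4, "Archaea": 0.7}
}
```

18,055 reads (18.1%) were classified ncRNA — the planted 18.4% fraction up
to binomial sampling — implying a depletion efficiency of 98.8% under the
retention model. The GC means recover the generator's targets (51% for
ncRNA, ~38% for coding sequence), and the kingdom-level bins mirror the
planted fungal/protozoal community. The CAZy stage calls modules on 180
contigs; of the 9 multi-domain contigs ≥ 500 bp, 100% carry the fungal
dockerin-like CBM10 (planted architectures pair GH6/GH45/GH48 with CBM10),
and the identity bins come out 45.6% / 37.2% / 17.2% (<50 / 50–70 / >70%
identity). The sample's GH profile clusters with the cellulolytic reference
profiles rather than the oligosaccharide-degrading ones:

```
((oligosaccharide_A,oligosaccharide_B),(sample,(cellulolytic_A,cellulolytic_B)));
```

and 80% of gene richness is reached at ~20% of sequencing effort — the
saturating collector's curve expected under heavy-tailed expression.

Per-stage subcommands (`simulate`, `filter-ncrna`, `bin-taxa`,
`annotate-cazy`, `profile`, `cluster`, `rarefy`) operate on the same plain
FASTA/TSV files, so any stage can be fed real search-tool output instead.

## Layout

```
src/rumenmt/
  core_io.py               file formats, taxonomy tree, run config
  synthetic_data.py        community/read/hit-table generator with planted truth
  ncrna_filter.py          ncRNA classification + depletion efficiency
  taxon_binning.py         top-hit / LCA binning, rank aggregation
  cazy_annotation.py       association table, module calls, architectures
  expression_profiler.py   counts, coverage, discovery rates, summaries
  comparative_profiler.py  profile matrix, Pearson distance, UPGMA
  rarefaction.py           collector's curves
  pipeline.py, cli.py      end-to-end orchestration and CLI
```

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
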