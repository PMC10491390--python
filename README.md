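# viromarker

A library and CLI for taxonomic characterisation of viral contigs in
metagenomic assemblies using taxon-informative profile-HMM markers. It
covers the computational core of such a pipeline, exercisable entirely on
synthetic fixtures:

- **Marker calibration** (`viromarker.curation`) — decide at which taxonomic
  rank (genus → subfamily → family → order) a profile HMM is a reliable
  marker, from homology-search hits annotated with source taxa. The winning
  taxon's bit-score range bounds give per-model S1/S2 scores, from which
  GA/TC/NC per-sequence and per-domain thresholds are derived
  (GA_seq = TC_seq = S1; GA_dom = TC_dom = S1 − 3 unless that drops to or
  below S2; NC = S2) and written into HMMER3 model headers.
- **Taxon statistics** (`viromarker.taxon_stats`) — per-taxon mean/SD CDS
  counts from assembly reports, descendant-aggregated marker counts, and
  the taxon-specific ratio TSR = min(1, markers / mean CDS).
- **Contig triage** (`viromarker.triage`) — combine VirSorter-style
  categories, VirFinder-style score/p-value tables and PPR-Meta-style class
  calls into high-confidence / low-confidence / putative-prophage /
  excluded verdicts after a 1.5 kb length filter, with prophage region
  excision.
- **Classification** (`viromarker.classify`) — parse hmmscan per-domain
  tables, gate hits against the calibrated thresholds (E ≤ 1e-3 fallback
  for unthresholded models), collapse to the best hit per CDS, and run a
  rank-escalating vote: a candidate taxon is accepted when its hit
  proportion ≥ 0.6 × TSR and the contig's CDS count ≤ mean + 2 SD for that
  taxon.
- **Benchmarking** (`viromarker.benchmark`) — label contigs truly viral
  when ≥ 70% of their length is covered by reference alignments at ≥ 90%
  identity (nucmer show-coords input), and score predictions with
  precision/recall/F1.
- **Synthetic fixtures** (`viromarker.simulate`) — fully seeded generators
  for every input format above, with planted ground truth, so the whole
  pipeline is testable offline.

## CLI

Each stage is a subcommand of `viromarker`:

```sh
viromarker simulate --seed 5 --out fix                       # fixture bundle
viromarker curate   --hits fix/curation_hits.tsv --taxonomy fix/taxonomy.tsv \
                    --out markers.tsv [--annotate-hmms DIR]
viromarker stats    --assemblies fix/assemblies.tsv --markers markers.tsv \
                    --taxonomy fix/taxonomy.tsv --out stats.tsv
viromarker triage   --fasta fix/contigs.fasta --virsorter fix/virsorter.csv \
                    --virfinder fix/virfinder.tsv --pprmeta fix/pprmeta.csv \
                    --min-len 1500 --out triage_out
viromarker classify --domtbl fix/scan.domtbl --markers markers.tsv \
                    --stats stats.tsv --taxonomy fix/taxonomy.tsv \
                    --cds fix/genes.gff3 --factor 0.6 \
                    [--triage-tsv triage_out/assignments.tsv | --only-annotate] \
                    --out class_out
viromarker bench    --coords fix/alignments.coords --fasta fix/contigs.fasta \
                    --predictions triage_out/assignments.tsv --out bench_out
```

`classify` writes a per-contig classification TSV, a Krona-compatible text
export and a per-CDS annotation table. Taxonomies load either from a
simplified lineage TSV (`taxid name rank parent_taxid`) or from NCBI
`nodes.dmp`/`names.dmp` (`--dialect ncbi-dmp`).

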