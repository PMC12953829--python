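# hgcpipe

Detection, validation, quantification and ecological profiling of putative
mercury-methylation (*hgcA*/*hgcB*) genes across a redox-stratified water
column with free-living (FL) vs particle-associated (PA) size fractions,
plus structural validation of predicted HgcA models by rigid superposition
with iterative outlier pruning.

A seeded synthetic-community generator with planted truth stands in for raw
metagenomes, so every stage of the pipeline can be scored against known
ground truth offline.

## Modules

| Module | What it does |
| --- | --- |
| `hgcpipe.synthetic_community` | Seeded generator of stratified water-column fixtures: carrier genomes with planted cap-helix motifs and tandem *hgcB* partners, universal single-copy marker genes, motif-violating paralog decoys, sub-100-aa fragment decoys, lognormal coverage noise, and a full truth table. |
| `hgcpipe.marker_screen` | The candidate-validation cascade: e-value gate (default 1e-25), cap-helix motif `N(V/I)WC(A/S)(A/G)GK` verification, 100-aa minimum-length filter, redundancy collapse (identical/substring) with one representative per cluster, 50%-identity representative selection, tandem-*hgcB* neighbourhood check, taxonomy assignment. |
| `hgcpipe.abundance` | Length-normalised gene coverage from SAM or a per-gene depth table, genome-equivalent estimation (median single-copy-marker family depth), relative abundance = coverage / genome equivalent x 100%, grouped aggregation. |
| `hgcpipe.ecology` | Depth-zone classification (surface <= 50 m < intermediate <= 100 m < deep), FL/PA labelling from filter pore size (0.22 um / 3 um), log2 PA/FL habitat-preference scores, per-depth and per-taxon profiles, dominant-methylator ranking. |
| `hgcpipe.phylo_annot` | Outgroup rerooting at the separating-edge midpoint (leaf set and path lengths preserved), monophyly tests, per-clade abundance and branch-length summaries, leaf annotation. |
| `hgcpipe.structure_compare` | Calpha pairing from tables or alignments, Kabsch least-squares superposition (proper rotations only), iterative outlier pruning at a 2.0-A cutoff, cap-helix localisation in structures, pLDDT/pTM confidence summaries. |

## CLI

All commands are under a single `hgcpipe` entry point:

```sh
# generate a seeded fixture with planted truth
hgcpipe simulate --out-dir fixture --seed 1 \
    --n-paralog-decoys 50 --n-fragment-decoys 20

# validate hgcA candidates
hgcpipe screen --proteins fixture/proteins.faa --genes fixture/genes.tsv \
    --out screen_out

# relative abundance (depth-table mode; --sam/--sample-id for SAM input)
hgcpipe abundance --depths fixture/depth.tsv --genes fixture/genes.tsv \
    --markers fixture/markers.tsv --validated screen_out.tsv \
    --out abundance.tsv

# depth profiles, taxon summaries, PA/FL preference
hgcpipe ecology --abundance abundance.tsv --metadata fixture/metadata.tsv \
    --out-dir eco

# reroot a gene tree and summarise clades
hgcpipe tree-annotate --tree tree.nwk --outgroup-ids outgroup.txt \
    --clades clades.tsv --abundance abundance.tsv --out-dir treeout

# superpose a predicted model onto a reference with outlier pruning
hgcpipe struct-compare --model model.pdb --reference ref.pdb \
    --cutoff 2.0 --ptm 0.8 --out report.tsv
```

## File formats

All inputs and outputs are plain text: FASTA (contigs, proteins), TSV
(gene table with 1-based inclusive coordinates; per-gene depth table with
one mean-depth column per sample; sample metadata with depth and filter
fraction; marker list), SAM, newick, PDB/mmCIF, JSON (run configuration).
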