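# famscan

Profile-HMM protein family analysis at desk scale: build and calibrate
simplified glocal profile HMMs, harvest significant domains from a
protein database, competitively classify them into families, detect
single- vs bi-domain (fusion) architectures, build neighbor-joining
trees with bootstrap supports and extract seed-anchored subclades, and
scan gene orders for co-clustered family labels. A synthetic-data module
generates ground-truth-labeled inputs for every stage.

## The model

Profiles are single-hit glocal: an alignment traverses every match
column (through match or delete states) while consuming a contiguous
subsequence of the target; residues outside the envelope are emitted by
background flanking states that are exactly score-neutral against the
null model. Match emissions are estimated with Henikoff position-based
sequence weights blended with background pseudocounts; transition
probabilities are fixed, documented constants stored per column in the
serialized model. Scores are bits (log2 odds vs background). E-values
come from a left-censored maximum-likelihood Gumbel fit to Forward
scores of random background sequences.

## CLI

```sh
famscan simulate fixture/ --seed 1        # write a synthetic fixture + config
famscan run fixture/config.yaml           # full pipeline -> report.json

famscan build-profile fam.fasta fam.hmm   # aligned FASTA/Stockholm -> profile
famscan calibrate fam.hmm --seed 1        # add Gumbel E-value parameters
famscan harvest db.fasta fam.hmm          # hits TSV + trimmed-domain FASTA
famscan classify domains.fasta a.hmm b.hmm --taxonomy-tsv tax.tsv
famscan architecture db.fasta ndom.hmm cdom.hmm
famscan nj aln.fasta tree.nwk
famscan bootstrap aln.fasta tree.nwk -B 100 --seed 1
famscan subclade tree.nwk A B --min-support 70
famscan synteny genes.tsv --window-span 7 --min-distinct 2
```

The pipeline config is flat YAML (`famscan simulate` writes a working
example); every parameter has a CLI flag equivalent. Reruns with the
same config and seeds are byte-identical (the timestamped log aside).

## Layout

| module | contents |
| --- | --- |
| `famscan.profile` | profile HMM type, builder, plain-text serialization |
| `famscan.scoring` | Viterbi/Forward bit scores, Gumbel calibration, E-values |
| `famscan.harvest` | database scan, envelope trimming, hits/domain output |
| `famscan.classify` | competitive family assignment, taxon count matrix |
| `famscan.architecture` | N-only / C-only / bi-domain calls |
| `famscan.phylo` | distances, NJ, bootstrap, Newick I/O, subclades |
| `famscan.synteny` | gene-table window scan, GFF3/TSV readers |
| `famscan.simulate` | synthetic families, fusions, decoys, genomes |
| `famscan.workflow` | YAML-configured end-to-end pipeline |
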