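# fpcharter

Unsupervised detection and quantification of transcription-factor (TF) and
nucleosome footprints in **single-molecule footprinting (SMF)** data.

SMF marks accessible cytosines with exogenous methyltransferases and reads
them out by bisulfite sequencing: on each sequenced molecule, an
*unmethylated* cytosine indicates protection by a DNA-bound protein. The
resulting per-molecule binary protection patterns reveal which fraction of a
cell population carries a TF footprint, a positioned nucleosome, or open
chromatin at a *cis*-regulatory element — without any prior annotation of
where those factors bind. `fpcharter` turns a table of single-molecule
methylation calls into a table of footprints with population frequencies.

## Method

For a genomic window (80 bp is a good width for 150 bp paired-end data):

1. **Smoothing** — each molecule's binary protection values
   (protection = 1 − methylated) are smoothed with a rolling mean over a
   centred 40 bp window, evaluated at the observed cytosines.
2. **Clustering** — molecules are compared by Euclidean distance over the
   smoothed in-window signal and partitioned with PAM (k-medoids,
   Kaufman–Rousseeuw BUILD+SWAP). Starting from k = 16, k is reduced one
   step at a time until every cluster holds at least n = 5 molecules, so
   rare noise molecules cannot form their own pattern.
3. **Detection** — per cluster, the mean *raw* protection is computed at
   each cytosine covered by at least half of the cluster's molecules.
   Cytosines with mean protection strictly above 50% are footprinted;
   maximal consecutive runs become footprints classified by width *w*:
   *w* < 5 bp → noise, 5 ≤ *w* ≤ 75 bp → TF, *w* > 120 bp → nucleosome,
   76–120 bp → unclassified. A run touching the edge of the covered
   positions is "unrecognized" (its full width cannot be established).
4. **Aggregation** — TF footprints recurring across clusters merge when
   they reciprocally overlap by ≥ 75% of their widths (transitively, via
   connected components), or when they share a user-supplied motif
   annotation. Each aggregate's frequency is the number of molecules in
   its contributing clusters divided by all molecules in the window.

A seeded simulator (`fpcharter.simulate`) generates call tables from known
occupancy-pattern mixtures with per-call flip noise, so every stage can be
validated against ground truth.

## Worked example

`examples/01_simulate_and_detect.py` simulates 200 molecules from a
30% TF-bound / 70% nucleosome-occupied mixture (5% flip noise) and runs the
full pipeline:

```
simulated 200 molecules; true TF fraction 0.30
chrom	start	end	label	n_molecules	frequency
chrSim	80	226	nucleosome	140	0.700
chrSim	120	136	TF	60	0.300
```

The TF footprint is recovered at the simulated location (truth: protected
121–140, 1-based) with frequency 0.300, and the nucleosome at 0.700 —
matching the mixture weights. Frequencies are population occupancy
estimates: 30% of molecules sit in clusters exhibiting the TF footprint.
The other `examples/*.py` scripts walk through width classification, motif
aggregation, and the cluster-size floor.

## Command line

```sh
fpcharter simulate --spec spec.json --out calls.tsv --truth truth.tsv
fpcharter run --calls calls.tsv --regions regions.bed [--motifs motifs.bed] --out prefix
```

`run` writes `<prefix>.footprints.tsv` (+ companion BED6),
`<prefix>.clusters.tsv` (per-molecule assignments), `<prefix>.profiles.tsv`
(per-cluster mean protection, for plotting) and `<prefix>.log`. All
algorithm parameters are flags with the defaults above.

## Input format

Calls are a flat TSV with columns `molecule_id`, `chrom`, `pos` (1-based
cytosine coordinate) and `methylated` (1 = methylated = accessible,
0 = protected), trivially produced from any methylation extractor. Regions
and motifs are BED (0-based half-open); the output table uses BED
coordinates too.

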