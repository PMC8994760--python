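# herbaudit

Multi-barcode (ITS2 / trnL) amplicon audit of herbal-mixture composition.

Given amplicon reads, per-read alignment hits, and a prescription definition
(the mapping of each prescribed herbal material, PHM, to its accepted source
species, PHS), `herbaudit` runs the full audit:

1. **read_qc** — demultiplex dual 7-bp MID tags (zero mismatches), excise
   primers (IUPAC-aware), and filter reads by barcode-specific length bounds
   (ITS2: 150–510 bp, trnL: ≥ 75 bp), rolling 5-bp window mean quality ≥ 20,
   no ambiguous bases, no homopolymer runs > 8.
2. **taxonomy** — one species call per read from 12-column tabular alignment
   hits (e-value ≤ 1e-10): the highest-scoring *prescribed* species wins if
   any hit is prescribed, otherwise the overall top-scoring species.
3. **abundance** — sample × species count tables, per-sample relative-
   abundance thresholds (ITS2: 0.002, trnL: 0.001, strictly-below removed),
   and rarefaction curves by exact subsampling without replacement.
4. **audit** — classify each detected species as PHS (prescribed), SHS (same
   genus as a PHS), or CHS (neither); pool detected PHS over samples, map
   them to materials, and report sensitivity = 100 × detected PHMs / total
   PHMs (half-up, one decimal). Reports from several barcodes merge by set
   union.
5. **compare** — Euclidean distances on PHS presence profiles, hierarchical
   clustering (newick output), distance-cutoff networks (ITS2: 5.0,
   trnL: 4.2), and deterministic PCA.
6. **biomarker** — group-discriminating marker screening (Kruskal–Wallis +
   effect size, a simplified single-factor LEfSe-style screen), greedy
   mutual-information mRMR ranking, the MEI abundance-ratio score, and
   ROC/AUC evaluation with pruning of markers whose single-marker AUC < 0.5.
7. **synthetic** — congener-structured reference databases, read and
   hit-table simulation with ground-truth manifests, so the whole pipeline
   is testable hermetically.

Bundled under `herbaudit/data` are prescription definitions for four
marketed preparations (BYW, DHW, NJW, YGW) and species-level detection
matrices recorded for NJW and DHW under each barcode, used as validation
fixtures (`herbaudit.datasets`).

## CLI

One subcommand per stage plus `run-all`:

```bash
# hermetic demo dataset with ground truth
herbaudit simulate --preset demo --seed 42 --out-dir demo/

# individual stages
herbaudit qc --barcode its2 --mids demo/mids_ITS2.tsv \
    --reads demo/reads_ITS2.fastq --out-dir demo/qc
herbaudit assign --hits demo/hits_ITS2.tsv --rx demo/prescription.json \
    --out demo/counts.tsv
herbaudit abundance --counts demo/counts.tsv --barcode its2 --out demo/filtered.tsv
herbaudit audit --tables ITS2 demo/filtered.tsv --rx demo/prescription.json \
    --out demo/report.json
herbaudit compare --presence run/ITS2/presence.tsv --cutoff 5.0 --out-dir cmp/
herbaudit biomarker --table table.tsv --labels labels.tsv --k 5 --out-dir bm/

# or everything from a YAML config
herbaudit run-all --config run.yaml
```

A `run-all` config lists the prescription, an output directory, and per
barcode the reads FASTQ, the MID/primer sheet, and the hit table; thresholds
default to the protocol values and every threshold actually applied is
recorded in `run_report.json` together with a checksum per output (reruns
with the same config and seed are bit-identical).

## File formats

Prescriptions: TSV (`preparation, phm, phs` semicolon list`, processed`) or
JSON. Reads: FASTQ (Phred+33, gzip-transparent). Hits: 12-column tabular
local-alignment format (`-outfmt 6`), optional subject→species sidecar TSV.
Tables: TSV. Dendrograms: newick. Edge lists: TSV importable by network
visualization tools.
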