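# svaduplicon

Structural-inference toolkit for retroelement-mediated segmental
duplication (SD). It implements, as a tested reusable pipeline, the
analyses needed to characterize how composite retrotransposons mobilize a
core duplicon:

- **TSD / junction / breakpoint analysis** — target-site duplication
  detection around insertions, junction typing (microhomology /
  inserted nucleotides / complex), single-linkage breakpoint clustering,
  and a repeat-overlap census of independent breakpoints.
- **Phylogenetic recombination testing** — K2P distances, neighbor
  joining with column-resampling bootstrap, Robinson–Foulds comparison,
  diagnostic-site partitioning against an outgroup, recombination-interval
  bracketing, the 5′/3′ split-tree incongruence test, and a
  downstream-segment gene-conversion control.
- **Median-joining haplotype networks** with equal site weights, median
  (Steiner) node inference, and external rooting.
- **Subfamily chimera detection** — diagnostic-site segmentation of
  elements, switch-point localization, and the circular-intermediate
  integration signature (reciprocal chimeras with swapped inner/outer TSD
  association).
- **Direct-repeat flank scanning** — a windowed genome scan for SDs
  flanked by large (≥1 kb, ≥90% identity) same-orientation repeats, with
  junction typing and NAHR-deletion-product prediction.
- **A synthetic-genome simulator** that plants every one of these
  structures with exact coordinates in a machine-readable truth ledger,
  so the whole pipeline is testable end to end without external data.

## Command line

All functionality is exposed through one entry point:

```bash
svaduplicon demo-config demo.toml          # write the bundled demo config
svaduplicon report --config demo.toml --out run/
```

`report` runs the full pipeline (simulate → annotate → detect → score)
and writes a result bundle: genome FASTA, RepeatMasker-style `.out` +
BED6 annotations, truth ledger JSON, per-detector TSV/JSON outputs,
breakpoint censuses, a recovery scorecard, and a replayable manifest.
Two runs of the same config produce byte-identical bundles.

Individual stages:

```bash
svaduplicon simulate  --config cfg.toml --out sim/
svaduplicon annotate  --genome g.fa --rm-out rm.out --out annots.bed
svaduplicon tsd       --genome g.fa --annotations rm.out --out tsd.tsv
svaduplicon junctions --copies copies.tsv --annotations ancestral.out --out-prefix j
svaduplicon recomb    --alignment aln.fa --groups groups.tsv --outgroup OUT \
                      --bootstrap 1000 --out-prefix rec
svaduplicon network   --alignment haps.fa --outgroup og --out-prefix net
svaduplicon chimera   --genome g.fa --annotations rm.out --library lib.json --out chim.tsv
svaduplicon circle    --genome g.fa --annotations rm.out --library lib.json --out circ.json
svaduplicon flankscan --genome g.fa --min-len 1000 --min-identity 0.9 --out-prefix hits
svaduplicon score     --calls calls.json --ledger truth.json --out score.json
```

Exit codes: 0 success, 2 validation error, 3 runtime error.

## Library API sketch

```python
from svaduplicon import synthetic_genome as sg
from svaduplicon.pipeline import run_detectors, score_recovery

conf = sg.SimulationConfig(seed=1, n_l1_insertions=20, n_duplication_copies=30,
                           n_circular_cassettes=2, n_direct_repeat_sds=4,
                           n_bp5_clusters=9, n_bp3_clusters=9,
                           n_contigs=4, contig_length=650_000,
                           tsd_length_range=(8, 16))
res = sg.simulate(conf)                      # genome + truth ledger
det = run_detectors(res.contigs, res.annotations, res.library,
                    ancestral_annotations=res.ancestral_annotations)
print(score_recovery(det["calls"], res.ledger).per_type)
```

Internal coordinates are 0-based half-open everywhere; 1-based formats
(RepeatMasker `.out`, consensus positions) are converted at the I/O
boundary.
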