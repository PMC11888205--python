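# enhancerkit

Tools for mapping the histone-mark enhancer landscape of a tissue from
ChIP-seq peak intervals, linking regulatory elements to genes, and calling
CRISPRa Perturb-seq activation — the kind of multi-omic integration used to
chart putative enhancers in term-pregnant human myometrium and to dissect
cis-acting elements of individual genes such as *PLCL2*.

## What it computes

Given per-sample peak intervals (BED) for H3K27ac and H3K4me1, gene models,
expression tables, TF-occupancy peaks, chromatin loops (BEDPE) and a
Perturb-seq count matrix, the package provides:

- **Putative enhancers** — regions carrying both marks in a sample: the
  union of H3K27ac and H3K4me1 peaks is merged and regions overlapped by at
  least one peak of each mark are kept ("double positive").
- **Super enhancers** — H3K27ac peaks stitched whenever they lie within
  12.5 kb of each other (`bedtools merge -d` semantics); stitched spans
  strictly larger than 15 kb are super enhancers. The rule is purely
  geometric; no signal ranking is involved.
- **Consensus sets** — union-merged regions supported by peaks in a
  required number of samples (default: all), plus Venn-style support
  partitions and per-sample shared fractions.
- **Gene linking** — RNA-seq counts scaled to a reference depth of
  56.5 million mapped pairs; active genes (FPKM ≥ 1, or mean normalized
  count > 1); expression strata (inactive < 1 ≤ low < 5 ≤ mid < 15 ≤ high,
  in FPKM); association of every element with every gene whose TSS lies
  within 100 kb; per-stratum association fractions; TF-occupancy
  colocalization percentages.
- **Loop-scoped candidates** — for a gene of interest, peaks falling inside
  chromatin loops that have one anchor on the gene's TSS.
- **Perturb-seq activation calls** — cells with exactly one detected gRNA
  are grouped by gRNA; a known target is "activated" when the gRNA group's
  mean expression exceeds the scramble-control group's by a fold change
  > 1.5; discovery mode adds a per-gene two-sided rank-sum test with
  Benjamini–Hochberg FDR and calls genes with FC > 1.5 and adjusted
  p < 0.05.
- **Synthetic data** — seeded generators for every input above with planted
  ground truth, so the whole pipeline is testable without downloads.

Coordinates are 0-based half-open (BED convention) throughout; "overlap"
means at least one shared base pair.

## Worked example

```python
from enhancerkit import (SimulationConfig, simulate_to_dir,
                         PipelineConfig, run_pipeline)

simulate_to_dir(SimulationConfig(seed=1), "sim")        # synthetic inputs
cfg = PipelineConfig.from_sim_dir("sim", out_dir="out") # thresholds: paper-style defaults
report = run_pipeline(cfg)
print(report.n_consensus_super_enhancers)  # 50  (all planted clusters recovered)
print(round(report.coloc_se_pct, 1))       # 84.0 (planted probability 0.76, 50 SEs)
print(report.grna_fractions)               # {'none': 0.1635, 'single': 0.568, 'multi': 0.2685}
print(round(report.activity_expression_r, 2))  # 0.56 (planted rho 0.47, n = 43)
```

The same stages run from the shell:

```bash
enhancerkit simulate --seed 1 --out sim
enhancerkit call-superenhancers --k27 sim/sample1_H3K27ac.bed --out se.bed
enhancerkit consensus sim/sample*_H3K27ac.bed --out common.bed
enhancerkit report --sim-dir sim --out out
```

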