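# splicexport

Quantification pipeline for the cellular phenotypes of defective mRNA
splicing and nuclear export, built for analyses of splicing/export factors
(e.g. THRAP3/BCLAF1 knockdowns) where the readouts are:

* **nuclear/cytoplasmic RNA-FISH ratios** — per cell, the mean fluorescent
  signal inside a 2-px-eroded nuclear mask divided by the mean inside a
  30-px cytoplasmic ring (2-px gap) around the nucleus; nuclear retention
  of poly(A) RNA raises the ratio;
* **DNA-repair foci** — per-nucleus γ-H2AX/53BP1 spot counts and the
  fraction of cells with ≥ 5 foci;
* **splicing-reporter ratios** — per-cell GFP/RFP intensity ratios from a
  two-channel reporter whose test intron truncates translation when
  unspliced;
* **qPCR splicing/export indices** — in-run standard-curve relative
  quantification (efficiency 10^(−1/slope)), ACTB normalization,
  pre-spliced (exon–intron) vs post-spliced (exon–exon) transcript levels,
  nuclear/cytoplasmic ratios, MALAT1 fractionation-purity and RT-minus
  contamination QC;
* **target-gene set arithmetic** — per-gene cytoplasmic fold-change +
  two-tailed t-test, Benjamini–Hochberg FDR, the "down > 1.5-fold at
  FDR < 0.01" filter, and overlap reports (intersection as % of union);
* **3′-UTR motif enrichment** — exhaustive k-mer over-representation
  (widths 8–20) against an order-0 background with a log-space binomial
  tail and Bonferroni correction;
* **CDS variant arithmetic** — 1-based coding-position → codon mapping and
  nonsense-truncation calls (e.g. C301>T → R101*, C2509>T → R837*);
* **condition statistics** — mean ± SEM, Student/Welch two-tailed t-tests,
  the */**/*** star convention, clonogenic surviving fractions normalized
  to plating efficiency.

No raw experimental data ships with the package. Instead,
`splicexport.synthetic_data` generates every input with recorded ground
truth — seeded fluorescence fields with known per-cell ratios and focus
counts, expression tables with planted down-regulated gene sets, UTR sets
with a planted consensus motif, Cq tables from a known log-linear curve —
so every stage is tested end-to-end against known answers.

## Worked example

```python
from splicexport import synthetic_data as sd, image_quant as iq

spec = sd.FishImageSpec(n_cells=50, true_nc_ratio=2.0, noise_sd=20.0, seed=1)
frame, truth = sd.generate_fish_image(spec)

labels = iq.segment_nuclei(frame["dapi"], min_area_px=100)
pairs = iq.build_region_pairs(labels, erosion_px=2, ring_gap_px=2, ring_width_px=30)
cells = iq.measure_nc_ratio(frame["signal"], pairs)
kept = cells.loc[cells["included"], "nc_ratio"]
print(f"{kept.mean():.4f} +/- {kept.sem():.4f} over {len(kept)} cells")
```

prints

```
1.9999 +/- 0.0004 over 50 cells
```

i.e. with segmentation in the loop and Gaussian noise at 5% of the
cytoplasmic signal, the measured mean N/C ratio recovers the planted value
2.0 to 0.01%. The same flow runs from the shell:

```sh
splicexport simulate fish --seed 1 --out sim/
splicexport quantify ncr --dapi sim/fish.tif --signal sim/fish.tif --out quant/
```

The numbered scripts under `analysis/` run the full story — simulate
inputs, quantify images, build target-gene sets and their overlap report,
scan UTRs for the planted motif, derive qPCR indices, annotate the
truncating variants:

```sh
python analysis/01_simulate_inputs.py   # writes results/inputs/
python analysis/02_quantify_images.py   # ... and so on through 06
```

Each prints what it found (e.g. the motif scan reports the top hit
`GGAGGCTGGGGC` in 200/200 sequences and zero significant k-mers on the
null set) and writes its tables under `results/`.

## Layout

```
src/splicexport/     library: synthetic_data, image_quant, transcript_sets,
                     motif_scan, qpcr_quant, cds_annot, stats_report,
                     cli_io (config + readers/writers + pipeline runner), cli
analysis/            numbered narrative drivers writing under results/
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      model, assumptions, parameter defaults, limitations
```

Conventions: 0-based (row, col) pixel coordinates; 1-based CDS
coordinates; images/masks as multi-page TIFF; tables as tidy CSV;
sequences as FASTA; configuration as YAML (`PipelineConfig`, unknown keys
rejected); reports as JSON. See `docs/methods.md` for the full model
description and design rationale.
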