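# eplink

Predict stimulation-dependent enhancer–promoter interactions from ChIP-seq
time-course occupancy.

`eplink` implements a Naive Bayes classifier whose features are (i) the
Pearson correlation of per-timepoint ChIP-seq occupancy between a distal
enhancer and a promoter-extended gene, one correlation per assay (estrogen
receptor, RNA polymerase II as the average of two replicates, H2AZ,
H3K4me3), and (ii) the log10 genomic separation between the enhancer centre
and the promoter-shifted TSS. Class-conditional feature densities are 1-D
Gaussian KDEs — leave-one-chromosome-out cross-validated bandwidths for the
(small) interacting class and Scott's rule `σ̂·n^(−1/5)` for the (large)
background class. For each enhancer the model assumes a single target among
its K same-chromosome candidate genes with a uniform structure prior, which
makes the posterior over candidates a softmax of per-pair log density
ratios. Derived outputs are the maximum-a-posteriori target per enhancer and
a per-gene regulation score `1 − Π(1 − posterior)`.

The surrounding pipeline is included: merging per-timepoint peak calls into
time-persistent consensus enhancers (union of overlap-connected components
supported by ≥ 2 post-stimulation timepoints, restricted to intergenic
regions), read counting and depth normalisation to t = 0, the minimum-30-read
coverage filter, labelling against interaction anchor pairs (BEDPE),
odd/even-chromosome train/test evaluation (precision at fixed recall, FDR
posterior cutoffs, MAP accuracy, TAD stratification, DE-gene validation
curves), and a fully self-contained synthetic benchmark generator with
planted links.

## Command-line pipeline

All stages share one working directory; each refuses to run before its
upstream stage and reuses existing outputs unless `--force`:

```sh
eplink simulate  --workdir run --seed 1          # synthetic bundle
eplink consensus --workdir run                   # persistent distal enhancers
eplink counts    --workdir run                   # count + filter + normalise
eplink features  --workdir run                   # pair features + labels
eplink train     --workdir run                   # KDE densities (odd chroms)
eplink predict   --workdir run --features ER,PolII,dist
eplink evaluate  --workdir run                   # eval.json incl. TAD strata
```

`simulate` accepts a YAML config (`--config`) overriding any
`eplink.synthetic.SynthConfig` field. Real data can be substituted by laying
out the same files the simulator writes (`manifest.json`, per-timepoint peak
BEDs, per-assay read BEDs with library sizes, `genes.tsv`,
`observed_links.bedpe`, `tads.bed`).

## Library use

```python
from eplink.synthetic import acceptance_config, generate
from eplink.pipeline import run_bundle, truth_recovery_report

bundle = generate(acceptance_config(seed=1))
result = run_bundle(bundle)                       # all five features
report = truth_recovery_report(bundle, result,
                               chroms=result.split.test_chroms)
print(report["map_accuracy"], report["precision_at_tpr"])
```

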