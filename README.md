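# polprof

RNA polymerase II occupancy profiling around genomic anchors, for
regulatory-genomics analyses of ChIP-seq-style data: binned
fold-enrichment-over-input metagene profiles (TSS, TES, peak-summit and
scaled gene-body anchors), between-condition window tests,
promoter-proximal pausing indices, gene-set overlap and promoter-motif
statistics, and phosphoproteomics candidate triage.  A synthetic-data
generator plants occupancy, expression and phosphorylation effects with
recorded ground truth, so every stage of the pipeline can be validated
end to end.

The package is aimed at analyses of the kind used to dissect transcription
regulation in model organisms — e.g. asking whether loss of a co-factor
impairs polymerase *recruitment* at a set of co-activated genes while
leaving promoter-proximal *pausing* untouched, and triaging phosphatase
substrate candidates from phosphopeptide intensities.

## The quantities it computes

* **Bin density** of extended fragments: `count x 10^9 / (bin_bp x
  total_mapped)` (reads per kb per million mapped), in 60 bp bins around an
  anchor or in 1%-of-gene-length bins across gene bodies.
* **Fold enrichment over input** per bin: `(mean IP density + eps) /
  (mean input density + eps)`, set-mean by default.
* **Window test**: two-sided t-test of the per-bin enrichment values in a
  window (default -600..+600 bp; 20 bins), paired across bins, between two
  conditions.
* **Pausing index** per gene: mean normalized ratio-track coverage over a
  pausing region divided by the gene-body mean, under a *relaxed*
  (-500..+500 from the TSS) and a *stringent* (TSS..+500) region
  definition; set values are means of per-gene ratios.
* **Gene-set statistics**: FDR-cut regulated sets, suppression fractions
  under an RNAi, exact one-sided hypergeometric overlap tests, and IUPAC
  promoter-motif enrichment (TATA = TATAWAWR in [-100, 0) by default).
* **Phospho triage**: total-signal normalization, moderated-t differential
  phosphorylation with Benjamini-Hochberg control, and per-protein
  candidate ranking combined with reporter-screen and co-purification
  evidence.

See `docs/methods.md` for the models, conventions and caveats.

## Worked example

Simulate the default two-condition study (200 genes on 1.2 Mb, 50
"co-activated" genes whose upstream recruitment component is halved in
condition B, 2x10^5 fragments per library), profile both conditions around
the TSS, and test the co-activated set:

```python
from polprof import SimulationConfig
from polprof.workflows import run_occupancy_experiment

exp = run_occupancy_experiment(SimulationConfig(), seed=4)
print(f"co-activated set: p = {exp.p_affected:.4f}")
print(f"unaffected set:   p = {exp.p_control:.4f}")
print(f"stringent pausing index A = {exp.pausing_a.set_stringent:.2f}, "
      f"B = {exp.pausing_b.set_stringent:.2f}")
```

prints

```
co-activated set: p = 0.0036
unaffected set:   p = 0.1035
stringent pausing index A = 7.04, B = 6.66
```

— the planted recruitment defect is detected at the co-activated genes
(p < 0.01), the unaffected control set is not flagged, and the pausing
index barely moves (the defect is in recruitment, not pause release).  The
same analysis runs from the shell:

```bash
polprof simulate --outdir sim --seed 3
polprof profile --reads sim/B_ip.sam --input sim/B_input.sam \
    --genes sim/genes.bed --anchor tss --out profB.tsv
polprof compare --a profA.tsv --b profB.tsv      # window=-600:600  t=-2.97  p=0.0078
polprof pausing --ip sim/A_ip.sam --input sim/A_input.sam \
    --genes sim/genes.gff3 --out pausing.tsv
```

`polprof genesets`, `polprof motif` and `polprof phospho` cover the
expression-table, promoter-motif and phosphoproteomics stages.

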