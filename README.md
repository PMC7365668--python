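# drgpop

Population-coding analysis of in vivo calcium imaging from dorsal root
ganglion (DRG) sensory neurons under graded mechanical stimulation.

## The problem

When a limb is compressed, how does the nervous system encode "how hard"?
Two candidate codes exist: *frequency coding* (each afferent fires faster)
and *population coding* (more afferents are recruited). In vivo GCaMP6s
imaging of DRG somata makes the population-level answer measurable: hundreds
of sensory neurons are recorded simultaneously while a pressure cuff is
inflated in 50 mm Hg steps every 10 s from 0 to 400 mm Hg, or while the limb
is moved through five extension–flexion pairs. In cancer-induced bone pain
(CIBP), the number of mechanically responsive neurons rises severalfold —
a signature of population coding driven by the recruitment (likely
"unsilencing") of previously mechanoinsensitive nociceptors.

`drgpop` implements the full analysis chain for such recordings, for
experimentalists who have per-cell fluorescence traces (CSV) or image stacks
with ROI tables (TIFF), plus a synthetic-population generator with complete
ground truth so that every stage of the pipeline is testable without any
recording.

## The method

1. **Normalization.** Per cell, ΔF/F(t) = 100·(F(t) − F₀)/F₀ with F₀ the
   mean fluorescence over a pre-stimulus baseline window; background signal
   is subtracted first when traces come from ROI extraction.
2. **Responder classification.** A cell responds to a stimulation epoch
   when its epoch-mean ΔF/F ≥ 70% + 4·SD, where SD is the baseline
   standard deviation of ΔF/F (inclusive comparison). Responder fractions
   are binary counts over *all* imaged cells.
3. **Size stratification.** Soma areas split at 700 and 1200 µm² into
   small / medium / large classes; sizes are analysed for responders only.
4. **Unsupervised response classes.** Epoch-averaged ΔF/F vectors of
   responders are correlated pairwise (Pearson); r > 0.9 draws an
   unweighted edge; the graph is clustered with a from-scratch Markov
   Cluster algorithm (preinflation 1.8, inflation 1.8, minimum cluster
   size 5); near-identical clusters (centroid r > 0.95) are merged and each
   cluster is labelled by its centroid shape: `Low`, `Mid`, `High`, `Ramp`
   for compression; `Extension`, `Flexion`, `Const` for movement.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate a sham and a CIBP population (300 cells each) under the pressure
ramp, run the whole pipeline, and report:

```python
from drgpop import RunConfig, run_pipeline

cfg = RunConfig.default_two_group("pressure_ramp", n_cells=300, seed=1)
report = run_pipeline(cfg, "out/demo")
print("step counts:", report.step_counts)
print("clusters:", {r["cluster_id"]: (r["label"], r["size"]) for r in report.cluster_table})
print("sham P400 fraction: %.3f" % report.curves["sham"]["fraction"][-1])
print("CIBP P400 fraction: %.3f" % report.curves["CIBP"]["fraction"][-1])
fc = report.fold_change["P400"]
print("fold change at P400: %.2f (95%% CI %.2f-%.2f)" % (fc["ratio"], fc["ci_low"], fc["ci_high"]))
```

prints (numbers from an actual run):

```
step counts: {'simulate': 600, 'dff': 600, 'classify': 600, 'responders': 71, 'graph': 71, 'clustered': 71}
clusters: {'C1': ('Ramp', 29), 'C2': ('High', 16), 'C3': ('Mid', 15), 'C4': ('Low', 11)}
sham P400 fraction: 0.037
CIBP P400 fraction: 0.113
fold change at P400: 3.09 (95% CI 1.69-7.80)
```

Of 600 simulated cells, 71 were classified as responders, all entered the
correlation graph, and the Markov clustering recovered the four canonical
compression classes. At maximal compression 11.3% of CIBP cells respond
versus 3.7% of sham cells — a ~3-fold recruitment, with a bootstrap CI over
cells. Every number in the report is backed by a CSV written in the output
directory.

The same is available from the shell:

```bash
drgpop run-all --kind pressure_ramp --n-cells 300 --seed 1 --out out/demo
drgpop simulate --kind pressure_ramp --group cibp --n-cells 200 --seed 7 \
    --out out/sim --render-tiff   # also writes a TIFF stack + ROI table
```

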