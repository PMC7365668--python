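# Methods

## Scope and design

`drgpop` analyses population calcium-imaging recordings of DRG sensory
neurons under three mechanical stimulation protocols: a graded pressure-cuff
ramp (eight 10 s steps, 50→400 mm Hg), five extension–flexion limb-movement
pairs, and dynamic brushing. The package couples the analysis chain
(ΔF/F → responder classification → size stratification → correlation-graph
clustering) to a forward model of the same experiments, so every stage can
be validated against known ground truth.

## Stimulus protocols

A protocol is an ordered list of labelled epochs over a recording, with one
pre-stimulus `baseline` epoch first. Frame *k* at sampling rate *f* (2–4 Hz,
the realistic range for full-frame confocal acquisition) is timestamped
*k/f*; a frame belongs to an epoch when its timestamp lies in the half-open
window `[start, end)` — half-open so that no frame is double-counted at
epoch boundaries. Epoch starts align to frame boundaries (the alignment of
stimulus onset to the frame clock is not otherwise constrained, so the
simplest deterministic convention is used).

Defaults: 20 s baseline (several indicator time constants, enough to
estimate the baseline SD stably; configurable), 10 s per pressure step,
5 s per movement event with 5 s rest gaps between events (event timing is a
package choice, exposed in `make_protocol`). The brush protocol exists as a
protocol kind, but the generator defines no brush-tuned archetypes: brushing
recruits few cells and shows no group difference, so there is no class
structure worth emulating.

## The forward model

A cell is assigned a response **archetype** — a deterministic tuning curve
mapping epoch identity to a drive in [0, 1]:

| archetype | modality | functional form | peak |
|---|---|---|---|
| Low | pressure | difference of logistics (centres 30/90 mm Hg) | ≤ 100 mm Hg |
| Mid | pressure | Gaussian, centre 200 mm Hg, σ = 60 mm Hg | 200 mm Hg |
| High | pressure | logistic (centre 325 mm Hg), exactly 0 ≤ 250 mm Hg | 400 mm Hg |
| Ramp | pressure | affine through the origin | 400 mm Hg |
| Extension / Flexion | movement | indicator of event type × adaptation | first event |
| Const | movement | adaptation only (responds to every event) | first event |
| NonResponder | — | identically zero | — |

Pressure drives are normalized to max 1 over the eight cuff steps. The
functional forms are the package's own concrete realisation of the verbal
class descriptions (low-pressure-tuned, mid-peak, high-threshold, linearly
graded); they are what gives the generator distinct, recoverable classes.
Movement drives decay geometrically across the ten events (factor 0.97 per
event). This mild adaptation matters: it gives "Const" cells a shared
non-flat profile, without which their epoch-feature vectors would be
zero-variance (Pearson correlation undefined) and the class could never
form a graph community.

The fluorescence model is

```
dff(t)  = [per-frame drive × amplitude] ⊛ k(t),   k ∝ e^(−t/τ_decay) − e^(−t/τ_rise)
F(t)    = F_base · (1 + dff(t)/100) + ε(t),       ε ~ N(0, (noise_sd·F_base/100)²) i.i.d.
```

with the kernel normalized to unit area, so a sustained epoch saturates at
the drive amplitude (within ~0.5% by the end of a 10 s epoch given
τ_decay ≤ 2 s). Kinetics default to τ_rise = 0.2 s, τ_decay = 1.8 s —
literature-typical GCaMP6s values, configurable. The slow decay produces
the realistic carry-over of signal from one pressure step into the next.
Per-cell response amplitudes are log-normal (median 150% ΔF/F, σ = 0.2) and
per-frame noise defaults to 5% ΔF/F, so the 70%+4SD criterion is
non-trivially exercised: a minority of genuine responders fall below
threshold at their weaker epochs, exactly as in real data. Not modelled:
photobleaching, motion drift (assumed corrected at acquisition), indicator
saturation, and spike-level dynamics (drive is epoch-level).

Population structure: the number of responders is `round(n · prevalence)`
and archetype counts among responders follow the mixture by
largest-remainder rounding, so realized counts match configured proportions
to within one cell. Default prevalences encode the study conditions the
package is built around: knee compression 6% (sham) vs 18% (CIBP) — a
three-fold recruitment — and movement 20% vs 40%. Default group mixtures
reflect the relative class abundances in the two conditions (sham
Low/Mid/High/Ramp = .27/.08/.19/.46; CIBP = .13/.24/.25/.38 — Mid strongly
enriched, Low depleted in CIBP); a pooled mixture (.15/.22/.24/.39) is used
for responder-only populations, and movement classes default to
Extension/Flexion/Const = .35/.35/.30. Soma areas are log-normal (σ = 0.4)
with archetype-specific medians (Low 900 µm², Mid 450 µm², otherwise
600 µm²), reproducing the observation that newly recruited mid-pressure
responders are small-diameter cells; optional truncation bounds let tests
construct populations confined to one size class.

Rendering: cells are drawn as non-overlapping discs in a 512×512 field at
2 µm/px (a 700 µm² soma ≈ 15 px across, plausible for a 10× objective);
disc pixels carry the raw trace value, frames are quantized to uint16, and
a reserved cell-free disc provides the background ROI. A pixel belongs to a
disc when its centre is within the radius — the same rule used by ROI
extraction, so render→extract round-trips are exact up to quantization.

## Responder criterion

Threshold = 70 (% ΔF/F) + 4 × SD of baseline ΔF/F, compared inclusively
(≥) against the epoch-mean ΔF/F of each stimulation epoch. Two readings of
the criterion are implemented: the additive default (`criterion="sum"`) and
a conjunctive variant (`criterion="and"`, epoch mean ≥ 70 *and* ≥ 4 SD);
whether the SD enters additively, and whether it is taken over raw F or
ΔF/F, are genuinely underdetermined — the package computes SD on ΔF/F so
that the two summands share units. Cells whose baseline mean F₀ ≤ 0 after
background subtraction are excluded and logged rather than clipped:
dividing by a non-positive baseline is meaningless.

Soma-size boundaries: the verbal limits "<700" and ">700 <1200" µm² leave
the boundary values unassigned; the package uses half-open classes
[0, 700), [700, 1200), [1200, ∞) so every cell is classified.

## Graph clustering

Responder feature vectors (one epoch-mean ΔF/F per stimulation epoch) are
correlated pairwise; r > 0.9 (strict, signed — anticorrelation never links
cells) draws an unweighted edge, and cells with no supra-threshold edge
leave the analysis. Zero-variance vectors are excluded (Pearson undefined)
with a log entry.

The Markov Cluster algorithm is implemented from scratch on dense matrices:
self-loops of weight 1, column normalization, one inflation pass with the
preinflation exponent (1.8), then iterated expansion (M ← M·M) and
inflation (1.8) with entries below `prune_eps = 1e-6` zeroed, until the
largest entry change < 1e-9 (max 200 iterations; non-convergence returns
the current interpretation with a warning flag, never silently). Clusters
are read off the converged matrix by the attractor interpretation: nodes
with positive diagonal mass are attractors, mutually-flowing attractors
form a system, and each node joins the system it sends flow to; the rare
node reaching several systems is assigned to the larger cluster (ties to
the lower cluster index). A support floor of 1e-8 distinguishes true zero
flow from the denormal-scale residue that geometric decay leaves behind
when pruning is disabled. The minimum-cluster-size parameter (default 5)
dissolves smaller clusters into an "unclustered" pool. The original MCL
software's resource schemes are speed approximations and are deliberately
not reproduced; at the scale of hundreds of responders, exact expansion is
cheap.

Because graph communities can split one biological class, clusters whose
centroids are near-identical in shape (Pearson r > 0.95, recomputed after
each merge) are merged greedily, highest-r pair first, with every action
recorded in a merge log. This replaces a supervised merge step with a
deterministic rule; an explicit user merge map overrides it. Merged
clusters are labelled from their centroid: `Ramp` when a linear fit against
cuff pressure gives R² ≥ 0.9 with positive slope, otherwise `Low` / `Mid` /
`High` by the pressure at the centroid peak (<100 / 100–300 / ≥300 mm Hg);
movement centroids are labelled by whichever event type carries more mass,
or `Const` when extension and flexion mass agree within 20%.

## Reporting

`run_pipeline` executes the stages in order (simulate → dF/F → features →
classify → cluster), writes every intermediate as CSV/JSON, and emits a
report whose every count equals a row count of a written file. Group
recruitment is summarised as the CIBP:sham ratio of responder fractions per
epoch with a percentile bootstrap CI over cells (1000 resamples, seeded) —
an uncertainty surrogate chosen because between-group hypothesis testing is
out of scope. Identical config + seed reproduce byte-identical report
files.

## Validation strategy and problem sizes

The test suite checks each stage against hand-computed oracles and property
tests (seeded/derandomized hypothesis), and the MCL against an independent
textbook implementation on random graphs. End-to-end recovery runs use
200-responder populations for cluster-structure recovery and 300 cells per
group across ten seeds for recruitment ratios — sizes chosen to match the
per-animal scale of real recordings while keeping a full suite run around
half a minute. Passing these tests shows the pipeline recovers the
structure the generator encodes under realistic noise; it cannot certify
performance against features the generator omits (drift, overlapping
somata, non-Gaussian noise, bleaching).

## Known limitations

- The correlation threshold (0.9) and merge threshold (0.95) assume class
  tuning shapes as distinct as the archetypes encode; closely spaced real
  classes may merge or fragment.
- MCL granularity is controlled only by the inflation exponents; there is
  no cluster-count objective, so the "4 compression / 3 movement" outcome
  is a property of the data, not a constraint.
- The bootstrap CI treats cells as exchangeable and ignores animal-level
  clustering of real datasets.
- Rendering places discs uniformly at random without somatotopy and does
  not model out-of-focus light or ROI mis-segmentation.
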