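# trimodal

Analysis pipeline for chronic intracortical microelectrode (IME) studies
that record three kinds of evidence about one implant: weekly
extracellular **recordings**, weekly **motor-behavior** testing, and
endpoint **histology** around the implant site. The package turns raw
inputs from all three modalities into a common set of analysis
variables, relates them with a bootstrap-validated signed correlation
network organised by numerical formal concept analysis (nFCA), and
models the recording outcomes with penalized mixed-model selection. A
synthetic-study generator with a plantable cross-modal correlation
structure makes every stage testable without animal data.

## What it computes

**Recording metrics** (per animal and week, from 16-channel voltage
traces): traces are band-pass filtered 300–3000 Hz (zero-phase, 4th
order Butterworth) and common-average referenced; background noise is
the robust MAD scale σ = median(|v − median(v)|)/0.6745; spikes are
downward crossings of mean − 3.5σ; waveform clusters are kept as single
units when they have ≥ 20 spikes and SNR > 3, where SNR is the
peak-to-peak of the unit mean waveform over the channel noise (2σ). The
10 consecutive channels with the highest mean unit count over the study
are retained, yielding the two outcomes: **% channels recording single
units** (Y2) and **units per (active) channel** (Y1).

**Histology** (per animal, marker ∈ {NeuN, GFAP, CD68, IgG}): mean
fluorescence intensity in 5 µm concentric rings out to 1 mm from the
implant center, normalized to the 700–750 µm background annulus, then
integrated (trapezoid) in 50 µm increments; neuron counts per ring area
out to 600 µm as percent of the 450–500 µm ring. Analysis values are the
0–50 and 50–100 µm AUC increments (intensity markers) and ring percents
(NeuN), averaged over 6 sections per animal.

**Behavior** (per animal and week): ladder time (mean of the fastest 3
of 5 crossings), grip force (mean of 3 pulls), open-field grid distance
and maximum velocity, and left/right paw slips; the two weekly sessions
average to one score, normalized to the presurgery baseline as

    % change = (weekly − baseline) / baseline × (−100)

(slip counts stay raw — their baselines sit at zero).

**nFCA network**: signed Pearson correlations over the 16 variables at
the finest granularity each pair shares (animal-week for longitudinal
pairs, per-animal values when endpoint histology is involved); an
independent bootstrap test (the two variables' animals resampled
independently, B = 1000) prunes pairs whose |cc| does not exceed the
95th percentile of the null; the surviving associations form a maximum
spanning forest (hierarchy layer) plus all remaining pairs with
|cc| ≥ τ = 0.25 (influence layer). Arrows run from the node with the
larger total association mass (the *dominant* variable); edges whose
endpoint masses agree within 5% are bidirectional. Formal concept
lattices of the thresholded incidence relation (NextClosure) are emitted
as a diagnostic of when variable clusters merge.

**Model selection**: for each recording outcome and histology distance
bin, every subset of the Table-style covariate pool is fitted (linear
mixed models on log/logit-transformed outcomes with animal random
effects; Poisson / negative-binomial / binomial GLMs) and ranked by the
BIC-type penalty −2·logLik + log(n)·(#nonzero fixed coefficients +
#unique nonzero random-covariance elements), with AIC reported alongside
and likelihood-ratio ties resolved toward the smaller model.

## Worked example

```python
import trimodal as tm

blocks = [["pct_channels_active", "units_per_channel", "neun_0_50"],
          ["gfap_0_50", "cd68_0_50"]]
config = tm.StudyConfig(
    rng_seed=1, latent_correlation=tm.block_correlation(blocks, 0.9))
bundle = tm.generate_study(config)

channel_metrics, outcomes, best = tm.recording_metrics(bundle.channel_units)
weekly = tm.behavior_weekly(bundle.behavior_trials)
tables = tm.assemble(config, channel_metrics, outcomes, weekly,
                     bundle.histology_table)

matrix, graph = tm.run_network(tables, B=1000, alpha=0.05, seed=1)
print(tm.export_edge_table(graph).to_string(index=False))
```

```
           variable relationship    network_variable  strength direction     layer
          neun_0_50     Positive pct_channels_active     0.978       UNI hierarchy
          neun_0_50     Positive   units_per_channel     0.953       UNI hierarchy
        ladder_time     Negative         neun_50_100     0.896        BI hierarchy
          cd68_0_50     Positive           gfap_0_50     0.842        BI hierarchy
        gfap_50_100     Negative  ladder_right_slips     0.825        BI hierarchy
pct_channels_active     Positive   units_per_channel     0.797        BI influence
```

The three planted associations (neuron density ↔ both recording metrics,
GFAP ↔ CD68) and the emergent coupling of the two recording metrics are
recovered with their signs; the strength column is |cc|. The two
remaining edges are endpoint-histology pairs correlated at n = 6
animals — at that sample size a few chance associations survive any 5%
test, which is exactly the small-n caution the bootstrap quantifies.

Selecting a model for units/channel against the 0–50 µm covariate pool
on the same study prints its coefficient table:

```python
sel = tm.select_model("units_per_channel", "0-50", tables)
print(sel.coefficient_table.to_string(index=False))
# exploratory_variable  estimate      p_value
#                const  0.430171 2.923399e-07
#                 time -0.107600 5.581626e-03
```

No behavior or histology covariate was planted on the outcome here, so
the search keeps only the intercept and a weekly time trend.

A `trimodal` console script exposes the stages over files:
`simulate`, `ephys`, `histo`, `behavior`, `assemble`, `nfca`, `regress`.

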