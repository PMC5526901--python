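# cytogate

Automated gating and rare-population detection for MHC-multimer flow
cytometry.

Quantifying antigen-specific CD8+ T cells by peptide–MHC multimer staining
is central to immune monitoring, but the populations of interest are rare
(often 0.01–1% of lymphocytes, down to a few events per million) and
manual gating is subjective and varies strongly between laboratories.
`cytogate` implements a fully automated analysis chain for this problem,
aimed at computational immunologists who want a reproducible, scriptable
alternative to manual gating:

1. **Directed automated gating (DAG) prefiltering** — the manual pregating
   sequence (lymphocytes on SSC-A/FSC-A, singlets on FSC-H/FSC-A, live
   cells on the viability channel) is replaced by sequential 2D
   density-contour gates: on each configured projection the event density
   is estimated on a smoothed 128×128 histogram, iso-density contours are
   traced at 32 evenly spaced levels, and the events inside the largest
   closed contour that fits a user-supplied rectangle are passed to the
   next step.
2. **Grid-density clustering** — prefiltered events are binned on a 16^d
   grid over the min–max-scaled marker channels (CD3/dump, CD8, multimer);
   dense hyper-bins are partitioned into local density modes, every event
   is assigned to the nearest mode centroid (Euclidean, scaled space), and
   the fitted model — centroids plus its frozen normalization scale — can
   be reused as a template to assign other samples (cross-sample centroid
   comparison, consensus templates built from subsampled concatenates).
3. **Rule-based annotation** — each cluster gets a per-marker expression
   level 1–4 (negative/low/positive/high, equal-width split of the observed
   channel range); the multimer+ population is every cluster with
   CD3 > 1 (when stained), CD8 > 1, multimer > 2, dump = 1 (when stained).
   Frequencies are reported as % of live single lymphocytes (primary) and
   % of CD8+ T cells, with the conventional 10-event detection threshold
   and duplicate averaging.
4. **Evaluation statistics** — CV = SD/mean × 100, the asymptotic
   Feltz–Miller CV-equality test, paired *t*, Pearson *r*/R² (optional
   log10), and limit-of-detection reports over spike-in dilution series.

Because proficiency-panel FCS data of this kind are generally not public,
the package ships a labeled synthetic generator (`cytogate.simulate`) that
emulates stained PBMC samples: debris, doublets, dead cells, non-T
lymphocytes, CD3+CD8− and CD8+ T cells with a configurable multimer+
fraction, lognormal channel intensities, per-lab gain shifts, and the two
bundled spike-in designs (fivefold × 7 steps from 1.7%, twofold × 9 steps
from 0.87% with a pure-negative end sample). Every simulated event carries
a ground-truth label, so the whole chain is testable end to end.

## Worked example

```python
from cytogate import AutoGatingPipeline
from cytogate.simulate import (preset_populations, preset_profile,
                               simulate_donor, true_frequencies)

# undiluted spike-in donor: 1.7% multimer+ of live single lymphocytes
table = simulate_donor(preset_populations("spikein1-positive"),
                       preset_profile("spikein1-positive"),
                       n_events=200_000, seed=42)
print(true_frequencies(table)["pct_of_live_single"])

pipe = AutoGatingPipeline()           # DAG -> clustering -> cutoff rule
call = pipe.analyze(table)
print(call.freq_of_lymphocytes, call.event_count, call.detected)
```

Output:

```
1.7496055596239291
1.7296101926600102 2749 True
```

The generator realized 1.7496% multimer+ cells among the live single
lymphocytes; the automated pipeline — never seeing the labels — recovered
1.7296% (2,749 events in 158,938 prefiltered events), flagged as detected
under the 10-event threshold.

The same workflow is available from the shell:

```bash
cytogate run-all --config config.yaml --outdir out --seed 1
```

with staged subcommands `simulate`, `gate`, `cluster`, `annotate`,
`evaluate`, three orchestration modes (`single-stage`, `template`,
`two-stage`), and CSV/JSON/FCS artifacts plus a log in the output
directory. Same config + seed reproduces every output byte for byte.

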