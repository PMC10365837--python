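# axonquant

Quantification pipeline for presynaptic physiology assays at corticostriatal
synapses: kymograph-based axonal transport of synaptic-vesicle precursors,
pHluorin exocytosis event counting with a reference-normalized activity
statistic, electron-microscopy morphometry of vesicle distributions around
the active zone, object-based puncta colocalization and PLA density, and
paired-pulse electrophysiology — together with the statistical decision
workflow (ROUT outlier removal, Shapiro-Wilk gating, test selection) used to
compare genotypes. Because raw recordings for such studies are rarely
deposited, the package ships first-class synthetic-data generators that
emulate every acquisition modality with exported ground truth, so every
stage is validated by blind parameter recovery.

Intended users: neurobiology labs quantifying live-imaging, EM and
patch-clamp readouts of presynaptic function, and anyone needing a tested,
scriptable replacement for ad-hoc ImageJ macros.

## The quantities at the core

- **Transport** (per 100 µm of axon, 1 min at 5 Hz): segmental anterograde /
  retrograde speeds (µm/s), vesicle classes (anterograde / retrograde /
  static), net directional flux `(n_antero − n_retro)` per 100 µm per min,
  linear flow (signed net displacement per vesicle per min), and
  directionality `(D_a − D_r)/(D_a + D_r)`.
- **Exocytosis**: per-field event counts before (`y_pre`) and after
  (`y_post`, mean of three acquisitions) stimulation, normalized activity

  ```
  y_i = ((y_i,post − y_i,pre) − mean_j(x_j) + 100) / 100
  ```

  where `x_j` are the post-minus-pre changes of the n reference fields; a
  test field matching the reference mean scores exactly 1. Event amplitudes
  are normalized per ROI as post/pre peak ΔF.
- **EM morphometry**: terminal area (µm²), vesicles/µm², and vesicle counts
  in 40-nm-wide distance bands from the active zone (zone 1: [0, 40) nm,
  zone 2: [40, 80) nm, zone 3: [80, 120) nm); synapses per 100 µm² of
  neuropil.
- **Colocalization**: DoG-enhanced, constant-threshold particle masks;
  percent colocalization = 100 · dual / reference-channel count; PLA dots
  per 100 µm² per nucleus.
- **Electrophysiology**: per-sweep EPSC amplitudes, paired-pulse ratio
  `A2/A1` averaged over 20 sweeps per interstimulus interval, with whole-
  experiment rejection when input or series resistance varies by more than
  20%.
- **Statistics**: ROUT (Q = 1%) per group, Shapiro-Wilk at α = 0.05, then
  t-test / Mann-Whitney, one-way ANOVA + Tukey / Kruskal-Wallis + Dunn, or
  two-way ANOVA + Tukey/Sidak; stars *p<0.05 … ****p<0.0001.

## Worked example

```python
from axonquant import simulate, kymo

cfg = simulate.TransportSimConfig(n_vesicles=30, seed=0,
                                  amplitude=simulate.amplitude_for_snr(8, 100))
movie, truth = simulate.simulate_axonal_movie(cfg)
path = kymo.AxonPath([[0, 6], [999, 6]], width=5)
tracks = kymo.detect_and_link(movie, path, cfg.pixel_size, cfg.frame_interval)
summary = kymo.summarize_axon(tracks)
print(summary.mean_antero_speed, summary.n_anterograde, summary.net_flux_per_100um_min)
```

prints `1.1315817144874194 14 1.0`: a mean segmental anterograde speed of
1.13 µm/s (the generator draws per-segment speeds around 1.2 µm/s), 14
vesicles classified anterograde, and a net flux of +1 vesicle per 100 µm
per minute for this seed. The matching ground-truth summary
(`kymo.summarize_axon(kymo.tracks_from_truth(truth.positions, 0.2))`) gives
1.18 µm/s, so the blind estimate is within 4%.

The numbered scripts under `analysis/` run each assay end to end (simulate →
analyze → score against truth) and write their tables to `results/`:

```bash
python analysis/01_transport_recovery.py
python analysis/02_exocytosis_events.py
...
```

A command-line interface mirrors the library for shell use:
`axonquant simulate|transport|exo|em|coloc|ppr|stats --help`.

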