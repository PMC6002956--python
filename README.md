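# damkit

Scriptable analysis of TriKinetics *Drosophila* Activity Monitor (DAM) data.

DAM monitors record infrared beam breaks of flies walking in glass tubes —
32 channels (flies) per monitor, one count per acquisition interval, over
days to weeks, under light:dark entrainment (LD) and constant darkness
(DD). `damkit` takes the raw monitor files plus an experiment layout and
produces the standard chronobiology read-outs as CSV tables and plots:

- **Validation & conversion** — integrity checks on DAMSystem3 monitor
  files (status codes, timestamp grid, gap repair), conversion of legacy
  DAMSystem2 per-channel files.
- **Dead-fly exclusion** — flies whose total counts on any complete day
  fall below a threshold (default 50 counts/day) are excluded
  automatically.
- **Locomotor activity** — daily means ± SEM per condition, day/night
  splits, day-by-day series, binned activity profiles, activity bouts.
- **Sleep** — the standard fly convention: any continuous inactivity
  lasting ≥ 5 min is sleep. Day/night sleep, sleep profiles, sleep bouts.
- **Circadian analysis** — chi-square periodograms with rhythmicity
  filtering, and single- or double-plotted actograms.
- **Synthetic data** — a seeded generator of realistic monitor files with
  known ground truth, so the whole pipeline is testable without hardware.

It is aimed at fly labs that want the familiar DAM workflow as a library
and command-line tool: reproducible from a config file, scriptable in
Python, and friendly to downstream statistics on the exported CSVs.

## The statistics in brief

**Sleep.** A minute is asleep iff it lies inside a maximal run of
zero-count readings of total duration ≥ 5 min (window configurable). This
run-length rule is provably identical to sliding a 5-min all-zero window
and marking every minute it covers.

**Chi-square periodogram** (Sokolove–Bushell). Counts are summed into bins
of width Δ chosen so every tested period is an integer number of bins.
For a candidate period of *p* bins the first *N′* = *K·p* points (*K*
complete cycles) are folded into a *K* × *p* array with column means
*M<sub>h</sub>* and grand mean *M*:

```
Q(p) = K · N′ · Σ_h (M_h − M)² / Σ_i (x_i − M)²
```

Under the no-rhythm null, Q(p) ≈ χ²(p − 1). The significance line S(p) is
the upper-tail χ² quantile; because the scan tests many periods at once,
the configured `alpha` (default 0.05) is the family-wise level of the
whole scan and the per-period quantile is Šidák-corrected by default.
The peak is the period maximizing Q − S, the **rhythm strength** is
Q(peak)/S(peak), and flies with strength < 1 (configurable) are classed
arrhythmic and excluded from period statistics.

**Aggregation.** Condition statistics are means of fly-level means, with
SEM across individuals — flies observed on different numbers of days get
equal weight.

## Worked example

Simulate one monitor — four diurnal flies with a 24 h square-wave rhythm,
one fly that dies on Jan 7, one arrhythmic fly — then analyze it:

```sh
damkit simulate --config sim.yaml --out demo/data
damkit analyze  --config run.yaml
```

with `run.yaml`:

```yaml
monitors: [demo/data/Monitor1.txt]
interval_minutes: 1
light_onset: "06:00"
ld_start: 2017-01-02
ld_end:   2017-01-04
dd_start: 2017-01-05
dd_end:   2017-01-11
dead_threshold: 50
conditions:
  - {name: ctrl, color: "#2b6cb0", monitor: Monitor1, channels: [1, 2, 3, 4, 5, 6]}
output_dir: demo/out
```

The run writes 21 files. `condition_counts.csv` shows the dead fly was
caught and excluded:

```
condition,n_assigned,n_dead,n_analyzed
ctrl,6,1,5
```

`condition_summary_LD.csv` gives mean daily counts ± SEM over the 5
analyzed flies, split by phase — these simulated flies are strongly
diurnal (day ≫ night activity):

```
condition,phase,mean,sem,n
ctrl,all,1930.3,128.1,5
ctrl,day,1724.3,258.7,5
ctrl,night,206.0,130.6,5
```

`circadian_period_by_fly.csv` recovers the programmed 24 h free-running
period for every rhythmic fly, while the arrhythmic fly's periodogram
peak never clears its significance line (strength < 1):

```
fly_id,peak_period_h,rhythm_strength,rhythmic
ctrl_Monitor1_01,24.0,4.20,True
ctrl_Monitor1_02,24.0,4.32,True
ctrl_Monitor1_03,24.0,4.22,True
ctrl_Monitor1_04,24.0,4.29,True
ctrl_Monitor1_06,22.4,0.93,False
```

(Values shown to fewer digits than the CSVs carry.)

Other subcommands: `damkit validate M*.txt` prints the integrity-issue
table for monitor files; `damkit convert --out M1.txt ch*.txt` merges
DAMSystem2 channel files into a monitor file.

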