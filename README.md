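# meadev

Quantitative analysis of developing spontaneous activity on
multielectrode arrays (MEAs).

Each 15-minute recording of per-electrode spike times is summarised by
an 11-dimensional feature vector:

| # | feature | array summary |
|---|---------|---------------|
| 1 | `firing_rate` | median electrode firing rate (Hz) |
| 2 | `within_burst_rate` | median over bursting electrodes (Hz) |
| 3 | `burst_rate` | median over bursting electrodes (/min) |
| 4 | `burst_duration` | median over bursting electrodes (s) |
| 5 | `fraction_in_bursts` | median over bursting electrodes |
| 6 | `cv_ibi` | median CV of interburst intervals |
| 7 | `ns_rate` | network spikes per minute |
| 8 | `ns_peak` | median network-spike peak electrode count |
| 9 | `ns_duration` | median network-spike duration (s) |
| 10 | `mean_correlation` | mean pairwise spike-time tiling coefficient (Δt = 5 ms) |
| 11 | `theta_fraction` | fraction of electrodes with a log-ISI density peak in 0.1–0.25 s (4–10 Hz) |

Bursts come from a max-interval detector (begin ISI < 0.1 s, end ISI
< 0.25 s, merge gap < 0.8 s, min duration 0.05 s, min 6 spikes);
network spikes are maximal runs of 3 ms bins with more than 10 active
electrodes.  Group differences (CTX vs HPC per age) are tested with
Mann–Whitney tests under Benjamini–Hochberg FDR control; recordings are
discriminated with PCA, random forests (Gini importance, normalised to
the top feature) and RBF-kernel SVMs (γ = 1/11) over repeated
two-thirds/one-third splits.  A synthetic-data module generates
recordings with controllable burst regularity, theta modulation and
array-wide shared bursting for calibration and testing.

## Data format

Recordings are single HDF5 files: `/spikes` (concatenated spike times,
s), `/sCount` (per-electrode counts), `/epos` (N×2 positions, µm),
`/names` (labels), `/array`, `/meta/region` (`"CTX"` or `"HPC"`),
`/meta/age` (days in vitro), optional `/t_start`/`/t_stop`.  The reader
also accepts integer sample counts via `read_recording(path,
units="samples", sample_rate=25000)`.

## CLI

```sh
meadev simulate --region HPC --div 14 --n 59 --duration 900 --seed 1 -o rec.h5
meadev info rec.h5
meadev validate rec.h5
meadev features rec1.h5 rec2.h5 -o features.csv
meadev bursts rec.h5 -o bursts.csv
meadev netspikes rec.h5
meadev sttc rec.h5 --dt 0.005 -o pairs.csv
meadev theta rec.h5
meadev compare features.csv -o comparison.csv
meadev pca features.csv --age 14 -o pca.csv
meadev classify features.csv --method forest --repeats 500 --seed 1 -o result.json
meadev table1 features.csv -o table1.csv
meadev run config.yaml -o out/
```

`meadev run` drives the whole pipeline from one YAML config (see the
`meadev.pipeline` module docstring for the schema) and writes
`features.csv`, `comparison.csv`, per-age PCA coordinates,
`classification.json`, `table1.csv` and a reproducibility manifest.

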