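# emgdi

ECG-artifact removal and breath-wise diaphragm-EMG amplitude analysis.

Esophageal diaphragm-EMG (EMGdi) recordings carry large ECG artifacts. This
package implements a semi-automated analysis chain — reference-channel LMS
adaptive FIR cancellation, breath segmentation from the flow signal,
per-breath RMS amplitudes normalized by the maximal activation reached
during inspiratory-capacity (IC) maneuvers — together with a reproducible
emulation of the classical *manual* method (selecting EMG between QRS
complexes, with the two documented rater strategies "highest" and
"widest"), the agreement statistics used to compare methods (ICC,
Bland–Altman, CV, Pearson, repeated-measures interaction), and a synthetic
multi-channel recording generator with full ground truth so everything is
testable without clinical data.

## Command-line usage

All stages are subcommands of `emgdi`:

```bash
# synthetic recording (tab-separated text) + ground-truth sidecar
emgdi simulate --seed 1 --out rec.txt --truth truth.json

# high-pass + adaptive ECG cancellation (filter length 70, step 0.01)
emgdi clean --in rec.txt --out rec_clean.txt

# breath segmentation from zero-flow points, IC detection, minute labels
emgdi segment --in rec.txt --out breaths.csv

# per-minute EMG/max% from the cleaned recording
emgdi analyze --in rec_clean.txt --breaths breaths.csv --out minutes.csv

# manual between-QRS emulation (rater strategy: highest | widest)
emgdi emulate-manual --in rec.txt --breaths breaths.csv \
    --strategy highest --out minutes_manual.csv --audit audit.csv

# agreement report between two per-minute series
emgdi compare --a minutes.csv --b minutes_manual.csv --out report.json

# the whole synthetic validation study in one go
emgdi demo --out demo_run --seed 0 --n-subjects 7
```

Every command writes a `<out>.config.json` sidecar with the effective
parameters and their hash; identical config + seed reproduces outputs
byte-for-byte.

Recordings are plain text: a `# fs=<Hz>` header, optional `# marker` lines,
a channel-name row (`emg_1..emg_5 ecg flow`; flow is L/s with negative
values during inspiration), then tab-separated samples at full float
precision. EDF files (16-bit, integer sampling rate) can be read with
`read_recording(path, format="edf")`.

## Library layout

| module | contents |
|---|---|
| `emgdi.synth` | `SynthConfig`, `simulate_recording`, `simulate_ecg`, `GroundTruth` |
| `emgdi.io` | `Recording`, delimited-text/EDF read-write, `resample` |
| `emgdi.preprocess` | zero-phase 20 Hz high-pass, moving-RMS envelope |
| `emgdi.cancel` | `LmsConfig`, `lms_clean`, `clean_recording` |
| `emgdi.breaths` | `detect_breaths`, IC detection, minute assignment, outlier flags |
| `emgdi.activation` | per-breath amplitudes, maximal-activation reference, minute summaries |
| `emgdi.manual` | QRS detection, clean-interval enumeration, rater strategies |
| `emgdi.agreement` | ICC (+CI), Bland–Altman, CV, Pearson, interaction ANOVA |
| `emgdi.cli` | subcommands above, `run_pipeline` |

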