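# wakeosc

Analysis of oscillation bursts and aperiodic activity in wake EEG across
child and adolescent development.

Wake EEG changes with both brain maturation and sleep pressure, but spectral
band power confounds three distinct phenomena: how *often* oscillations
occur, how *large* they are, and the broadband 1/f background they ride on.
`wakeosc` separates them. It provides, as a tested Python library:

- **Automated artifact rejection** for high-density (128-channel) recordings:
  a 40 Hz low-pass / notch / 250 Hz / 0.5 Hz Kaiser high-pass filter chain,
  a 3-s-segment artifact matrix (major: >500 µV; minor: best neighbor
  correlation < 0.3), least-loss channel/segment removal, a 140 µV second
  pass, spherical-spline interpolation onto a 123-channel analysis montage,
  and exclusion rules (>25 channels removed or <1 min of clean data).
- **Cycle-by-cycle oscillation-burst detection** (2–16 Hz): narrowband
  zero-crossings delimit cycles, broadband peaks define them, and seven
  regularity scores (period/amplitude/flank/shape consistency, monotonicity
  in time and amplitude, reversal ratio) feed three a-priori criteria sets.
  Amplitude is never a threshold, so burst **density** (% of recording
  occupied by bursts) and burst **amplitude** (mean negative-to-positive
  peak difference, µV) stay independent measures.
- **Spectral parameterization**: Welch spectra (4-s Hanning, 50% overlap,
  2 Hz smoothing) decomposed into an aperiodic component
  `log10 P(f) = offset − exponent · log10 f` (fit 2–35 Hz, fixed mode) plus
  Gaussian peaks, yielding offset, exponent, 4–16 Hz power and periodic
  power.
- **Developmental statistics**: the mixed-effects model
  `Measure ~ Task + Time*Age + Group + Sex + (1|Participant) +
  (1|Participant:Session)`, per-channel fits with Benjamini–Hochberg FDR,
  overnight-change (morning − evening) Pearson correlations with age, and
  Steiger's Z1* test for dependent correlations.
- **A synthetic-EEG generator** with analytic ground truth (1/f^x
  backgrounds by inverse-spectrum phase randomization, planted bursts and
  artifacts, simulated cohorts), so every stage is testable end to end
  without any recorded data.

## Worked example

```python
import numpy as np
from wakeosc.core import Recording
from wakeosc.montage import make_geodesic_montage
from wakeosc.synthetic import BurstSpec, generate_aperiodic, insert_bursts
from wakeosc.bursts import detect_recording_bursts
from wakeosc.metrics import compute_amplitude, compute_density
from wakeosc.spectral import fit_specparam, smooth_spectrum, welch

montage = make_geodesic_montage().subset(["E1"])
background = generate_aperiodic(1, 120.0, 250.0, exponent=1.5, offset=0.5,
                                seed=4, montage=montage)
specs = [BurstSpec((0,), onset=10.0 + 3 * k, frequency=10.0, n_cycles=15,
                   peak_to_peak=30.0) for k in range(30)]
rec, truth = insert_bursts(background, specs)

bursts = [b for b in detect_recording_bursts(rec) if b.frequency >= 4]
print(f"density  {compute_density(bursts, rec.duration, rec.fs, pooled=True):.1f}%"
      f"  (planted {truth.density():.1f}%)")
print(f"amplitude {compute_amplitude(bursts):.1f} uV  (planted 30.0 uV)")
fit = fit_specparam(smooth_spectrum(welch(rec.signal, rec.fs)))
print(f"exponent {fit.exponent:.2f}  offset {fit.offset:.2f}")
```

Output:

```
density  35.7%  (planted 37.5%)
amplitude 30.8 uV  (planted 30.0 uV)
exponent 1.48  offset 0.50
```

The detector recovers the planted burst load (the ~2-percentage-point gap
is the expected one-cycle edge loss per burst of peak-to-peak cycle
parsing), the planted amplitude within 3%, and the 1/f background
parameters of the synthesis within 0.02.

A thin CLI wraps the same functions:

```bash
wakeosc preprocess --in raw.edf --line-freq 50 --out clean.edf --qc qc.json
wakeosc bursts --in clean.edf --out bursts.csv
wakeosc stats --table measures.csv --outcome Amplitude --out effects.json
```

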