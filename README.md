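# accelsleep

Sleep staging from a chest-worn triaxial accelerometer.

A single accelerometer on the chest carries three superimposed signals:
respiration (slow orientation changes of the sensor), heartbeats (small
seismocardiographic peaks), and gross body movement (high-amplitude bursts).
`accelsleep` turns those into an overnight hypnogram and evaluates it:

1. **extract** — sum the three channels and localize heartbeats by dynamic
   programming over band-passed envelope peaks with an inter-beat-interval
   (IBI) smoothness prior; compute instantaneous heart rate IHR = 60/IBI,
   sample-and-hold at 10 Hz, masking low-quality stretches. In parallel,
   decimate the channels to 10 Hz, convert to an orientation signal
   (h1, h2, v), estimate respiratory effort *Res* from the horizontal
   components, compute per-second activity counts

       Act = mean|x − x̄| + mean|y − ȳ| + mean|z − z̄|

   over each 1-s window, and mix them: **ResAct = (1 + Act)·Res**, so
   movement artifacts look like those of a thoracic belt.
2. **sync** — align two independently clocked recordings by retiming one
   IBI series with offset *o* and rate *r* (t′ = o + r·t) to maximize the
   cross-correlation of the two IBI tachograms.
3. **stage** — classify each 30-s epoch into Wake / N1+N2 / N3 / REM from
   per-epoch cardiorespiratory features, with whole-night temporal context
   from hidden-Markov smoothing (Viterbi labels, forward–backward
   posteriors).
4. **evaluate** — epoch-by-epoch agreement (confusion matrix, Cohen's κ,
   accuracy, one-vs-rest sensitivity/specificity/PPV), sleep metrics (TST,
   sleep efficiency, latencies, WASO, time in stage) with Bland–Altman 95%
   limits of agreement, M-gap stage-interval matching, and cohort factor
   tests (Mann–Whitney U, Spearman ρ, Benjamini–Hochberg FDR).
5. **simulate** — synthetic overnight recordings (Markov hypnogram,
   stage-conditional heart rate/HRV and respiratory regularity, movement
   bursts, full triaxial acceleration) so every stage is testable without
   clinical data.

Clinical polysomnography datasets are not distributable, so the staging
classifier here is a transparent, trainable stand-in with the same
10 Hz-in / 30-s-probabilities-out contract as a deep cardiorespiratory
network; a learned estimator can be dropped in behind the same interface.

## Worked example

```python
import numpy as np
from accelsleep import simulate as sim
from accelsleep import extract as ex
from accelsleep import evaluate as ev

# a 30-min synthetic recording at 100 Hz
rec = sim.simulate_recording(sim.SleepArchitecture(n_epochs=60), seed=1, fs=100.0)

# heartbeats from the channel-summed acceleration
beats = ex.detect_heartbeats(ex.collapse_channels(rec.accel), fs=100.0)
d = np.abs(rec.true_beats.times[:, None] - beats.times[None, :]).min(axis=1)
print(f"beats: {len(beats)} detected / {len(rec.true_beats)} true, "
      f"recall@50ms = {(d <= 0.05).mean():.3f}")
```

Running the detection part prints:

```
beats: 2005 detected / 2024 true, recall@50ms = 0.959
```

i.e. 2005 heartbeats localized, 95.9% of the true beats matched within
±50 ms (the misses sit inside movement bursts, whose IHR the pipeline masks
out anyway). Agreement metrics work on any pair of label sequences:

```python
from accelsleep.types import StageSequence
ref = StageSequence(np.array(list("WWLLRWDD"), dtype=object))
m = ev.sleep_metrics(ref)
print(m.tst, m.sleep_latency, m.sleep_efficiency)   # 2.5 1.0 62.5
```

— 2.5 min total sleep time, 1.0 min sleep-onset latency, 62.5% sleep
efficiency for that 4-minute toy hypnogram.

A command-line umbrella covers the same flow:

```bash
accelsleep simulate --seed 7 --n-epochs 960 --out night/
accelsleep extract  --accel night/accel.tsv --out night/
accelsleep sync     --ref night/beats.tsv --test night/beats.tsv --out align.json
accelsleep train    --data cohort/ --out model.json --seed 0
accelsleep stage    --bundle night/bundle.tsv --model model.json --out est.tsv
accelsleep evaluate --ref refs/ --est ests/ --out report/
```

## Layout

```
src/accelsleep/
  types.py      shared containers (TriaxialAccel, BeatSeries, GappedSeries, ...)
  simulate.py   synthetic recordings and ground truth
  extract.py    acceleration -> IHR, Res, Act, ResAct
  sync.py       IBI-tachogram clock alignment
  stage.py      epoch features, stager training, HMM-smoothed classification
  evaluate.py   agreement, sleep metrics, intervals, factor statistics
  io.py         columnar text formats, manifest
  pipeline.py   extract -> sync -> stage -> evaluate for one recording
  cli.py        the `accelsleep` command
docs/methods.md  model assumptions, parameters, limitations
```
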