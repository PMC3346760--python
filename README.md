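# lfp2spike

Tools for asking two questions about a simultaneously recorded local field
potential (LFP) and single-unit spike train during repeated sensory
stimulation:

1. **How reliably do spikes and LFPs code for stimulus occurrence?**
   Spike responsiveness is the Shannon mutual information (bits) between the
   binary stimulus category (post- vs. pre-stimulus window) and the spike
   count, bias-corrected by label shuffling and maximized over a grid of
   count windows (5–50 ms) and stimulus locations. LFP responsiveness is an
   evoked-to-fluctuation ratio computed from the single-trial response
   matrix, and the Spectral Ratio compares stimulated to spontaneous LFP
   power on a fixed 1–40 Hz grid.

2. **Can single-trial spike patterns be predicted from LFP features?**
   A model genome combines three normalized LFP features — the LFP, its time
   derivative, and the Hilbert phase of the derivative — through unary
   operators `u_i` drawn from a configurable set `U` and convex weights
   `w`:

       M(x1, x2, x3) = w1·u_{j1}(x1) + w2·u_{j2}(x2) + w3·u_{j3}(x3)
       B_pred = H_θ(M),   θ set so that #spikes(B_pred) = #spikes(B_true)

   Genomes are scored on three chance-anchored costs — Spike Match (SM,
   trial-by-trial Hamming distance), PSTH Fit (PF, distance between
   trial-averaged responses) and Complexity Order (CO, weight entropy) — and
   searched with an NSGA-II variant in which crossover is restricted to
   parents sharing an operator structure. Training/validation halves are
   split trial-wise and the validation-non-dominated front is returned; a
   unit counts as predicted above chance when mean(PF) − std(PF) over that
   front is below 1.

A synthetic-data module generates complete recording bundles — couplet
tactile stimulation protocol, 1/f background LFP with gain-jittered evoked
deflections, and spikes produced by a known genome of the same model class —
so the whole pipeline can be exercised and tested without any experimental
data, including ground-truth recovery.

## Worked example

```python
import lfp2spike as l
from lfp2spike.synthetic import ProtocolSpec, LFPSimSpec, GroundTruth, make_dataset
from lfp2spike.io import RunConfig
from lfp2spike.pipeline import run_pipeline

rec = make_dataset(ProtocolSpec(n_couplets=100), LFPSimSpec(),
                   GroundTruth(spike_noise=0.1), seed=42)
cfg = RunConfig(seed=42, use_sta=False,
                ga=l.GAConfig(pop_size=64, generations=20, seed=42))
report = run_pipeline(cfg, rec)
```

prints (via the report fields):

```
MI  = 0.470 bits (window 40 ms, location 0, reliable=True)
R_LFP = 0.837
SR  = 4.179
above_chance: True
validation front:
  1*x2                                      SM=0.994 PF=1.617 CO=0.000
  0.745*x1 + 0.0643*cube(x2) + 0.191*cube(x3)  SM=0.681 PF=1.140 CO=0.648
  0.228*cube(x1) + 0.772*ssqrt(x2)          SM=0.783 PF=1.022 CO=0.489
```

Reading the numbers: the unit carries 0.47 bits about stimulus occurrence
(1 bit would be perfect separation of pre- from post-stimulus counts); the
LFP evoked response is comparable to its trial-to-trial fluctuations
(R_LFP ≈ 0.8) and stimulation amplifies low-frequency LFP power roughly
4-fold. On the validation half, the best trade-off model predicts individual
2-ms spike bins about 32% better than chance (SM = 0.68; 0 would be a
perfect bin-for-bin match, 1 is chance), and mean(PF) − std(PF) < 1, so the
unit is counted as predicted above chance. Each front row is one Pareto
model written as its explicit equation in the features x1 (LFP), x2
(derivative) and x3 (phase of derivative).

The same pipeline is scriptable from the shell:

```sh
lfp2spike simulate --spec spec.yaml --seed 42 --out bundle/
lfp2spike responsiveness --bundle bundle/ --config run.yaml --out resp.csv
lfp2spike fit --bundle bundle/ --config run.yaml --out fitdir/
lfp2spike run --bundle bundle/ --config run.yaml --out report.json
```

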