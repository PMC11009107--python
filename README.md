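# cupore

Signal analysis for amino-acid sensing with a copper(II)-functionalized
MspA nanopore — from raw single-channel current traces to amino-acid
calls, concentrations and peptide-hydrolysate inference, together with a
synthetic recording simulator that gives every stage of the pipeline a
testable ground truth.

## The problem

A histidine-substituted MspA pore (N91H) loaded with Cu²⁺ coordinates the
α-amine and α-carboxyl groups of free amino acids. Each binding event
transiently blocks the ionic current: the fractional **blockade**
(I₀ − I₁)/I₀ against the copper-bound baseline I₀, the **dwell time** Δt,
the in-event current s.d., and a 1,000-point density profile of the
I₀-standardized current together fingerprint the bound amino acid. Event
*frequency* is proportional to concentration, which makes the same
recordings quantitative; and because exopeptidases release residues
sequentially from one terminus, the relative abundances of amino acids in
a partial peptide hydrolysate encode positional information about the
peptide sequence.

`cupore` implements the full analysis chain for such recordings:

| stage | module | method |
| --- | --- | --- |
| synthetic recordings | `cupore.simulate` | Poisson capture, Gaussian blockades, exponential dwells, two-state copper kinetics, sequential-cleavage hydrolysis |
| event detection | `cupore.signals` | PELT change points (Gaussian mean+variance cost), piecewise polish, modal baseline, blockade ≥ 0.1 extraction, KDE feature vectors |
| background rejection | `cupore.background` | KNN test against blank-control events on z-scored features |
| classification | `cupore.classify` | RF / NB / NNet / KNN / bagged CART / AdaBoost with 10-fold CV, macro one-vs-rest AUC, accuracy–recovery threshold curve |
| quantification | `cupore.quantify` | frequency–concentration OLS calibration, inversion with delta-method s.e., count-based LOD (> 5 calls / 10 min) |
| hydrolysate inference | `cupore.hydrolysate` | confident calls (p > 0.95), capture-rate-normalized abundances, Spearman positional trend, peptide density profiles + classical MDS |
| orchestration | `cupore.cli`, `cupore.pipeline` | `cupore` command line; seeded, bit-reproducible end-to-end runs |

## Worked example

Simulate a mixed recording of serine and phosphoserine, detect events and
fit the serine blockade distribution:

```python
import numpy as np
from cupore import DEFAULT_PARAMS, TraceConfig, simulate_trace
from cupore.signals import detect_events, fit_blockade_distribution

cfg = TraceConfig.fast(duration=120.0, seed=1)   # 2 kHz test mode
trace, truth = simulate_trace([(DEFAULT_PARAMS["S"], 600.0)], cfg)

events, baseline, _ = detect_events(trace, with_features=False)
blockades = np.array([e.blockade for e in events if e.n_sublevels == 1])
mu, sd, se, _ = fit_blockade_distribution(blockades)
print(f"I0 = {baseline.I0:.2f} pA")
print(f"{len(blockades)} state-1 events; blockade {mu:.4f} +/- {sd:.4f}")
```

```
I0 = 99.99 pA
714 state-1 events; blockade 0.1320 +/- 0.0041
```

The fitted mean (0.1320) recovers the serine blockade the simulator was
calibrated with (0.132); the fitted spread is slightly wider than the
generative 0.0033 because each event's level is estimated from finitely
many noisy samples.

The same chain runs from the shell:

```sh
cupore simulate --out trace.tsv --analyte S:600 --duration 120 --seed 1
cupore detect trace.tsv --out events.tsv
cupore train events_labeled.tsv --algo rf --out model.joblib
cupore predict model.joblib events.tsv --out calls.tsv
```

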