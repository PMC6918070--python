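# mmphys

Single-cell bacterial cell-cycle simulation and physiology analysis:
a stochastic generative model of growth and replication control built on
the **initiation-mass threshold** picture, together with the estimators
used to analyse mother-machine, turbidostat and qPCR experiments.

## The scientific problem

How does a bacterium decide when to replicate its chromosome?  A large
body of single-cell work supports a threshold model: initiator molecules
are produced in proportion to volume growth and accumulate at the
replication origins; when the amount per origin reaches a threshold, all
origins fire simultaneously.  The cell size per origin at initiation,
*s*ᵢ, is then invariant — across nutrient conditions, under translation
inhibition, and even through nutrient shifts — while division timing
follows from the replication period *C* (origin to terminus) plus the
post-replication period *D*.

`mmphys` implements this model as a reproducible, event-driven simulator
(the stand-in for mother-machine lineage data, turbidostat OD traces and
qPCR marker-frequency samples) and the full analysis stack that measures
it back:

* **trace analysis** — per-generation physiology (τ, λ, L_b, L_d, septum
  position, S_b, S_d) from frame-sampled traces, plus C, D, *s*ᵢ and the
  number of overlapping cycles *n*_oc from replication-event annotations,
  with the 4-SD population filter;
* **ensemble method** — cells aligned by size rather than age; the mean
  replisome-pair focus count steps from one plateau to the next at the
  population's initiation size (maximum rate of change, 0.2 µm
  differentiation step), and
  `C + D = [n_oc + log2(S_d/S_i)] · τ`;
* **marker frequency** — the C period from relative locus copy numbers
  via `f(m) = 2^{C(1−m)/τ}` (ori = 0, ter = 1), as an OLS Model/Results
  pair with `summary()`;
* **physiology statistics** — CV hierarchies, cross-correlations of
  mean-normalized parameters, the spherocylinder volume
  `π(W/2)²(L−W) + (4/3)π(W/2)³`, imaging discretization error
  `2^{1/k} − 1`, turbidostat growth-interval fits, and the 12-min
  binned / baseline-normalized series used for nutrient-shift analysis;
* **1-D focus detection** — axial-profile synthesis and a
  Laplacian-of-Gaussian detector for replisome foci.

Core model relations (noiseless limit, held to 1e-9 in the tests):

```
v ← v/2 + δ            per-ori volume at initiation → fixed point 2δ = s_i
S_d = S_i · exp[(C+D)λ]     division size, no overlapping cycles
C + D = [n_oc + log2(S_d/S_i)] · τ
```

## Worked example

```python
import mmphys as m

res = m.simulate_steady_state(m.DEFAULT_CONDITION, m.SamplingConfig(),
                              n_generations=60, n_lineages=8, seed=11)
records = m.build_generations(res.frames)
records, events, _ = m.assign_cell_cycles(records, res.initiations)
kept, report = m.filter_outliers(records)
```

prints, after summarising `kept`:

```
generations analyzed: 435  (excluded: 5)
  doubling time tau (min)             38.0103 +/- 10.0318
  growth rate lambda (1/min)           0.0182 +/- 0.0013
  initiation size per ori s_i (um^3)   1.1985 +/- 0.0936
  C period (min)                      39.8181 +/- 4.5890
  D period (min)                      20.1905 +/- 4.9806
ensemble initiation size: 2.375 um^3
ensemble C + D: 59.7 min
```

The default ("mannose-like") condition is configured with τ = 38 min,
C = 40 min, D = 20 min and *s*ᵢ = 1.2 µm³; the analysis recovers all of
them from the simulated frames, and the ensemble initiation size
(2.375 µm³) matches the single-cell mean S_i = *s*ᵢ · n_ori ≈ 2.4 µm³.
The marker-frequency route works the same way:

```python
data = m.simulate_qpcr(C=40.0, tau=28.0,
                       positions=list(m.TABLE_LOCI.values()),
                       noise_cv=0.05, seed=7)
print(m.MarkerFrequencyModel(data, tau=28.0).fit().summary())
```

```
Marker-frequency C-period fit
-----------------------------
loci (n)            : 9
doubling time tau   : 28 min
slope (C/tau)       : 1.50187 +/- 0.0475
C period            : 42.0524 +/- 1.33 min
intercept (log2 f)  : -0.0562  (normalization diagnostic; 0 = exact ter reference)
```

A `mmphys` console script exposes the same pipeline as subcommands
(`simulate`, `simulate-shift`, `analyze`, `ensemble`, `markerfreq`,
`turbidostat`, `report`), each writing a `run.log` with the seed, config
hash and filter counts.

## Acceptance script

`scripts/acceptance.py` recomputes the headline nutrient-shift result
from scratch: it simulates a 64-lineage mother-machine ensemble through
an upshift (τ 65 → 30 min) and a downshift back 12 h later (with a
60–120 min growth pause), bins the per-origin initiation sizes in 12-min
bins, normalizes to the 4-h pre-upshift baseline, and reports the
maximum percent deviation from that baseline across the whole time
course.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/mmphys/
  conditions.py   growth conditions, shift schedules, config files
  simulate.py     event-driven lineage simulator, qPCR + turbidostat generators
  traces.py       per-generation trace analysis and outlier filtering
  ensemble.py     size-aligned focus-count profiles, C+D inference
  markerfreq.py   marker-frequency C-period model
  physiology.py   geometry, CV tables, correlations, binning, OD fits
  foci.py         1-D axial profiles and LoG focus detection
  tables.py       tab-delimited generation/frame table formats
  cli.py          command-line interface
docs/methods.md   model description, assumptions, numerical choices
```
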