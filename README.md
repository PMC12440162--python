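# hiveflow

Analysis pipeline for individual variation in honey-bee sociability from
automated barcode tracking. Given per-frame detections of hundreds of
individually tagged bees (1 image/s), raw trophallaxis (food-sharing)
detections, hive-entrance trip logs, laboratory assay observations, and
optionally genotypes, `hiveflow` produces a per-bee phenotype table:

* **sociability** — trophallaxis events per day after merging raw detector
  fragments (< 1 min apart) and discarding implausible durations (< 3 s or
  > 3 min);
* **movement kinematics** — mean linear (mm/s) and angular (deg/s) speeds,
  suppressing sub-threshold motion (< 4.9 mm displacement *and* < 60° turn,
  about one honeycomb cell) as stationary behavior rather than locomotion;
* **social influence** — bidirectional information flow, in bits, between a
  bee and its neighbors during proximal interactions;
* **behavioral state** — forager / guard / nurse / generalist /
  non-responder / baseline by explicit rules over trips and assays;
* **polygenic score** — effect-size-weighted sum of alternative-allele
  dosages, plus hypergeometric gene-list overlap and the standard group
  statistics (one-way ANOVA with Tukey HSD, Wilcoxon rank-sum, Spearman).

It is written for behavioral ecologists and systems biologists who need the
full chain — event processing, kinematics, network inference, and downstream
association statistics — as a tested, reusable library rather than a
collection of analysis scripts. A ground-truthed synthetic-colony generator
(`hiveflow.simulate`) stands in for colony-scale tracking data, so every
stage can be validated against known injected signal.

## The influence measure

A *proximal interaction* is a contiguous run of ≥ 30 frames in which a focal
bee and one neighbor are both detected, within R ≤ 20 mm of each other,
both moving, and not in trophallaxis with each other. For each interaction
and each coordinate axis, a vector autoregressive model

```
y(t) = A₁ y(t−1) + … + A_p y(t−p) + w(t),   w ~ (0, Σ_w)
```

is fitted to the mean-removed (focal, neighbor) coordinate pair by
conditional least squares (order chosen by AIC over p ∈ {1, 2, 3}). With
Ā(f) = I − Σₘ Aₘ e^(−i2πfm/fs), the squared information partial directed
coherence for the direction j → i is

```
iPDC²_{i←j}(f) = |Ā_ij(f)|² / ( Σ_ii · ā_j(f)ᴴ Σ_w⁻¹ ā_j(f) )
```

which lies in [0, 1] and reduces to the generalized PDC when Σ_w is
diagonal (classic PDC and gPDC are available behind a `variant` switch).
Spectra are averaged pointwise across a bee's interactions, then integrated
into information flow

```
I_flow = −(1/fs) ∫₀^{fs/2} log₂(1 − iPDC²(f)) df      [bits]
```

and finally the X and Y results are averaged, giving each bee one outgoing
(bee → neighbor) and one incoming (neighbor → bee) influence value.

## Worked example

`examples/03_influence_estimation.py` simulates a leader/follower pair with
coupling c = 0.6 for one 30-frame window and estimates influence in both
directions:

```
axis X: VAR(1), I_flow leader->follower 0.4035 bits, follower->leader 0.0587 bits
axis Y: VAR(2), I_flow leader->follower 0.3891 bits, follower->leader 0.0172 bits
averaged over axes: leader->follower 0.3963 bits, follower->leader 0.0379 bits
```

The follower's velocity tracks the leader's previous displacement, so the
leader's past carries information about the follower's present — the
leader → follower flow dominates by roughly a factor of ten. The other
examples cover the colony generator, kinematics and trophallaxis
processing, behavioral-state classification, association statistics, and
the end-to-end run (`examples/06_full_pipeline.py`), which prints the
joined 20-bee phenotype table and per-stage row counts.

A thin CLI mirrors the library (`hiveflow simulate | validate | kinematics |
trophallaxis | proximity | influence | classify | associate | run-all`); a
YAML config whose keys override the built-in defaults drives `run-all`.

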