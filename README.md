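# rsvpcar

Cross-subject transfer for ERP-based brain–computer interfaces: simulate
multi-subject RSVP speller sessions, quantify inter-subject ERP similarity,
and train target detectors for a *new* subject from other subjects' data,
with donors chosen by **correlation analysis rank (CAR)** instead of at
random.

## The problem

An ERP speller detects which symbol a user attends by finding the P300 — a
positive EEG deflection ~300–500 ms after a rare, attended stimulus — among
rapid serial visual presentation (RSVP) flashes. Classifiers trained on one
person transfer poorly to another because P300 latency, amplitude and
topography differ across people. CAR addresses this with a short calibration
recording from the new subject: average their target epochs into an ERP
`ŝ(t) = (1/M) Σᵢ xᵢ(t)`, rank every database ("donor") subject by the Pearson
correlation

    r = 1/(n−1) Σᵢ ((Xᵢ − X̄)/s_X)((Yᵢ − Ȳ)/s_Y)

between the vectorized donor and calibration ERPs, and train a shrinkage LDA
(`w ∝ Σ̂⁻¹(μ₁ − μ₀)`) on the pooled epochs of the top-N donors only.
Detection quality is the Mann–Whitney AUC of target vs nontarget scores;
speller throughput is the information transfer rate

    ITR = [log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))] / T  bits/min

for N symbols, selection accuracy P and selection time T.

Because no public multi-subject RSVP corpus accompanies the method, the
package ships a first-class synthetic cohort generator: subject-specific
Gaussian-bump P300 templates (latency/amplitude/width/topography) drawn
around cluster archetypes, embedded in 1/f background noise, organized into
the round/trial/block structure of a real speller session. Cluster
membership is recorded as ground truth, so donor-ranking behaviour is
testable end to end.

## Worked example

```python
import numpy as np
import rsvpcar as rc
from rsvpcar.synthetic_cohort import ClusterDispersion

spec = rc.CohortSpec(
    n_subjects=12, n_clusters=2, seed=7,
    paradigm=rc.ParadigmConfig(n_blocks=3),
    cluster_latencies=(300.0, 460.0),
    within=ClusterDispersion(10.0, 0.5, 8.0, 0.05),
)
cohort, truth = rc.generate_cohort(spec)
print(f"{len(cohort)} subjects, {cohort[0].n_epochs} epochs each "
      f"({int(cohort[0].labels.sum())} targets)")

erps = [rc.coherent_average(ep) for ep in cohort]
counts, _ = rc.match_counts(erps, threshold=0.5)
print("mean cosine match count:", round(np.mean(list(counts.values())), 2))

car = rc.evaluate_model(cohort, "car", n_donors=5, calibration_blocks=1, seed=0)
rnd = rc.evaluate_model(cohort, "random", n_donors=5, calibration_blocks=1,
                        reps=5, seed=0)
cmp = rc.compare_models(car, rnd)
print(f"mean AUC  CAR: {car.mean_auc:.3f}   random: {rnd.mean_auc:.3f}")
print(f"paired t = {cmp.t_stat:.2f}, p = {cmp.p_value:.2e}")

t = rc.selection_time(spec.paradigm)
print(f"ITR at P=0.95: {rc.compute_itr(26, 0.95, t).bits_per_minute:.2f} bits/min")
```

prints

```
12 subjects, 3120 epochs each (120 targets)
mean cosine match count: 5.0
mean AUC  CAR: 0.916   random: 0.872
paired t = 8.33, p = 4.44e-06
ITR at P=0.95: 6.43 bits/min
```

Twelve subjects fall into two P300-latency clusters (300 vs 460 ms). Each
subject's target ERP matches five others at the 0.5 cosine threshold — their
cluster mates. Picking the 5 donors by correlation rank instead of at random
lifts mean cross-subject AUC from 0.872 to 0.916; the paired t-test over the
12 test subjects confirms the gain. At 95 % symbol accuracy the 26-class
speller with a 39 s selection (5 rounds × 26 symbols × 300 ms SOA) transfers
6.43 bits/min.

## Command line

Every stage is also a subcommand of `rsvpcar`: `simulate`, `preprocess`
(EDF + events sidecar), `erp`, `similarity`, `evaluate`, `itr`, and `run`,
which executes the whole pipeline from a JSON config and writes similarity
matrices, a tidy AUC table, an AUC-vs-N summary, ITR results and a
provenance log, all stamped with the config hash. Example:

```
rsvpcar simulate --subjects 24 --clusters 2 --seed 1 --out cohort/
rsvpcar similarity --cohort cohort/cohort_manifest.json --metric cosine --out sim.tsv
rsvpcar evaluate --cohort cohort/cohort_manifest.json --model car -N 5 --out eval.tsv
rsvpcar itr -N 26 -P 0.9 -T 0.65
```

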