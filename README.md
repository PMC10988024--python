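# neuralign

Multiset canonical correlation analysis (MCCA) of multi-subject, band-limited
sensor recordings, for studies that track **neural alignment** — the degree to
which different listeners' brain signals rise and fall together while they
receive the *same* naturalistic stimulus stream — and relate it to behavioral
change.

The package targets the design used in intervention electrophysiology:
several groups of subjects (e.g. an intervention group and two controls)
listen to a fixed sequence of ~22 auditory statements (≈9 minutes) while
multichannel activity is recorded; alignment is analyzed per frequency band
(delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–12 Hz) and per intervention timeslot
(beginning / middle / end thirds of the pause-free recording), and compared
with per-statement agreement ratings and pre/post questionnaire scales.
Because raw recordings of this kind usually cannot be shared, the package
ships a synthetic-data generator that plants the latent structure the
analysis assumes — so every stage is testable end to end without access to
human data.

## The model

For M subjects with standardized channel-by-time matrices X₁…X_M, MCCA finds
one spatial filter wᵢ per subject such that the component time-series
yᵢ = wᵢᵀXᵢ are maximally correlated *between* subjects. Stacking
v = (w₁, …, w_M), the fit solves the generalized eigenproblem

    R v = λ D v,

with R the full block matrix of within- and cross-subject covariances and D
the block diagonal of ridge-regularized within-subject covariances. With
filters normalized to unit component variance, λ = 1 + (M−1)·ρ̄ where ρ̄ is
the mean pairwise train correlation; for M = 2 the problem is classical CCA.
The top component is additionally refined to the exact maximizer of the sum
of pairwise correlations (SUMCOR, Horst iteration). Each filter's
interpretable counterpart is its activation pattern a ∝ Cw — the sensor
topography one would localize.

The group statistic is the cross-validated **intersubject correlation
(ISC)**: filters are fitted on two of three contiguous time folds, the
held-out fold is projected, and the component with the highest mean *test*
ISC (mean pairwise Pearson correlation) is selected. Significance comes from
a **circular bootstrap**: each subject's series is rotated by an independent
random offset — preserving its autocorrelation, destroying alignment — and
p = (1 + #{null ≥ observed}) / (B + 1). Group-level inference uses a
split-plot (mixed) ANOVA of individual ISCs over groups × timeslots, and
individual ISCs are correlated with questionnaire T2−T1 changes under
Benjamini–Hochberg FDR correction.

## Worked example

```python
from neuralign import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    simulation=SimulationConfig(
        group_sizes=(5, 5, 5), n_channels=8, sampling_rate=100.0,
        n_statements=6, statement_duration_range=(4.0, 6.0),
        shared_snr_schedule=((0.0, 0.0, 0.5), (0, 0, 0), (0, 0, 0)),
    ),
    bands=("delta",), n_components=4, n_bootstrap=200, seed=11,
    output_dir="scratch/smoke",
)
report = run_pipeline(cfg)
for slot in ("beginning", "middle", "end"):
    cell = report.summary["group_isc"][f"paradoxical/delta/{slot}"]
    boot = report.summary["bootstrap"][f"paradoxical/delta/{slot}"]
    print(slot, cell["group_isc"], boot["p_value"])
```

prints (seed 11):

```
beginning -0.006909 0.547264
middle 0.0595 0.079602
end 0.127035 0.004975
```

The simulation planted a shared source only in the last timeslot of the
first group (per-channel SNR 0.5): the end-slot cross-validated ISC (0.13)
dwarfs the earlier slots and is the only one the circular bootstrap calls
significant (p ≈ 0.005, the attainable minimum at B = 200 being
1/201 ≈ 0.005). The same run's `summary.json` carries the mixed-ANOVA table:
at this toy size (5 subjects per group) the omnibus group × time interaction
stays below threshold (F(4, 24) = 1.48, p = 0.24), while the per-group
repeated-measures follow-up flags a time effect exactly in the group with
the planted build-up (F(2, 8) = 12.46, p = 0.0035) and in neither control —
plus the FDR-corrected ISC-questionnaire correlations.

The same analysis is scriptable from a shell:

```
neuralign simulate --config cfg.yaml --out data/ --seed 1
neuralign run --config cfg.yaml --out results/ --seed 1
```

(verbs `preprocess`, `fit`, `isc`, `bootstrap`, `stats` expose the individual
stages).

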