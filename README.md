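# hippomeg

**Probabilistic detection of hippocampal engagement in MEG through Bayesian
comparison of anatomical generative models.**

The hippocampus is deep (its centroid sits ~8.7 cm from the nearest MEG
sensor at full scale), curved, and wrapped in neocortex, so claims of
hippocampal MEG signals based on where an activation peak lands are easy
to dispute.  `hippomeg` takes the model-comparison route instead: build
two generative models of the same sensor data — one supporting current
flow on the cortical surface only, one on cortex *plus* the hippocampal
surface — invert both under empirical-Bayes covariance priors, and ask
which model has the higher variational free energy *F*, a lower bound on
the log model evidence that rewards fit and penalizes complexity.

The decision statistic is the anatomical free-energy difference

    dF = F_combined − F_cortical,      p(combined | data) = 1 / (1 + e^(−dF)),

with dF > 3 (odds > e³ ≈ 20:1) read as decisive.  Because the framework
is simulation-based, it also quantifies when the inference breaks:
co-registration error between the functional and anatomical frames, and
sensor-level SNR.  Group-level reliability uses random-effects Bayesian
model selection (a Dirichlet posterior over model frequencies) and the
Bayes Omnibus Risk (BOR < 0.05 rejects "the models are equally frequent").

Everything runs on self-generated synthetic fixtures: a cortex-like
hemispheric shell and a nested hippocampus-like tube with matched vertex
spacing, a 274-channel axial-magnetometer helmet, and a closed-form
spherical-conductor (Sarvas) lead field.  Three covariance-prior schemes
are implemented: MNE (identity), EBB (beamformer variances derived from
the data) and MSP (100 sparse patch priors).  See `docs/methods.md` for
the model, parameters and limitations.

## Worked example

Thirty hippocampal patch sources (20 nAm, 6 mm FWHM, 20 Hz for 300 ms)
at SNR −5 dB, no co-registration error, inverted with EBB under both
anatomical models:

```python
from hippomeg import experiments as exp, compare as cmp

cfg = exp.ExperimentConfig(schemes=("EBB",), n_sims_per_cell=10, master_seed=7)
table = exp.run_grid(cfg)                 # one row per (dataset, scheme, model)
delta = exp.delta_f_table(table)          # per-dataset dF and posterior prob
print(delta[["dataset", "delta_F", "posterior_prob_combined"]].head())
print("mean dF = %.2f nats" % delta.delta_F.mean())

F = table.pivot_table(index="dataset", columns="anatomy", values="F")
bms = cmp.rfx_bms(F[["combined", "cortical"]].to_numpy())
print("P(combined wins) = %.3f, BOR = %.2e" % (bms.prob_combined_wins, bms.bor))
```

prints

```
 dataset  delta_F  posterior_prob_combined
       0    8.771                      1.0
       1   13.642                      1.0
       2   25.970                      1.0
       3   18.356                      1.0
       4   24.409                      1.0
mean dF = 15.09 nats
P(combined wins) = 1.000, BOR = 1.06e-02
```

Every simulated dataset decisively favours the model that includes the
hippocampus (dF ≫ 3), the random-effects analysis says a randomly drawn
dataset would almost surely be explained better by the combined model,
and BOR ≈ 0.01 < 0.05 rejects the hypothesis that the two models are
interchangeable.  Running the matching *cortical* control
(`structures=("cortical",)`) gives mean |dF| < 3: the extra hippocampal
vertices do not bias the comparison when the source is not hippocampal.

The same pipeline is scriptable from a shell:

```sh
hippomeg fixtures --preset desk --seed 1 --out fixtures/   # meshes + sensors
hippomeg grid --seed 1 --scheme EBB --snr -5 --coreg 0 --out out/
hippomeg bms out/grid.csv --out out/                       # group statistics
hippomeg neighbours / shifts / mixture ...                 # control batteries
```

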