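# fishgrowth

Growth modelling for river fish populations from three kinds of field
data, built around the study design used for European grayling
(*Thymallus thymallus*) in a large alpine river:

1. **age-at-length** from scale annuli → von Bertalanffy growth model
   (vBGM), fitted by frequentist nonlinear least squares *and* by a
   Bayesian model with literature-informed priors;
2. **mark–recapture length increments** from PIT-tagged fish → the
   Fabens reparameterisation of the vBGM (no individual ages needed);
3. **length-frequency time series** from seasonal electrofishing →
   ELEFAN (electronic length-frequency analysis) driven by a genetic
   algorithm, with bootstrap confidence intervals.

All pathways estimate the parameters of

    L(t) = L∞ (1 − e^(−K (t − t0))) + ε,   ε ~ Normal(0, σ)

where `L∞` is the mean asymptotic length (mm), `K` the Brody growth
coefficient (1/yr) and `t0` the nominal age at zero length. The point
of running all three on one population is diagnostic: the pathways fail
differently. Age-based NLS explodes when old fish are missing or
under-aged; the Bayesian version stays reasonable under the same data;
increment data identify (L∞, K) without any ageing; ELEFAN needs large
individuals and otherwise rides the L∞–K trade-off.

The package also ships seeded generators for all three dataset types
(`fishgrowth.simulate`), emulating a 25-event, nine-year monitoring
programme, used throughout the tests as ground-truth recovery studies.

## Worked example

The `analysis/` scripts run the full study on synthetic data. With
seed 1:

```sh
python analysis/01_simulate_data.py --seed 1     # writes results/data/
python analysis/04_fit_mark_recapture.py --seed 1
```

prints

```
Fabens frequentist  L_inf  514.88 mm (495.12-538.01), K 0.423/yr
Fabens Bayesian     L_inf  516.19 mm (496.13-538.80), K 0.418/yr
asymptotic-length agreement between modes: 0.3%
```

i.e. on a well-designed tagging sample (121 pairs, recapture intervals
of 0.09–1.01 yr) the frequentist and Bayesian increment fits are nearly
congruent, and both recover the generating asymptote (536.8 mm) within
the quoted intervals. `03_fit_age_length.py` shows the same agreement
for the age-based model on a healthy age sample, `02_cohort_structure.py`
summarises per-cohort length ranges, `05_fit_length_frequency.py` runs
the ELEFAN bootstrap, and `06_compare_models.py` produces the five-row
comparison table plus overlay growth curves (t0 set to zero for
comparability across methods).

The same functionality is available as a CLI
(`fishgrowth simulate|fit-vbgm|fit-fabens|fit-elefan|compare`) for use
on real CSV data; formats are documented in `fishgrowth/io.py`.

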