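# cirs — phase-space analysis of post-transplant immune reconstitution

Immune recovery after allogeneic hematopoietic stem cell transplantation
(allo-HSCT) is highly variable between patients, and that variability
carries prognosis. `cirs` implements a complete, testable pipeline for
turning longitudinal multivariate blood immune profiles into a validated
mortality risk stratification:

1. **Phase space.** Every blood draw is a 20-feature *immune profile*
   (six CBC counts, eight flow-cytometry fractions, six derived subset
   counts). All profiles are min–max rescaled and embedded into a 2-D
   plane with t-SNE, so a patient's reconstitution becomes a trajectory.
   Axis meaning is quantified by the planar regression
   φ(x, y) = c + αx + βy + ε per feature; population kinetics by a
   100-sample bootstrap average trajectory over day windows of width
   δt = 30 (0 < t ≤ 90), 90 (90 < t ≤ 360), or 180 days (t > 360).
2. **Anchor discovery.** A 121×121 grid is overlaid on the plane. For a
   candidate period (days 1–90, 91–180, 181–270, 271–360), each grid
   point splits patients into those *near* it (any in-window profile
   within the nearness radius) and those not, and a univariate Cox model
   of death after the period-end landmark is fitted on that label
   (Efron ties, likelihood-ratio p). Grid points with p < .01 and HR > 1
   are *anchor points*; a patient near any anchor carries the
   **high-risk composite immune signature**. Periods are screened by
   ten-fold cross-validation inside the training split; anchors and all
   downstream models are fitted on the training split only.
3. **Composite Immune Risk Score.** The signature is distilled into a
   linear score by forward-and-backward stepwise logistic regression
   (AIC). The fixed published score is included:

   ```
   CIRS = WBC (10⁹/L) × 0.7304 + neutrophils (10⁹/L) × (−0.4745)
        + lymphocyte % of nucleated cells × (−16.7825)
        + lymphocytes (10⁹/L) × (−1.7612)
        + NK % of lymphocytes × (−7.9450) + T % × 10.2955
        + CD4⁺ T % × (−7.9703) + B % × (−15.7887)
   ```

   with fractions as proportions in [0, 1]; a patient whose mean score
   during days 91–180 is **strictly greater than 2.50** is high-risk.
4. **Validation.** Kaplan–Meier stratification with log-rank tests,
   landmark multivariate Cox models, Aalen–Johansen cumulative incidence
   and Fine–Gray subdistribution hazards per death cause (IPCW-weighted
   Cox formulation), and a logistic model for clinical predictors of a
   high score.

Because the underlying patient data are restricted, the package ships a
**synthetic cohort generator** with planted ground truth: saturating
recovery kinetics per cell lineage with patient-level rate and level
random effects, a latent "derailed" subgroup whose lymphoid recovery
collapses (placing it in a distinct phase-space region) and whose death
hazard is multiplied by a known ratio, exponential survival with
competing causes, and administrative censoring. Every discovery step is
tested by recovering the planted truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (2000 patients, 15 % derailed, true hazard ratio 3,
seed 0) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_embed_phase_space.py
python analysis/03_screen_periods.py
python analysis/04_discover_anchors.py
python analysis/05_fit_risk_score.py
python analysis/06_validate_survival.py
```

Representative output (seed 0):

```
days  91-180: pooled CV HR 2.08, p 5.96e-06 (passes the screen)
testable grid points: 8818 of 14641; anchors: 339 (n=986 training patients, 201 events)
against planted truth: sensitivity 0.833, specificity 0.930
  training: signature HR 3.34 (Cox p 1.22e-14, log-rank p 1.48e-18; n=986, events=201)
validation: signature HR 2.32 (Cox p 4.09e-04, log-rank p 1.07e-04; n=477, events=94)
      test: signature HR 2.09 (Cox p 1.10e-03, log-rank p 4.36e-04; n=453, events=101)
Fine-Gray subdistribution HRs (signature carriers vs not):
    exposure|infection_nrm: HR 2.80 (1.84-4.25), p 1.57e-06
logistic model for carrying the high-risk signature:
   severe_agvhd_100d: OR 3.17 (2.29-4.40), p 4.80e-12
```

Reading this: cross-validation singles out days 91–180 as carrying a
mortality signature; the anchor scan recovers the planted derailed
region (sensitivity 0.83, specificity 0.93 against the latent flag); the
signature's hazard ratio replicates in the untouched validation and test
splits near the planted value of 3; carriers die disproportionately of
infection-related non-relapse causes; and early severe aGVHD predicts
carrying the signature.

The same steps run as one command with a machine-readable report:

```bash
cirs run-all --seed 0 --out results/run
```

### Calculator mode

The published score for a single patient, from the shell:

```bash
cirs score --wbc 6.4 --neut 4.2 --lymph-frac-nuc 0.22 --lymph 1.4 \
           --nk-frac 0.18 --t-frac 0.62 --cd4-frac 0.21 --b-frac 0.08
# score = -1.4599  ->  low-risk (threshold 2.5)

cirs score --wbc 9.5 --neut 6.0 --lymph-frac-nuc 0.08 --lymph 0.5 \
           --nk-frac 0.05 --t-frac 0.85 --cd4-frac 0.10 --b-frac 0.01
# score = 9.2676  ->  high-risk (threshold 2.5)
```

A high score reflects the lymphopenic, myeloid-dominated profile of a
derailed reconstitution: leukocytosis with a low lymphocyte fraction,
low NK/CD4/B proportions and a correspondingly inflated total-T share.

`--percent` accepts cytometry values on the 0–100 scale. A CSV of
patients can be scored with `cirs score --csv patients.csv --out scored.csv`.

## Layout

```
src/cirs/        library: cohort model, simulator, embedding, anchor scan,
                 risk score, survival validation, pipeline, CLI
analysis/        numbered narrative drivers over the library
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
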