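# petkin

Compartmental kinetic analysis of dynamic brain PET with an arterial
input function, built around the quantification problem posed by
[¹¹C](R)-PK11195, a radioligand for the 18-kDa translocator protein
(TSPO) expressed by activated microglia.  TSPO imaging is used to follow
neuroinflammation, but quantifying [¹¹C](R)-PK11195 is hard: uptake is
low, plasma metabolites accumulate, and there is no reference region
truly devoid of binding.  The package implements the full
arterial-input quantification chain for such a tracer — input-function
construction with metabolite and dispersion correction, one- and
two-tissue compartment fitting, Logan graphical analysis, outcome
measures, model selection, and test–retest reliability statistics —
together with a synthetic-study generator that emulates a six-subject
test–retest design, so every stage is testable without access to raw
scanner data.

It is aimed at imaging scientists and methodologists who want a
transparent, scriptable reference implementation of "classical" PET
kinetic analysis rather than a GUI workstation tool.

## The model

Regional time–activity curves C(t) (kBq/cc, decay-corrected) are
described by the two-tissue compartment model

    dC_ND/dt = K1·Cp − (k2 + k3)·C_ND + k4·C_B
    dC_B/dt  = k3·C_ND − k4·C_B

driven by the metabolite-corrected arterial plasma curve Cp(t), with the
one-tissue model (K1, k2 only) as the nested alternative.  The measured
signal adds fractional blood volume V_B and a bolus time shift t_bolus:

    M(t) = (1 − V_B)·[h ⊛ Cp](t − t_bolus) + V_B·C_blood(t − t_bolus),

frame-averaged over the acquisition schedule (20 s × 9, 30 s × 6,
180 s × 5, 300 s × 5).  The convolution kernel h is the analytic
sum-of-exponentials impulse response; fits are bounded weighted
nonlinear least squares from fixed initial values (K1, k2, k3, k4 =
0.5, 0.1, 0.5, 0.5, all constrained to (0, 0.9] min⁻¹), with V_B and
t_bolus estimated once per scan by a six-parameter whole-brain fit and
then frozen for the regional fits.  A modified protocol couples several
regions in one fit sharing a single K1/k2 ratio.

Outcome measures follow the standard definitions

    V_T  = K1/k2 · (1 + k3/k4)        total distribution volume
    BP_ND = k3/k4                     binding potential
    %ID(t) = C(t) · V_brain / (dose · 1000) · 100

with Logan graphical analysis (slope of ∫Ct/Ct vs ∫Cp/Ct beyond
t* = 8 min) as the linear alternative for V_T.  Model choice uses the
Akaike criterion and the one-tailed F test; test–retest reliability uses
the symmetric percent error and the one-way intraclass correlation
ICC = (MS_BS − MS_WS)/(MS_BS + MS_WS) for two repeats.

## Worked example

Simulate a six-subject, two-scan cohort and analyse one scan:

```sh
$ petkin simulate --spec cohort.yaml --out fixtures --seed 42   # noise_scale: 0.2
wrote 12 scan(s) under fixtures

$ petkin fit --tacs fixtures/sub01_test/tacs.tsv --blood fixtures/sub01_test/blood.tsv
whole_brain: vt=1.216 bp_nd=3.45
grey_matter: vt=0.8861 bp_nd=1.541
white_matter: vt=0.606 bp_nd=0.7058

$ petkin logan --tacs fixtures/sub01_test/tacs.tsv --blood fixtures/sub01_test/blood.tsv
whole_brain: VT=0.7418 intercept=-1443.0 n=9 r2=0.98977
grey_matter: VT=0.7041 intercept=-995.4 n=9 r2=0.99747
white_matter: VT=0.5442 intercept=-778.7 n=9 r2=0.99907
```

This scan was generated with grey-matter truth BP_ND = 1.513 and
V_T = 0.865: the compartmental fit recovers them to within the noise
(1.541 / 0.886), while the Logan slope (0.704) sits below the
compartmental V_T, as expected for a slowly equilibrating tracer in a
finite window.  The whole-brain fit also recovered the generating blood
volume (fitted V_B = 0.0698 vs truth 0.0691) and bolus delay (6.46 s vs
6.43 s).  The full pipeline and the test–retest table come from one
config:

```sh
$ petkin run --config pipeline.yaml      # scan_dirs + out_dir
analysed 12 scan(s); results in out

$ petkin trt --results out/results.json --outcome bp_nd_2tcm
      region  test_mean  test_cv_pct  retest_mean  ...  error_pct_mean  error_pct_sd    icc
 grey_matter      1.912       35.466        1.904  ...           1.062        10.184  0.968
```

i.e. per-region test and retest group means with CV%, per-subject
percent errors, and the ICC.  `petkin verify` recomputes the published
worked-example arithmetic (binding-potential ratios, group means,
test–retest averages) and lists the table entries that are internally
inconsistent as printed:

```sh
$ petkin verify
ok  gm_test_subject1_bp_nd: computed 1.134 vs printed 1.13
ok  gm_test_subject4_bp_nd: computed 1.447 vs printed 1.45
...
note gm_test_subject2_bp_nd: printed value 1.86 is internally inconsistent (arithmetic gives 2.23)
```

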