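# lqrg

Radiobiological modelling of loco-regional tumor control after fractionated
radiotherapy, for medical physicists and modellers who want to connect
fractionation schedules to follow-up-time-dependent outcome curves.

Conventional radiobiology summarizes a schedule by the linear-quadratic
(LQ) cell kill `-alpha*D - beta*D*d` and a tumor control probability (TCP)
at a single time point. That machinery cannot track how loco-regional
progression-free survival (LPFS) evolves over years of follow-up. This
package implements an extended model, **LQRG**, whose log surviving
fraction

```
ln SF(t) = -alpha*D - beta*G(tau_R)*D^2 + (sigma^2/2)*G(tau_S)*D^2
           + ln2 * max(0, T - T_k)/tau_P + (ln2 * t/tau_P)^delta
```

adds the four "R"s — repair (Lea-Catcheside factor `G(tau_R)`),
redistribution + reoxygenation (resensitization variance `sigma^2` with
time constant `tau_S`), repopulation (doubling time `tau_P` after lag
`T_k`) — and Gompertzian post-treatment regrowth (exponent `delta`).
A Gaussian-threshold TCP, `1 - Phi((K_0*SF - K_cr)/sigma_k)`, turns
surviving-clonogen counts into control probability, and TCP(t) is fitted to
Kaplan-Meier LPFS curves by mean-absolute-error minimization. The classical
LQ model with a Poisson TCP is included as the baseline, plus the
biologically effective dose `BED = -ln SF(0)/alpha`, the effective
`beta_eff` recasting, a surrogate likelihood / AIC / leave-one-out
comparison, and a synthetic-cohort generator so the whole pipeline runs
without any patient data.

## Worked example

Protraction factors and BED for three treatment groups known by their
summary statistics (mean GTV dose / median fraction size:
62.92 Gy / 2.1 Gy, 64.07 Gy / 2.4 Gy, 62.89 Gy / 2.8 Gy):

```python
from lqrg import group_representative_schedule, lea_catcheside_G, bed_lqrg, LQRGParams

sched = group_representative_schedule(62.89, 2.8)   # 22 fx, weekdays
print(sched.n_fractions, round(lea_catcheside_G(sched, 6.32), 4),
      round(bed_lqrg(LQRGParams(), sched), 2))
# 22 0.0471 90.42
```

`python examples/dose_protraction.py` prints all three groups:

```
group    n  D (Gy)  OTT (wk)  G(tau_R)  G (1/n)
A       30   62.92      5.57    0.0346    0.033
B       27   64.07      5.14    0.0384    0.037
C       22   62.89      4.14    0.0471    0.045
```

`G(tau_R)` is the dose-protraction factor at the fitted 6.32 h repair time;
`G (1/n)` is its complete-inter-fraction-repair limit, the value the
classical LQ model uses. Fewer, larger fractions interact more (larger G),
and BED rises with fraction size (`examples/bed_and_beta_eff.py`:
81.94 / 86.42 / 90.42 Gy for groups A/B/C) — the radiobiological case for
hypofractionation in this setting.

End-to-end on synthetic data (`examples/simulate_fit_compare.py`):

```
simulated 103 patients (100 loco-regional events), 103 KM samples

model    k      MAE     logL       AIC
lq       5   0.1227     41.7     -73.5
lqrg     6   0.0535    127.1    -242.3
```

The LQRG fit halves the mean absolute error against the KM samples and
wins on AIC: classical LQ's exponential regrowth makes its TCP curve
collapse after ~20 months, while the Gompertz term lets LQRG track the
late, slowly decaying part of the survival curve. `examples/tcp_curves.py`
prints the curves themselves; both models order the groups C > B > A.

The same workflow is scriptable from the shell:

```sh
lqrg simulate --seed 7 --out cohort.csv
lqrg run --seed 7 --out results/        # KM + both fits + comparison bundle
lqrg g --schedule n=30,d=2.1,weekdays --tau 6.32
```

## Layout

| path | contents |
| --- | --- |
| `src/lqrg/schedule.py` | fractionation schedules, group-representative builder |
| `src/lqrg/lea_catcheside.py` | dose-protraction factor G(tau), closed forms + quadrature |
| `src/lqrg/cell_survival.py` | LQRG / LQ surviving fraction, BED, beta_eff |
| `src/lqrg/tcp.py` | Gaussian and Poisson/binomial TCP, TCP(t) curves |
| `src/lqrg/survival_curves.py` | Kaplan-Meier LPFS (lifelines), step sampling |
| `src/lqrg/model_fitting.py` | MAE cost, gradient-descent fitting, CIs |
| `src/lqrg/model_selection.py` | surrogate likelihood, AIC, leave-one-out CV |
| `src/lqrg/synthetic_cohort.py` | cohort generator (inverse-transform event times) |
| `src/lqrg/pipeline.py`, `cli.py` | one-command workflow and the `lqrg` CLI |

`docs/methods.md` documents the model assumptions, unit conventions,
fitting choices and known limitations.
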