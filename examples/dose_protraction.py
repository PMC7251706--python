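"""Dose-protraction (Lea-Catcheside) factors for clinical schedules.

Builds the three group-representative schedules (conventional 2.1 Gy,
moderate 2.4 Gy and hypofractionated 2.8 Gy per fraction) and prints their
protraction factor G at the fitted repair time and in the complete-repair
limit. G scales the quadratic cell-killing term: larger G means more
interaction between fractions, i.e. stronger two-track killing.
"""

from lqrg import group_representative_schedule, lea_catcheside_G

GROUPS = {"A": (62.92, 2.1), "B": (64.07, 2.4), "C": (62.89, 2.8)}
TAU_REPAIR_H = 6.32

print(f"{'group':<6}{'n':>4}{'D (Gy)':>8}{'OTT (wk)':>10}"
      f"{'G(tau_R)':>10}{'G (1/n)':>9}")
for name, (dose, frac) in GROUPS.items():
    sched = group_representative_schedule(dose, frac)
    g_repair = lea_catcheside_G(sched, TAU_REPAIR_H)
    g_limit = lea_catcheside_G(sched, 1e-6)
    print(f"{name:<6}{sched.n_fractions:>4}{sched.total_dose_gy:>8.2f}"
          f"{sched.overall_time_weeks:>10.2f}{g_repair:>10.4f}{g_limit:>9.3f}")

print()
print("G(tau_R) with a 6.32 h repair time exceeds the complete-repair limit")
print("1/n: overnight repair is nearly, but not exactly, complete, and the")
print("residual interaction grows as fewer, larger fractions are used.")
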