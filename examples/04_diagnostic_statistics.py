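"""Diagnostic agreement statistics for localization-vs-outcome data.

Given per-patient localization concordance (CC = the map alone localized
inside the surgical field) and seizure outcome (Engel IA = seizure-free),
compute the 2x2 confusion table, sensitivity/specificity/PPV/NPV with
Clopper-Pearson CIs, Cohen's kappa, and McNemar's exact test between two
methods.
"""

from cbmpet import CC, DC, PC, build_confusion, cohens_kappa, diagnostics, mcnemar_from_calls

# a 42-patient cohort: 31 seizure-free, 11 not
outcomes = [True] * 31 + [False] * 11
cbm_calls = [CC] * 27 + [PC] + [DC] * 3 + [CC] + [DC] * 10
tmap_calls = [CC] * 15 + [DC] * 16 + [CC] * 3 + [DC] * 8

for name, calls in (("surface z-map", cbm_calls), ("voxel t-map", tmap_calls)):
    table = build_confusion(calls, outcomes)
    d = diagnostics(table)
    kappa, p = cohens_kappa(table)
    print(f"{name}: confusion (tp, fp, fn, tn) = {table.as_tuple()}")
    print(f"  sensitivity {d['sensitivity']['value']:.3f} "
          f"({d['sensitivity']['ci'][0]:.3f}-{d['sensitivity']['ci'][1]:.3f}), "
          f"specificity {d['specificity']['value']:.3f}")
    print(f"  PPV {d['ppv']['value']:.3f}, NPV {d['npv']['value']:.3f}, "
          f"kappa {kappa:.3f} (p = {p:.3g})")

p = mcnemar_from_calls(cbm_calls, tmap_calls)
print(f"McNemar exact p between methods: {p:.4g}")
print("Kappa near 0.7 indicates substantial agreement between unaided")
print("localization and surgical outcome; near 0.15, only slight agreement.")
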