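"""The four QA assessments on small worked datasets.

Stability (percent deviation against a ±10% threshold), sensitivity
(contrast response linear in 256/DR; monotone DOP-vs-power trend),
repeatability (intra-/inter-operator coefficients of variation), and the
semi-automated success rate.
"""

import sonoqa as sq

# stability: gray-map change moved a contrast slope from 5.00 to 5.23 gray/dB
t = sq.stability_test("contrast_linear", 5.00, 5.23, "gray map D->A")
print(f"stability: {t.percent_deviation:+.1f}% deviation -> {t.verdict}")

# sensitivity: contrast response at three dynamic ranges vs predicted 256/DR
fit = sq.sensitivity_linear_fit([48.0, 69.0, 90.0], [5.41, 3.78, 2.80])
print(f"sensitivity (256/DR): slope {fit.fit[0]:.3f}, r² {fit.fit[2]:.4f}, "
      f"p {fit.fit[3]:.2g} -> {fit.verdict}")

# sensitivity: DOP should fall as output power falls
print("DOP vs power:",
      sq.trend_verdict([100, 50, 20], [10.0, 9.6, 9.0], "decrease"))

# repeatability: four operators, two sessions each
rep = sq.repeatability({"A": [9.9, 10.1], "B": [10.0, 10.0],
                        "C": [10.2, 10.0], "D": [9.8, 10.0]})
for op, values, cv in rep.per_operator:
    print(f"operator {op}: values {values} -> intra CV {cv:.2f}%")
print(f"inter-operator CV: {rep.inter_cv:.2f}%")

# success rate: 12 of 27 measurements completed without manual help
sr = sq.success_rate(["auto"] * 12 + ["manual"] * 15)
print(f"semi-automated success rate: {sr.n_auto}/{sr.n_total} = {sr.rate:.1%}")
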