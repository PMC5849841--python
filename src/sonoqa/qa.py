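"""QA assessment statistics: stability, sensitivity, repeatability, success.

Four assessments are applied to any of the imaging measurements:

* **Stability** — a measurement should not change when acquisition
  parameters unrelated to it (overall gain, gray map, ...) are changed.
  Deviation is the signed percent error from the baseline value; a deviation
  within ±10% (inclusive) passes by default.
* **Sensitivity** — a measurement should follow physics when related
  parameters change: DOP falls with output power, in-plane resolution
  improves with transmit frequency, and contrast response is linear in
  256/DR for an 8-bit display.
* **Repeatability** — intra- and inter-operator coefficients of variation
  (CV, sample standard deviation over mean, in percent) across repeated
  sessions.
* **Success rate** — the fraction of semi-automated measurements that needed
  no manual intervention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RepeatabilityResult",
    "SensitivityTest",
    "StabilityTest",
    "SuccessRateResult",
    "coefficient_of_variation",
    "percent_deviation",
    "repeatability",
    "sensitivity_linear_fit",
    "stability_test",
    "stability_verdict",
    "success_rate",
    "trend_verdict",
]


def percent_deviation(measured: float, baseline: float) -> float:
    """Signed percent error from the baseline: ``100·(measured−baseline)/baseline``.

    Note this is baseline-referenced: swapping the arguments does not negate
    the result.
    """
    if baseline == 0:
        raise ValueError("baseline value is zero; percent deviation undefined")
    return 100.0 * (measured - baseline) / baseline


def stability_verdict(deviation_pct: float, threshold_pct: float = 10.0) -> str:
    """'pass' iff |deviation| ≤ threshold (the ±threshold boundary passes)."""
    if threshold_pct <= 0:
        raise ValueError("threshold must be > 0")
    return "pass" if abs(deviation_pct) <= threshold_pct else "fail"


@dataclass
class StabilityTest:
    """One stability comparison: a measurement repeated after changing a
    parameter that should not affect it."""

    measurement_id: str
    baseline_value: float
    variant_value: float
    changed_parameter: str
    threshold: float = 10.0
    percent_deviation: float = field(init=False)
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.percent_deviation = percent_deviation(self.variant_value, self.baseline_value)
        self.verdict = stability_verdict(self.percent_deviation, self.threshold)


def stability_test(
    measurement_id: str,
    baseline_value: float,
    variant_value: float,
    changed_parameter: str,
    threshold: float = 10.0,
) -> StabilityTest:
    """Convenience constructor for :class:`StabilityTest`."""
    return StabilityTest(measurement_id, baseline_value, variant_value,
                         changed_parameter, threshold)


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 · sample SD (n−1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean; coefficient of variation undefined")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass
class RepeatabilityResult:
    """Intra- and inter-operator repeatability."""

    per_operator: list[tuple[str, list[float], float]]  # (id, values, intra CV %)
    inter_cv: float | None  # % over operator means; None with one operator
    n_sessions: int
    inter_method: str = "means"


def repeatability(sessions: dict[str, list[float]], inter_method: str = "means") -> RepeatabilityResult:
    """Repeatability from per-operator value lists.

    Intra-operator CV is computed per operator.  The inter-operator CV is, by
    default, the CV of the operator means (``inter_method='means'``); a pooled
    alternative (``'pooled'``: CV of all values together) is available.  With
    a single operator the inter-CV is absent, with a warning.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    per_operator = []
    for op, values in sessions.items():
        per_operator.append((str(op), [float(v) for v in values],
                             coefficient_of_variation(values)))
    n_sessions = max(len(v) for _, v, _ in per_operator)
    if len(per_operator) < 2:
        warnings.warn("single operator: inter-individual CV unavailable", stacklevel=2)
        inter = None
    elif inter_method == "means":
        inter = coefficient_of_variation([float(np.mean(v)) for _, v, _ in per_operator])
    elif inter_method == "pooled":
        inter = coefficient_of_variation([x for _, v, _ in per_operator for x in v])
    else:
        raise ValueError("inter_method must be 'means' or 'pooled'")
    return RepeatabilityResult(per_operator=per_operator, inter_cv=inter,
                               n_sessions=n_sessions, inter_method=inter_method)


@dataclass
class SensitivityTest:
    """Outcome of a sensitivity check: does the measurement follow the
    expected trend when a related parameter changes?"""

    parameter_values: list[float]
    measurements: list[float]
    expected_direction: str  # increase | decrease | linear
    verdict: str  # follows | flat | contradicts
    predictor: list[float] | None = None  # e.g. 256/DR for contrast response
    fit: tuple[float, float, float, float] | None = None  # slope, intercept, r², p


def sensitivity_linear_fit(
    dynamic_ranges, contrasts, alpha: float = 0.05
) -> SensitivityTest:
    """Linearity of contrast response versus the predicted 256/DR.

    For an 8-bit display the predicted contrast response at dynamic range DR
    is 256/DR gray levels per dB, so measured responses at several DR values
    should fall on a rising line against 256/DR.  Verdict is ``follows`` when
    the OLS slope is positive and significant at ``alpha``, ``contradicts``
    when significantly negative, ``flat`` otherwise.
    """
    dr = np.asarray(dynamic_ranges, dtype=float)
    y = np.asarray(contrasts, dtype=float)
    if dr.size != y.size:
        raise ValueError("dynamic_ranges and contrasts must have the same length")
    if np.unique(dr).size < 3:
        raise ValueError("need at least 3 distinct dynamic-range values")
    x = 256.0 / dr
    if np.ptp(y) == 0:
        fit = (0.0, float(y.mean()), 0.0, 1.0)
        verdict = "flat"
    else:
        res = stats.linregress(x, y)
        fit = (float(res.slope), float(res.intercept),
               float(res.rvalue) ** 2, float(res.pvalue))
        if fit[3] < alpha:
            verdict = "follows" if fit[0] > 0 else "contradicts"
        else:
            verdict = "flat"
    return SensitivityTest(
        parameter_values=[float(v) for v in dr],
        measurements=[float(v) for v in y],
        expected_direction="linear",
        verdict=verdict,
        predictor=[float(v) for v in x],
        fit=fit,
    )


def trend_verdict(
    parameter, measurements, expected_direction: str, flat_band_pct: float = 5.0
) -> str:
    """Qualitative trend check for a monotone expectation.

    The net change of the measurement relative to its first (baseline) value
    decides: within ±``flat_band_pct`` → ``flat``; sign matching
    ``expected_direction`` → ``follows``; otherwise ``contradicts``.  The
    parameter list must be strictly ordered (either direction) and the
    expected direction describes the measurement along the listed order.
    """
    p = np.asarray(parameter, dtype=float)
    m = np.asarray(measurements, dtype=float)
    if p.size != m.size or p.size < 2:
        raise ValueError("parameter and measurements must have equal length >= 2")
    dp = np.diff(p)
    if not (np.all(dp > 0) or np.all(dp < 0)):
        raise ValueError("parameter list must be strictly ordered")
    if expected_direction not in ("increase", "decrease"):
        raise ValueError("expected_direction must be 'increase' or 'decrease'")
    net = percent_deviation(m[-1], m[0])
    if abs(net) <= flat_band_pct:
        return "flat"
    observed = "increase" if net > 0 else "decrease"
    return "follows" if observed == expected_direction else "contradicts"


@dataclass
class SuccessRateResult:
    """Semi-automated measurement success accounting."""

    n_total: int
    n_auto: int

    @property
    def rate(self) -> float:
        return self.n_auto / self.n_total


def success_rate(outcomes) -> SuccessRateResult:
    """Fraction of measurements that completed automatically.

    ``outcomes`` is a list of 'auto'/'manual' method labels.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes supplied")
    bad = {o for o in outcomes if o not in ("auto", "manual")}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    return SuccessRateResult(n_total=len(outcomes),
                             n_auto=sum(1 for o in outcomes if o == "auto"))
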