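"""Quantification of spot-plating viability assays.

Covers the algebra of serial-dilution plating (CFU/ml from colony counts),
detectable ranges and the escape-frequency detection limit, censoring-aware
escape-frequency estimation against the NIH containment criterion (1e-8),
exponential growth kinetics (mu_max and doubling time), reporter
normalization (RFU/OD600), and the two-tailed pooled-variance t-test with
the usual significance-star convention.

Two plating schemes are built in as constructors: the *induced* scheme
(1 ml of culture concentrated into one step-0 spot, then 1:5 serial dilution
across eight steps, 15 ul spots) and the *non-induced* scheme (1:100
pre-dilution, then 1:10 serial dilution across eight steps, 15 ul spots).
With one colony at the extreme steps these give detectable ranges of
1.0-3.9e5 CFU/ml (induced) and 6.7e3-6.7e11 CFU/ml (non-induced), hence an
escape-frequency detection limit of 1.5e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: NIH guideline criterion for engineered-organism containment: escape
#: frequency at or below 1e-8 (inclusive).
NIH_ESCAPE_CRITERION = 1e-8

#: Countable band for a 15 ul spot: 1-50 colonies.  Manual counting has no
#: published band; a fixed one makes the estimator deterministic.
COUNT_MIN = 1
COUNT_MAX = 50

CENSOR_NONE = "none"
CENSOR_BELOW = "below_detection"
CENSOR_ABOVE = "above_range"


class GrowthFitError(RuntimeError):
    """No window of the growth curve met the linearity threshold."""


@dataclass(frozen=True)
class DilutionScheme:
    """Geometry of one serial-dilution spotting scheme.

    ``source_volume_ml`` is the volume of original culture represented by a
    single step-0 spot; ``pre_dilution_factor`` and ``step_ratio`` give the
    dilution applied before and at each serial step.
    """

    source_volume_ml: float
    pre_dilution_factor: float
    step_ratio: float
    n_steps: int = 8
    spot_volume_ml: float = 0.015
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("source_volume_ml", "pre_dilution_factor", "step_ratio",
                     "spot_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps < 0 or self.replicates < 1:
            raise ValueError("n_steps must be >= 0 and replicates >= 1")

    def dilution_factor(self, step: int) -> float:
        """Total dilution of the original culture at serial step ``step``."""
        if not 0 <= step <= self.n_steps:
            raise ValueError(f"step {step} outside [0, {self.n_steps}]")
        return self.pre_dilution_factor * self.step_ratio**step

    @classmethod
    def induced(cls) -> "DilutionScheme":
        """1 ml concentrated into one spot; 1:5 across eight steps."""
        return cls(source_volume_ml=1.0, pre_dilution_factor=1.0, step_ratio=5.0)

    @classmethod
    def uninduced(cls) -> "DilutionScheme":
        """15 ul spotted after 1:100 pre-dilution; 1:10 across eight steps."""
        return cls(source_volume_ml=0.015, pre_dilution_factor=100.0,
                   step_ratio=10.0)


@dataclass(frozen=True)
class SpotObservation:
    """One manually counted spot."""

    condition: str
    replicate: int
    step: int
    colony_count: int
    countable: bool = True

    def __post_init__(self) -> None:
        if self.colony_count < 0:
            raise ValueError("colony counts are non-negative integers")
        if self.step < 0:
            raise ValueError("step must be non-negative")


def cfu_per_ml(count: int, step: int, scheme: DilutionScheme) -> float:
    """CFU/ml of the original culture implied by ``count`` colonies at
    serial step ``step``."""
    if count < 0:
        raise ValueError("colony count must be non-negative")
    return count * scheme.dilution_factor(step) / scheme.source_volume_ml


def expected_spot_count(true_cfu_per_ml: float, step: int,
                        scheme: DilutionScheme) -> float:
    """Expected colonies in one spot at ``step`` for a given true CFU/ml;
    exact inverse of :func:`cfu_per_ml` at count 1."""
    return true_cfu_per_ml * scheme.source_volume_ml / scheme.dilution_factor(step)


def detectable_range(scheme: DilutionScheme) -> tuple[float, float]:
    """(min, max) CFU/ml detectable under the single-colony-at-extreme
    convention: one colony at step 0 and one colony at the last step."""
    return (cfu_per_ml(1, 0, scheme), cfu_per_ml(1, scheme.n_steps, scheme))


def detection_limit(induced: DilutionScheme,
                    uninduced: DilutionScheme) -> float:
    """Theoretical escape-frequency detection limit: minimum detectable
    induced CFU/ml over maximum detectable non-induced CFU/ml."""
    return detectable_range(induced)[0] / detectable_range(uninduced)[1]


@dataclass(frozen=True)
class CfuEstimate:
    """Point estimate of CFU/ml with a censoring flag."""

    value: float
    censored: str = CENSOR_NONE
    replicate_values: tuple[float, ...] = ()


def estimate_cfu(observations: Sequence[SpotObservation],
                 scheme: DilutionScheme,
                 count_min: int = COUNT_MIN,
                 count_max: int = COUNT_MAX) -> CfuEstimate:
    """Aggregate spot counts into one CFU/ml estimate.

    Per replicate the least-diluted spot with a count inside the countable
    band is converted via :func:`cfu_per_ml`; replicate values are averaged.
    A replicate whose spots are all zero is censored at the scheme's
    detectable minimum; a replicate with counts only above the band is
    censored at the detectable maximum.  The aggregate is flagged
    ``below_detection`` only when every replicate is, and ``above_range``
    when at least one replicate saturates and none is countable.
    """
    if not observations:
        raise ValueError("need at least one observation")
    rng_min, rng_max = detectable_range(scheme)
    by_rep: dict[int, list[SpotObservation]] = {}
    for obs in observations:
        if obs.step > scheme.n_steps:
            raise ValueError(
                f"step {obs.step} outside scheme with {scheme.n_steps} steps"
            )
        by_rep.setdefault(obs.replicate, []).append(obs)
    values: list[float] = []
    flags: list[str] = []
    for rep in sorted(by_rep):
        spots = sorted(by_rep[rep], key=lambda o: o.step)
        usable = [o for o in spots
                  if o.countable and count_min <= o.colony_count <= count_max]
        if usable:
            best = usable[0]  # least diluted countable spot
            values.append(cfu_per_ml(best.colony_count, best.step, scheme))
            flags.append(CENSOR_NONE)
        elif all(o.colony_count == 0 for o in spots):
            values.append(rng_min)
            flags.append(CENSOR_BELOW)
        else:
            values.append(rng_max)
            flags.append(CENSOR_ABOVE)
    if all(f == CENSOR_BELOW for f in flags):
        censored = CENSOR_BELOW
    elif CENSOR_ABOVE in flags and CENSOR_NONE not in flags:
        censored = CENSOR_ABOVE
    else:
        censored = CENSOR_NONE
    return CfuEstimate(
        value=float(np.mean(values)),
        censored=censored,
        replicate_values=tuple(values),
    )


@dataclass(frozen=True)
class EscapeEstimate:
    """Fraction viable (induced CFU / uninduced CFU) with censoring."""

    fraction_viable: float
    lower_bound: float
    upper_bound: float
    censored: str
    nih_pass: bool


def escape_frequency(
    induced: CfuEstimate | float,
    uninduced: CfuEstimate | float,
    induced_scheme: DilutionScheme | None = None,
) -> EscapeEstimate:
    """Escape frequency = induced CFU/ml divided by uninduced CFU/ml.

    A below-detection induced estimate propagates as an upper bound (the
    value reported is "<= bound", never zero).  ``lower_bound`` and
    ``upper_bound`` are the edges of the measurable escape range implied by
    the induced scheme's detectable range over the given denominator.
    ``nih_pass`` tests <= 1e-8 inclusive, evaluated on the reported value
    (for censored estimates that value is the bound).
    """
    induced_scheme = induced_scheme or DilutionScheme.induced()
    censored = CENSOR_NONE
    if isinstance(induced, CfuEstimate):
        censored = induced.censored
        induced_value = induced.value
    else:
        induced_value = float(induced)
    if isinstance(uninduced, CfuEstimate):
        uninduced_value = uninduced.value
    else:
        uninduced_value = float(uninduced)
    if uninduced_value <= 0:
        raise ValueError("uninduced CFU/ml must be positive")
    if induced_value < 0:
        raise ValueError("induced CFU/ml must be non-negative")
    rng_min, rng_max = detectable_range(induced_scheme)
    fraction = induced_value / uninduced_value
    return EscapeEstimate(
        fraction_viable=fraction,
        lower_bound=rng_min / uninduced_value,
        upper_bound=rng_max / uninduced_value,
        censored=censored,
        nih_pass=fraction <= NIH_ESCAPE_CRITERION,
    )


def stringency_fold(reference_freq: float, improved_freq: float) -> float:
    """Fold increase in containment stringency between two escape
    frequencies (reference / improved)."""
    if improved_freq <= 0:
        raise ValueError("improved frequency must be positive")
    return reference_freq / improved_freq


# ---------------------------------------------------------------------------
# growth kinetics


@dataclass(frozen=True)
class GrowthFit:
    """Maximum specific growth rate and its derived doubling time.

    ``doubling_time * mu_max == ln 2`` holds bit-exactly by construction.
    """

    mu_max: float
    doubling_time: float
    fit_window: tuple[int, int]
    r_squared: float

    @classmethod
    def from_mu(cls, mu_max: float, fit_window: tuple[int, int],
                r_squared: float) -> "GrowthFit":
        return cls(mu_max=mu_max, doubling_time=math.log(2) / mu_max,
                   fit_window=fit_window, r_squared=r_squared)


def doubling_time(mu_max: float) -> float:
    """ln 2 / mu_max, in the units of 1/mu_max."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    return math.log(2) / mu_max


def fit_growth(time: Sequence[float], od600: Sequence[float],
               min_points: int = 3,
               r2_threshold: float = 0.99) -> GrowthFit:
    """Estimate mu_max as the maximal slope of ln(OD600) over sliding
    windows of at least ``min_points`` points with r^2 >= ``r2_threshold``.

    Ties go to the earliest window (smallest start index, then smallest
    end).  Raises :class:`GrowthFitError` with diagnostics when no window
    meets the threshold.
    """
    t = np.asarray(time, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise ValueError("time and od600 must be 1-d series of equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(od <= 0):
        raise ValueError("OD600 values must be positive")
    y = np.log(od)
    best: tuple[float, int, int, float] | None = None  # (slope, i, j, r2)
    best_r2_seen = -np.inf
    n = len(t)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            xs, ys = t[i : j + 1], y[i : j + 1]
            if np.ptp(xs) == 0:
                continue
            if np.ptp(ys) == 0:
                slope, r2 = 0.0, 1.0
            else:
                res = stats.linregress(xs, ys)
                slope, r2 = res.slope, res.rvalue**2
            best_r2_seen = max(best_r2_seen, r2)
            if r2 < r2_threshold:
                continue
            if best is None or slope > best[0] + 1e-12:
                best = (slope, i, j, r2)
    if best is None:
        raise GrowthFitError(
            f"no window of >= {min_points} points reached r^2 >= "
            f"{r2_threshold} (best r^2 seen: {best_r2_seen:.4f})"
        )
    slope, i, j, r2 = best
    if slope <= 0:
        raise GrowthFitError(
            "best linear window has non-positive slope; series shows no "
            "exponential growth phase"
        )
    return GrowthFit.from_mu(mu_max=slope, fit_window=(i, j), r_squared=r2)


def specific_fluorescence(rfu: float, od600: float) -> float:
    """Reporter expression normalized to biomass: RFU / OD600."""
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return rfu / od600


def percent_difference(a: float, b: float) -> float:
    """|a - b| / b * 100, the percent deviation of ``a`` from reference ``b``."""
    if b == 0:
        raise ValueError("reference value must be non-zero")
    return abs(a - b) / abs(b) * 100.0


# ---------------------------------------------------------------------------
# significance


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    stars: str
    n_substituted: int = 0


def significance_stars(p: float) -> str:
    """Figure-caption star convention: * p<.05, ** p<.01, *** p<.001,
    **** p<.0001, else NS (strict inequalities)."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "NS"


def ttest_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float],
    log_transform: bool = False,
    detection_floor: float | None = None,
) -> TTestResult:
    """Two-tailed Student's (pooled-variance) t-test.

    For escape frequencies set ``log_transform=True``: values are compared
    on the log10 scale, and zero or negative entries (censored observations)
    are substituted with half the ``detection_floor`` before the transform
    so that logs stay finite; the number of substitutions is reported.
    Two identical constant groups return t=0, p=1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    n_sub = 0
    if log_transform:
        out = []
        for arr in (a, b):
            arr = arr.copy()
            mask = arr <= 0
            if mask.any():
                if detection_floor is None or detection_floor <= 0:
                    raise ValueError(
                        "log transform of non-positive values requires a "
                        "positive detection_floor"
                    )
                arr[mask] = detection_floor / 2.0
                n_sub += int(mask.sum())
            out.append(np.log10(arr))
        a, b = out
    df = len(a) + len(b) - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TTestResult(0.0, df, 1.0, "NS", n_sub)
    res = stats.ttest_ind(a, b, equal_var=True)
    t_stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(p):  # zero pooled variance, equal means
        t_stat, p = 0.0, 1.0
    return TTestResult(t_stat, df, p, significance_stars(p), n_sub)
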