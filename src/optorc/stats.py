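"""Significance machinery: two-proportion z-tests of PSTH bins against a
baseline, per-lag Welch t-tests of triggered averages against a control,
and onset/offset summaries of significance traces.

Tests are two-sided by default and no multiple-testing correction is
applied (per-bin p < alpha reporting); a Benjamini-Hochberg option is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidArgumentError
from .lnmodel import EmpiricalPSTH
from .revcorr import TriggeredAverage

__all__ = [
    "SignificanceTrace",
    "two_proportion_ztest",
    "ztest_valid",
    "psth_vs_baseline",
    "ta_vs_control_ttest",
    "onset_ttest",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class SignificanceTrace:
    """Per-bin p-values with normal-approximation validity flags and the
    first/last significant times (None when nothing is significant)."""

    times: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        p = np.asarray(self.p_values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if not (times.shape == p.shape == valid.shape):
            raise InvalidArgumentError("times, p_values and valid must have equal shapes")
        finite = p[np.isfinite(p)]
        if np.any((finite < 0) | (finite > 1)):
            raise InvalidArgumentError("p-values must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p_values", p)
        object.__setattr__(self, "valid", valid)

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.valid & np.isfinite(self.p_values) & (self.p_values < self.alpha)

    def _runs(self, sustain: int) -> list[tuple[int, int]]:
        """(start, stop) index pairs of runs of >= sustain significant bins."""
        sig = self.significant
        runs, start = [], None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            elif not s and start is not None:
                if i - start >= sustain:
                    runs.append((start, i - 1))
                start = None
        if start is not None and sig.size - start >= sustain:
            runs.append((start, sig.size - 1))
        return runs

    def onset_time(self, sustain: int = 1) -> float | None:
        """First time opening a run of >= sustain consecutive significant
        bins (valid bins only)."""
        runs = self._runs(sustain)
        return float(self.times[runs[0][0]]) if runs else None

    def offset_time(self, sustain: int = 1) -> float | None:
        """Last time closing a run of >= sustain consecutive significant
        bins (valid bins only)."""
        runs = self._runs(sustain)
        return float(self.times[runs[-1][1]]) if runs else None

    @property
    def onset(self) -> float | None:
        """First time with p < alpha (valid bins only)."""
        return self.onset_time(1)

    @property
    def offset(self) -> float | None:
        """Last time with p < alpha (valid bins only)."""
        return self.offset_time(1)


def two_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled-proportion z statistic and its normal p-value.

    ``z = (p1 - p2) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2))``.

    Raises
    ------
    DegenerateDataError
        If the pooled proportion is 0 or 1 (z undefined).
    """
    if n1 < 1 or n2 < 1:
        raise InvalidArgumentError("sample sizes must be at least 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise InvalidArgumentError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateDataError("pooled proportion is 0 or 1; z is undefined")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "larger":
        p = sps.norm.sf(z)
    elif alternative == "smaller":
        p = sps.norm.cdf(z)
    else:
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def ztest_valid(k1: int, n1: int, k2: int, n2: int) -> bool:
    """Normal-approximation validity: np >= 5 and n(1-p) >= 5 must hold
    in both groups (observed counts)."""
    return min(k1, n1 - k1) >= 5 and min(k2, n2 - k2) >= 5


def psth_vs_baseline(
    psth: EmpiricalPSTH,
    baseline: tuple[int, int],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    correct: bool = False,
) -> SignificanceTrace:
    """Per-bin two-proportion z-test of PSTH counts against a baseline
    (k, n) pair; degenerate bins propagate as invalid (p = NaN), not as
    failures.  ``correct=True`` applies Benjamini-Hochberg to the valid
    bins before thresholding."""
    k2, n2 = baseline
    if n2 < 1:
        raise InvalidArgumentError("baseline n must be at least 1")
    p_values = np.full(psth.times.size, np.nan)
    valid = np.zeros(psth.times.size, dtype=bool)
    for i, (k1, n1) in enumerate(zip(psth.k, psth.n)):
        if n1 < 1:
            continue
        try:
            _, p = two_proportion_ztest(int(k1), int(n1), int(k2), int(n2), alternative)
        except DegenerateDataError:
            continue
        p_values[i] = p
        valid[i] = ztest_valid(int(k1), int(n1), int(k2), int(n2))
    if correct:
        mask = np.isfinite(p_values)
        p_values[mask] = benjamini_hochberg(p_values[mask])
    return SignificanceTrace(times=psth.times, p_values=p_values, valid=valid, alpha=alpha)


def ta_vs_control_ttest(ta: TriggeredAverage, control: TriggeredAverage) -> np.ndarray:
    """Per-lag Welch t-test p-values between two triggered averages.

    Uses the per-lag means, standard deviations and event counts retained
    in each average.  Lags where either group has fewer than 2 events are
    NaN (invalid).
    """
    if ta.lags.shape != control.lags.shape or not np.allclose(ta.lags, control.lags):
        raise InvalidArgumentError("triggered averages must share one lag grid")
    if ta.n_events < 2 or control.n_events < 2:
        return np.full(ta.lags.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = sps.ttest_ind_from_stats(
            ta.mean, ta.sd, ta.n_events,
            control.mean, control.sd, control.n_events,
            equal_var=False,
        )
    return np.asarray(p, dtype=float)


def onset_ttest(onsets, popmean: float = 0.0) -> tuple[float, float]:
    """One-sample t-test of per-animal deceleration-onset times against a
    reference (default 0)."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        raise InvalidArgumentError("need at least 2 onset times")
    t, p = sps.ttest_1samp(onsets, popmean)
    return float(t), float(p)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out
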