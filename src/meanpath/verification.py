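"""Statistical verification of a transport engine against IP references.

The protocol: run N trajectories under Lambertian illumination of the
non-absorbing medium, form the sample mean <L>_MC and its standard
error sigma_<L> = sigma_L / sqrt(N), and t-test <L>_MC (and every
per-layer <L_k>_MC) against the closed-form invariance reference.  The
achievable accuracy scales as 1/sqrt(N), so any systematic error --
boundary treatment, entrance law, path accounting, or even RNG
granularity -- eventually surfaces as a significant t once N is large
enough.

No multiplicity correction is applied to the individual tests; instead
the report compares the observed number of 5%-level rejections with the
m * alpha expected by chance (exact binomial compatibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .invariance import IPReference, ip_partial_paths
from .transport import EnsembleTallies

__all__ = [
    "PathStats",
    "TestResult",
    "VerificationReport",
    "summarize",
    "summarize_layers",
    "one_sample_test",
    "expected_rejections",
    "path_length_histogram",
    "verification_report",
]


@dataclass(frozen=True)
class PathStats:
    """Sample moments of a path-length quantity (mm)."""

    n: int
    mean: float
    sd: float  # sigma_L, N-1 denominator

    @property
    def standard_error(self) -> float:
        """sigma_<L> = sigma_L / sqrt(N)."""
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    """One-sample t-test of a sample mean against an IP reference."""

    reference: float
    t: float
    p: float
    tails: str
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class VerificationReport:
    """t-test battery over the total path and every partial path."""

    labels: Tuple[str, ...]
    stats: Tuple[PathStats, ...]
    references: Tuple[float, ...]
    tests: Tuple[TestResult, ...]
    alpha: float
    n_capped: int
    ip_valid: bool
    ip_warnings: Tuple[str, ...]
    passed: bool
    rejection_pvalue: float

    @property
    def m(self) -> int:
        return len(self.tests)

    @property
    def expected_rejections(self) -> float:
        return self.m * self.alpha

    @property
    def observed_rejections(self) -> int:
        return sum(t.significant for t in self.tests)


def _moments(n: int, s: float, s2: float) -> PathStats:
    if n < 2:
        raise ValueError("need at least two trajectories for a standard deviation")
    mean = s / n
    var = (s2 - n * mean * mean) / (n - 1)
    return PathStats(n=n, mean=float(mean), sd=float(np.sqrt(max(var, 0.0))))


def summarize(tallies: EnsembleTallies) -> PathStats:
    """Sample mean, SD and standard error of the total path length."""
    return _moments(tallies.n, tallies.sum_L, tallies.sum_L2)


def summarize_layers(tallies: EnsembleTallies) -> List[PathStats]:
    """Per-region partial-path statistics."""
    return [
        _moments(tallies.n, s, s2)
        for s, s2 in zip(tallies.sum_lk, tallies.sum_lk2)
    ]


def one_sample_test(
    path_stats: PathStats,
    reference: float,
    tails: str = "two",
    alpha: float = 0.05,
) -> TestResult:
    """Student t-test of the sample mean against the IP reference.

    ``tails``: "two" for verification grids, "less" for one-sided bias
    detection (alternative: mean < reference).
    """
    se = path_stats.standard_error
    if se <= 0.0:
        raise ValueError("zero standard error: t statistic undefined")
    t = (path_stats.mean - reference) / se
    df = path_stats.n - 1
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tails == "less":
        p = stats.t.cdf(t, df)
    elif tails == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError("tails must be 'two', 'less' or 'greater'")
    return TestResult(reference=float(reference), t=float(t), p=float(p), tails=tails, alpha=alpha)


def expected_rejections(m: int, alpha: float) -> float:
    """Expected number of chance rejections among m independent tests."""
    if m < 0 or not (0.0 <= alpha <= 1.0):
        raise ValueError("need m >= 0 and alpha in [0, 1]")
    return m * alpha


def path_length_histogram(tallies: EnsembleTallies):
    """(bin_centers_mm, density_per_mm) estimate of PDF(L), normalized
    to unit integral over the binned support."""
    if tallies.histogram_counts is None:
        raise ValueError("run the ensemble with histogram_bins > 0")
    counts = tallies.histogram_counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty histogram")
    w = tallies.histogram_bin_width
    centers = (np.arange(counts.shape[0]) + 0.5) * w
    density = counts / (total * w)
    return centers, density


def verification_report(
    medium,
    tallies: EnsembleTallies,
    alpha: float = 0.05,
    tails: str = "two",
) -> VerificationReport:
    """Full t-test battery: total path plus every partial path.

    PASS requires (a) the observed rejection count to be binomially
    compatible with m * alpha at the 1% level and (b) zero capped
    trajectories.  An invalid IP configuration (n_k > n_e with
    mu_s = 0) is reported via warnings but does not abort.
    """
    ref = ip_partial_paths(medium)
    labels = ["total"] + [f"layer_{k}" for k in range(1, medium.n_layers + 1)]
    stats_rows = [summarize(tallies)] + summarize_layers(tallies)
    references = [ref.total] + list(ref.per_layer)
    tests = [
        one_sample_test(s, r, tails=tails, alpha=alpha)
        for s, r in zip(stats_rows, references)
    ]
    observed = sum(t.significant for t in tests)
    binom = stats.binomtest(observed, len(tests), alpha)
    passed = (binom.pvalue >= 0.01) and (tallies.n_capped == 0)
    return VerificationReport(
        labels=tuple(labels),
        stats=tuple(stats_rows),
        references=tuple(references),
        tests=tuple(tests),
        alpha=alpha,
        n_capped=tallies.n_capped,
        ip_valid=ref.valid,
        ip_warnings=ref.warnings,
        passed=bool(passed),
        rejection_pvalue=float(binom.pvalue),
    )
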