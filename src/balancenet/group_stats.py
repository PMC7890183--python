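"""Paired univariate and multivariate tests with Simes post-hoc control.

The study design is fully within-subject per group: each subject is
measured pre and post training, so every comparison reduces to a
one-sample test on the paired differences. The multivariate layer is the
one-sample Hotelling T-squared on the difference vectors, reported with
its Wilks' lambda equivalent ``lambda = (1 + T2/(n-1))^-1``; post-hoc
per-variable paired t-tests are controlled by the Simes procedure, which
is exact at level alpha under independence and avoids the
over-correction of Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

__all__ = [
    "PairedSample",
    "TestResult",
    "SimesResult",
    "paired_t",
    "paired_hotelling",
    "simes",
    "hotelling_family",
]


@dataclass
class PairedSample:
    """Matched pre/post measurements: subjects x variables, same row order."""

    pre: np.ndarray
    post: np.ndarray
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        self.post = np.atleast_2d(np.asarray(self.post, dtype=float))
        if self.pre.shape != self.post.shape:
            raise DataError("pre and post must have identical shape")
        if not self.variables:
            self.variables = tuple(f"v{i}" for i in range(self.pre.shape[1]))
        if len(self.variables) != self.pre.shape[1]:
            raise DataError("one variable label per column required")

    @property
    def n(self) -> int:
        return self.pre.shape[0]

    @property
    def p(self) -> int:
        return self.pre.shape[1]

    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass
class TestResult:
    """Outcome of one paired test (univariate t or Hotelling T2)."""

    statistic: float
    p_value: float
    df: tuple[int, ...]
    wilks_lambda: float | None = None
    post_hoc: pd.DataFrame | None = field(default=None, repr=False)


def paired_t(pre: np.ndarray, post: np.ndarray) -> TestResult:
    """Two-sided paired t-test on post - pre.

    Zero-variance, nonzero-mean differences are the degenerate
    perfectly-consistent shift: reported as an infinite statistic with
    p = 0 rather than an error.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.shape != post.shape or pre.size < 2:
        raise DataError("paired_t needs >= 2 matched pairs")
    d = post - pre
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, 1.0, (n - 1,))
        return TestResult(float(np.sign(d.mean()) * np.inf), 0.0, (n - 1,))
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(p), (n - 1,))


def paired_hotelling(sample: PairedSample) -> TestResult:
    """One-sample Hotelling T2 on the paired differences.

    ``T2 = n * dbar' S^-1 dbar`` with S the sample covariance of the
    differences; ``F = (n - p) / (p (n - 1)) * T2`` on (p, n - p) degrees
    of freedom; Wilks' lambda is ``(1 + T2 / (n - 1))^-1``.
    """
    n, p = sample.n, sample.p
    if n <= p:
        raise DataError(
            f"paired Hotelling needs n > p; got n={n}, p={p}"
        )
    d = sample.differences()
    if np.allclose(d, 0.0):
        # no change at all: T2 = 0, lambda = 1, p = 1 by definition
        return TestResult(0.0, 1.0, (p, n - p), wilks_lambda=1.0)
    dbar = d.mean(axis=0)
    s = np.cov(d, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    # guard: singular difference covariance has no T2
    if np.linalg.matrix_rank(s) < p:
        raise DataError(
            "singular difference covariance; drop redundant variables "
            "before the multivariate test"
        )
    t2 = float(n * dbar @ np.linalg.solve(s, dbar))
    f = (n - p) / (p * (n - 1)) * t2
    pval = float(stats.f.sf(f, p, n - p))
    lam = float(1.0 / (1.0 + t2 / (n - 1)))
    return TestResult(t2, pval, (p, n - p), wilks_lambda=lam)


@dataclass
class SimesResult:
    """Simes global decision plus per-hypothesis rejections."""

    global_reject: bool
    reject: np.ndarray          # bool, original hypothesis order
    thresholds: np.ndarray      # i * alpha / m in sorted order
    alpha: float


def simes(pvals: np.ndarray, alpha: float = 0.05) -> SimesResult:
    """Simes multiple-testing procedure.

    With ordered p-values ``p_(1) <= ... <= p_(m)`` the global null is
    rejected iff ``p_(i) <= i * alpha / m`` for some i; elementary
    hypothesis H_(i) is rejected at the same criterion. Exact level-alpha
    under independent uniforms.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    m = p.size
    if m < 1:
        raise DataError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) * alpha) / m
    hit = p[order] <= thresh
    reject_sorted = hit.copy()
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    return SimesResult(bool(hit.any()), reject, thresh, alpha)


def hotelling_family(
    sample: PairedSample, alpha: float = 0.05
) -> TestResult:
    """Hotelling T2 across one variable family with Simes post-hoc t-tests.

    The family-level multivariate test is reported together with a tidy
    per-variable table (t, p, Simes threshold, rejection flag) where m =
    number of variables in the family.
    """
    res = paired_hotelling(sample)
    rows = []
    for k, name in enumerate(sample.variables):
        tr = paired_t(sample.pre[:, k], sample.post[:, k])
        rows.append({"variable": name, "t": tr.statistic, "p": tr.p_value})
    tab = pd.DataFrame(rows)
    sim = simes(tab["p"].to_numpy(), alpha=alpha)
    # map each variable's rank-based threshold back to original order
    order = np.argsort(tab["p"].to_numpy(), kind="stable")
    thr = np.empty(len(tab))
    thr[order] = sim.thresholds
    tab["simes_threshold"] = thr
    tab["reject"] = sim.reject
    res.post_hoc = tab
    return res
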