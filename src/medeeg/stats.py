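"""Aggregate statistics: 50%-split summaries, paired t-tests, dip test.

``summarize`` reproduces the study's reporting layer: per-experiment mean
accuracy, the grand mean +/- SD over all tests, and the means of the sorted
bottom and top halves.  ``paired_ttest`` compares pipelines on paired
per-cell means.  ``dip_statistic``/``dip_test`` implement Hartigan's dip —
the minimum over unimodal distribution functions of the supremum distance to
the empirical distribution function — via the greatest-convex-minorant /
least-concave-majorant algorithm, with a seeded uniform(0,1) bootstrap for
the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import TestResult


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class StudySummary:
    n_tests: int
    mean_all: float
    sd_all: float
    mean_bottom50: float
    sd_bottom50: float
    mean_top50: float
    sd_top50: float
    experiment_means: dict[int, float]
    experiment_sds: dict[int, float]


def _half_split(sorted_acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted sample -> (bottom, top); odd counts give the extra element
    to the bottom half."""
    n = len(sorted_acc)
    cut = n - n // 2
    return sorted_acc[:cut], sorted_acc[cut:]


def summarize(results: list[TestResult] | np.ndarray) -> StudySummary:
    """All-tests / bottom-50% / top-50% means +/- SD plus per-experiment rows.

    Accepts either TestResult objects (grouped by ``experiment_id``) or a
    bare accuracy array (treated as one experiment).
    """
    if isinstance(results, (list, tuple)) and results and isinstance(
            results[0], TestResult):
        acc = np.array([r.accuracy for r in results], dtype=float)
        exp_ids = np.array([r.experiment_id for r in results])
    else:
        acc = np.asarray(results, dtype=float).ravel()
        exp_ids = np.zeros(len(acc), dtype=int)
    if acc.size == 0:
        raise ValueError("no results to summarize")
    if not np.all(np.isfinite(acc)):
        raise ValueError("non-finite accuracies")
    exp_means, exp_sds = {}, {}
    for e in np.unique(exp_ids):
        vals = acc[exp_ids == e]
        exp_means[int(e)] = float(vals.mean())
        exp_sds[int(e)] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    s = np.sort(acc)
    bottom, top = _half_split(s)

    def _sd(v: np.ndarray) -> float:
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    return StudySummary(
        n_tests=len(acc),
        mean_all=float(acc.mean()), sd_all=_sd(acc),
        mean_bottom50=float(bottom.mean()), sd_bottom50=_sd(bottom),
        mean_top50=float(top.mean()), sd_top50=_sd(top),
        experiment_means=exp_means, experiment_sds=exp_sds,
    )


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def paired_ttest(a, b) -> TTestResult:
    """Classical paired t on the differences a - b, two-sided p, df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("all paired differences are (near-)identical; "
                         "t is undefined")
    res = sps.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), df=len(a) - 1,
                       p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------

def dip_statistic(sample) -> float:
    """Hartigan's dip: min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.

    Computed with the iterative greatest-convex-minorant (GCM) /
    least-concave-majorant (LCM) algorithm: the candidate modal interval is
    narrowed until the maximal GCM/LCM discrepancy stops improving, while
    the deviations of the empirical distribution from the convex fit below
    and the concave fit above the modal interval accumulate into the dip.
    Satisfies 1/(2n) <= dip <= 1/4 on every input.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    if n <= 3 or x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # 1-based index arrays as in the classical formulation
    xs = np.concatenate([[np.nan], x])
    mn = np.zeros(n + 1, dtype=np.int64)  # GCM predecessor chain
    mj = np.zeros(n + 1, dtype=np.int64)  # LCM successor chain
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (xs[j] - xs[mnj]) * (mnj - mnmnj) < \
                    (xs[mnj] - xs[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (xs[k] - xs[mjk]) * (mjk - mjmjk) < \
                    (xs[mjk] - xs[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in count units; divided by 2n at the end
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)
    while True:
        # GCM change points from high down to low; LCM from low up to high
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i

        ix, ig = l_gcm - 1, l_gcm
        iv, ih = 2, l_lcm
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - \
                        (xs[lcmiv] - xs[gcmi1]) * (gcmix - gcmi1) / \
                        (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / \
                        (xs[lcmiv] - xs[lcmiv1]) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # deviation of the empirical CDF above the convex fit on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                jj = np.arange(jb, je + 1)
                t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                max_t = max(max_t, float(t.max()))
            dip_l = max(dip_l, max_t)
        # deviation below the concave fit on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                jj = np.arange(jb, je + 1)
                t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                max_t = max(max_t, float(t.max()))
            dip_u = max(dip_u, max_t)

        dip = max(dip, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    dip = max(dip, d)
    return float(dip / (2.0 * n))


@dataclass
class DipResult:
    dip: float
    p: float
    n: int
    n_boot: int
    seed: int


def dip_test(sample, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Dip statistic with a uniform(0,1) bootstrap p-value.

    p = fraction of ``n_boot`` uniform samples of the same size whose dip is
    at least the observed one (the standard null calibration: the uniform is
    the least favourable unimodal distribution).
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError("dip test needs n >= 4")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: dip test undefined")
    observed = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boot = np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
    p = float(np.mean(boot >= observed))
    return DipResult(dip=observed, p=p, n=n, n_boot=n_boot, seed=seed)
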