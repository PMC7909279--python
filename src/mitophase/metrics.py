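"""Haplotype-accuracy metrics for mixture deconvolution.

Phasing accuracy is measured by Hamming distance between estimated and true
haplotypes.  For a two-person mixture with truth (A, B) and estimate (a, b)
the total paired distance is min(d(A,a) + d(B,b), d(A,b) + d(B,a)) — the
matching absorbs label swaps; the rule generalizes to K contributors by
minimizing over permutations.  Deconvolution accuracy is the percentage of
mixtures in which every contributor is recovered at distance zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .empop import Haplotype
from .interpolate import MINOR_MISSING


@dataclass
class AccuracyRecord:
    """Evaluation of one deconvolved mixture under the optimal matching."""

    total: int
    per_contributor: tuple[int, ...]
    major_correct: bool
    minor_correct: bool
    uncalled: int = 0
    true_minor_proportion: float | None = None
    est_minor_proportion: float | None = None


def hamming(x: Haplotype | np.ndarray, y: Haplotype | np.ndarray) -> int:
    """Number of differing sites; uncalled estimate sites are excluded."""
    xa = x.alleles if isinstance(x, Haplotype) else np.asarray(x)
    ya = y.alleles if isinstance(y, Haplotype) else np.asarray(y)
    if xa.size != ya.size:
        raise ValueError("haplotypes have different lengths")
    called = (xa != MINOR_MISSING) & (ya != MINOR_MISSING)
    return int(np.sum((xa != ya) & called))


def _uncalled(arrs: Sequence[np.ndarray]) -> int:
    return int(sum(np.sum(a == MINOR_MISSING) for a in arrs))


def paired_distance(
    truth: Sequence[Haplotype],
    estimate: Sequence[Haplotype],
    true_minor_proportion: float | None = None,
    est_minor_proportion: float | None = None,
) -> AccuracyRecord:
    """Optimal truth-to-estimate matching and its summed Hamming distance.

    ``truth`` and ``estimate`` are ordered major-first (by true and by
    estimated proportion respectively).  The matching minimizes the summed
    distance over all permutations (K <= 5, at most 120); ties prefer the
    identity so that correct label order is reported as such.  Correctness
    flags refer to the truth-ordered contributors under the chosen matching.
    """
    if len(truth) != len(estimate):
        raise ValueError("truth and estimate must have the same number of contributors")
    k = len(truth)
    d = np.array(
        [[hamming(t, e) for e in estimate] for t in truth], dtype=np.int64
    )
    best_perm = min(
        itertools.permutations(range(k)),
        key=lambda perm: (int(sum(d[i, perm[i]] for i in range(k))), perm),
    )
    per = tuple(int(d[i, best_perm[i]]) for i in range(k))
    est_arrays = [e.alleles for e in estimate]
    return AccuracyRecord(
        total=int(sum(per)),
        per_contributor=per,
        major_correct=per[0] == 0,
        minor_correct=per[-1] == 0,
        uncalled=_uncalled(est_arrays),
        true_minor_proportion=true_minor_proportion,
        est_minor_proportion=est_minor_proportion,
    )


def deconvolution_accuracy(
    records: Sequence[AccuracyRecord],
) -> tuple[float, tuple[float, float]]:
    """Percentage of mixtures with total paired distance zero, with 95% CI.

    The Wilson binomial interval backs the crossbars of accuracy-by-ratio
    plots.  Returns (percentage, (low, high)) on the 0-100 scale.
    """
    if not records:
        raise ValueError("no records to summarize")
    n = len(records)
    perfect = sum(1 for r in records if r.total == 0)
    low, high = proportion_confint(perfect, n, alpha=0.05, method="wilson")
    return 100.0 * perfect / n, (100.0 * low, 100.0 * high)


def major_accuracy(records: Sequence[AccuracyRecord]) -> float:
    """Percentage of mixtures whose major contributor is recovered exactly."""
    if not records:
        raise ValueError("no records to summarize")
    return 100.0 * sum(r.major_correct for r in records) / len(records)


@dataclass
class ProportionFit:
    """Goodness of fit of estimated vs expected minor proportions."""

    r_squared: float
    slope: float
    intercept: float
    per_ratio_variance: dict[float, float]
    per_ratio_sd: dict[float, float]


def proportion_fit(expected: Sequence[float], observed: Sequence[float]) -> ProportionFit:
    """OLS of observed on expected minor proportions, plus per-ratio spread.

    The per-ratio sample variance/SD of the observed proportions quantifies
    estimator stability within each expected mixture ratio.
    """
    x = np.asarray(expected, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length sequences of at least 2")
    if np.ptp(x) == 0:
        raise ValueError("expected proportions are constant; fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    per_var: dict[float, float] = {}
    per_sd: dict[float, float] = {}
    for v in np.unique(x):
        ys = y[x == v]
        var = float(ys.var(ddof=1)) if ys.size > 1 else 0.0
        per_var[float(v)] = var
        per_sd[float(v)] = float(np.sqrt(var))
    return ProportionFit(r2, float(slope), float(intercept), per_var, per_sd)
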