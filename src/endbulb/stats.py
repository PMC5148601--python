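"""Bespoke statistical utilities: Benjamini-Hochberg FDR and Cohen's U1.

Standard hypothesis tests (t-tests, rank tests, ANOVA machinery) are
delegated to scipy/statsmodels by the callers; only the two small
procedures the pipeline needs natively live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg outcome: rejections aligned to the input order."""

    p_sorted: np.ndarray
    threshold: float          # largest rejected p-value (0 if none)
    rejected: np.ndarray      # boolean, input order
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def benjamini_hochberg(pvalues, q: float) -> FdrResult:
    """Step-up FDR procedure: reject all p <= p_(k*) with
    k* = max{k : p_(k) <= (k/m) q}.

    Empty input yields an empty result; the rejection set is always a
    down-set of the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return FdrResult(p_sorted=p, threshold=0.0,
                         rejected=np.zeros(0, dtype=bool), q=q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    ok = np.flatnonzero(ps <= crit)
    if len(ok) == 0:
        return FdrResult(p_sorted=ps, threshold=0.0,
                         rejected=np.zeros(m, dtype=bool), q=q)
    thr = ps[ok[-1]]
    return FdrResult(p_sorted=ps, threshold=float(thr),
                     rejected=p <= thr, q=q)


@dataclass(frozen=True)
class EffectSize:
    name: str
    value: float
    n_a: int
    n_b: int


def cohens_u1(sample_a, sample_b) -> EffectSize:
    """Cohen's U1: the proportion of non-overlap of two distributions.

    Estimated distribution-free from the empirical CDFs: for two densities
    with a single crossing, the overlapping coefficient is OVL = 1 - D with
    D the two-sample Kolmogorov-Smirnov statistic, and
    U1 = 2 (1 - OVL) / (2 - OVL) = 2D / (1 + D).  Fully separated samples
    give 1; identical samples give 0 (identical constant samples by
    convention as well).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    d = float(np.max(np.abs(fa - fb)))
    u1 = 2.0 * d / (1.0 + d)
    return EffectSize(name="U1", value=u1, n_a=len(a), n_b=len(b))
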