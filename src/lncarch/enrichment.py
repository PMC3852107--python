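"""Hypergeometric over/under-representation of classes across filtration steps.

At each filtration step a class's frequency among the retained lncRNAs is
contrasted with its frequency among the removed lncRNAs.  Significance is
an exact hypergeometric tail (over: P(X >= k); under: P(X <= k), with
X ~ Hypergeometric(N, K, n): population N with K marked, draw n = the
retained set); effect size is the fold enrichment

    FE = (k / n) / ((K - k) / (N - n)),

i.e. retained-set frequency over removed-set frequency.  Two tabulation
schemes are supported: a class versus all non-members, and a class versus
one other class (population restricted to the two classes).  P-values are
Bonferroni-corrected within the batch of tests actually performed in one
invocation.

Tails are computed exactly with integer binomial coefficients (a single
terminal division), switching to scipy's log-space survival function for
populations above 10,000 where exact integer sums become wasteful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

#: Population size above which tails fall back to scipy's implementation.
_EXACT_N_LIMIT = 10_000

OVER = "over"
UNDER = "under"

CLASS_VS_REST = "class_vs_rest"
CLASS_VS_CLASS = "class_vs_class"


def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if not all(isinstance(v, (int,)) for v in (k, K, n, N)):
        raise ValueError("hypergeometric arguments must be integers")
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k < max(0, n - (N - K)):
        raise ValueError(f"impossible count: k={k} < n - (N - K) = {n - (N - K)}")


def hypergeom_tail(k: int, K: int, n: int, N: int, direction: str = OVER) -> float:
    """Exact hypergeometric tail probability.

    ``over``: P(X >= k); ``under``: P(X <= k) for X ~ Hypergeometric(N, K, n)
    (n draws without replacement from N items of which K are marked).
    """
    _check_bounds(k, K, n, N)
    if direction not in (OVER, UNDER):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if N > _EXACT_N_LIMIT:
        from scipy import stats

        if direction == OVER:
            return float(stats.hypergeom.sf(k - 1, N, K, n))
        return float(stats.hypergeom.cdf(k, N, K, n))

    lo = max(0, n - (N - K))
    hi = min(K, n)
    if direction == OVER:
        support = range(k, hi + 1)
    else:
        support = range(lo, k + 1)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in support)
    den = math.comb(N, n)
    return num / den


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """FE = retained-set frequency / removed-set frequency.

    Returns ``inf`` when the class is absent from the removed set
    (K - k = 0) but present in the retained set; 0.0 when absent from the
    retained set; NaN for a degenerate contrast (empty retained or
    removed set).
    """
    _check_bounds(k, K, n, N)
    if n == 0 or N - n == 0:
        return float("nan")
    retained_freq = k / n
    removed = (K - k) / (N - n)
    if removed == 0:
        return float("inf") if retained_freq > 0 else float("nan")
    return retained_freq / removed


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """min(1, m * p) for each p, with m = number of tests in the batch."""
    m = len(p_values)
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return [min(1.0, m * p) for p in p_values]


@dataclass(frozen=True)
class EnrichmentResult:
    """Frequency shift of one class across one filtration step."""

    step: str
    label: str
    tabulation: str  # "class_vs_rest" or "class_vs_class:<other>"
    k: int
    K: int
    n: int
    N: int
    p_value: float
    direction: str
    fold_enrichment: float
    p_adjusted: float = float("nan")
    n_tests: int = 0


def _one_test(step: str, label: str, tabulation: str, k: int, K: int, n: int, N: int) -> EnrichmentResult:
    p_over = hypergeom_tail(k, K, n, N, OVER)
    p_under = hypergeom_tail(k, K, n, N, UNDER)
    if p_over <= p_under:
        p, direction = p_over, OVER
    else:
        p, direction = p_under, UNDER
    return EnrichmentResult(
        step=step,
        label=label,
        tabulation=tabulation,
        k=k,
        K=K,
        n=n,
        N=N,
        p_value=p,
        direction=direction,
        fold_enrichment=fold_enrichment(k, K, n, N),
    )


def class_shift_tests(
    cascade,
    step: str,
    kind: str = "ga_class",
    tabulation: str = CLASS_VS_REST,
    labels: Optional[Sequence[str]] = None,
) -> List[EnrichmentResult]:
    """Test every class (or ordered class pair) for a frequency shift at one step.

    ``cascade`` is a :class:`~lncarch.expression.CascadeResult`; ``step``
    is any step after the first; the retained set is the step's members
    and the removed set is the previous step's members not retained.
    ``kind`` selects the label column of the cascade flags (``ga_class``
    or ``superclass``) or a mode table.  For each label the smaller of the
    over/under tails is reported with its direction; Bonferroni m = number
    of tests in this batch.
    """
    from .expression import CASCADE_STEPS

    if step not in CASCADE_STEPS or step == CASCADE_STEPS[0]:
        raise ValueError(f"step must be one of {CASCADE_STEPS[1:]}, got {step!r}")
    prev = CASCADE_STEPS[CASCADE_STEPS.index(step) - 1]

    flags = cascade.flags
    prev_members = flags[flags[prev]]
    retained = prev_members[prev_members[step]]
    removed = prev_members[~prev_members[step]]
    if len(retained) == 0 or len(removed) == 0:
        raise ValueError(f"degenerate step {step!r}: retained={len(retained)}, removed={len(removed)}")

    if kind in flags.columns:
        ret_labels = retained[kind]
        all_labels = prev_members[kind]
    else:
        raise ValueError(f"unknown label kind {kind!r}")

    if labels is None:
        labels = sorted(all_labels.unique())

    results: List[EnrichmentResult] = []
    if tabulation == CLASS_VS_REST:
        N = len(prev_members)
        n = len(retained)
        for lbl in labels:
            K = int((all_labels == lbl).sum())
            k = int((ret_labels == lbl).sum())
            results.append(_one_test(step, lbl, CLASS_VS_REST, k, K, n, N))
    elif tabulation == CLASS_VS_CLASS:
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                in_ab = all_labels.isin([a, b])
                ret_ab = ret_labels.isin([a, b])
                N = int(in_ab.sum())
                n = int(ret_ab.sum())
                K = int((all_labels == a).sum())
                k = int((ret_labels == a).sum())
                if N == 0 or n == 0 or n == N:
                    continue
                results.append(_one_test(step, a, f"{CLASS_VS_CLASS}:{b}", k, K, n, N))
    else:
        raise ValueError(f"unknown tabulation {tabulation!r}")

    if results:
        adj = bonferroni([r.p_value for r in results])
        results = [
            EnrichmentResult(
                **{**r.__dict__, "p_adjusted": a, "n_tests": len(results)}
            )
            for r, a in zip(results, adj)
        ]
    return results


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Enrichment report as a DataFrame (stable column order)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "step": r.step,
                "label": r.label,
                "tabulation": r.tabulation,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "direction": r.direction,
                "p_value": r.p_value,
                "fold_enrichment": r.fold_enrichment,
                "p_adjusted": r.p_adjusted,
                "n_tests": r.n_tests,
            }
            for r in results
        ],
        columns=[
            "step",
            "label",
            "tabulation",
            "k",
            "K",
            "n",
            "N",
            "direction",
            "p_value",
            "fold_enrichment",
            "p_adjusted",
            "n_tests",
        ],
    )
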