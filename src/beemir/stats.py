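"""The statistical battery: hypergeometric enrichment with representation
factors, Benjamini–Hochberg correction, the expression t-test, and
reciprocal-best-hit orthologue matching.

The representation factor of an overlap is RF = x/E with E = nD/N, where x
is the observed overlap between two gene lists, n and D their sizes and N
the universe size; RF = 1 is the chance expectation, RF > 1 over-,
RF < 1 under-representation.  Over- and under-enrichment p-values come
from the hypergeometric tails P[X >= x] and P[X <= x] (both include the
point mass at x, so they sum to >= 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .homology import (
    KarlinAltschulParams,
    ScoringScheme,
    evalue,
    smith_waterman,
    solve_karlin_altschul,
)

logger = logging.getLogger("beemir")


@dataclass
class EnrichmentResult:
    x: int
    n: int
    D: int
    N: int
    E: float
    RF: float
    p_over: float
    p_under: float
    p_adj: float = float("nan")
    label: str = ""


def hypergeom_enrichment(
    list1: set[str], list2: set[str], universe: set[str], label: str = ""
) -> EnrichmentResult:
    """Hypergeometric over/under-enrichment of the overlap of two gene lists.

    Both lists must be subsets of the universe; tail probabilities are
    evaluated in log space and exponentiated for numerical stability.
    """
    if not universe:
        raise ValueError("empty universe")
    for name, lst in (("list1", list1), ("list2", list2)):
        extra = lst - universe
        if extra:
            raise ValueError(f"{name} not within universe: {sorted(extra)[:5]}")
    N, n, D = len(universe), len(list1), len(list2)
    x = len(list1 & list2)
    E = n * D / N
    dist = sps.hypergeom(N, D, n)
    p_over = float(np.exp(dist.logsf(x - 1))) if x > 0 else 1.0
    p_under = float(np.exp(dist.logcdf(x)))
    return EnrichmentResult(
        x=x, n=n, D=D, N=N, E=E,
        RF=x / E if E > 0 else float("nan"),
        p_over=min(p_over, 1.0), p_under=min(p_under, 1.0),
        label=label,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j)·m/j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def expression_ttest(
    ls_expr, hom_expr, log_transform: bool = True, alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Welch two-sample t-test of lineage-specific vs homologous expression.

    Expression is compared on log2(RPM + 1) by default (raw small-RNA
    abundances are heavy-tailed).  ``alternative="less"`` asks one-sided
    whether the first group is lower.  Returns (t, df, p).
    """
    a = np.asarray(ls_expr, dtype=float)
    b = np.asarray(hom_expr, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if log_transform:
        a, b = np.log2(a + 1.0), np.log2(b + 1.0)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(a.size + b.size - 2), 1.0
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def reciprocal_best_hits(
    set_a: dict[str, str],
    set_b: dict[str, str],
    scoring: ScoringScheme | None = None,
    params: KarlinAltschulParams | None = None,
    max_evalue: float = 1e-5,
    protein: bool = True,
) -> list[tuple[str, str]]:
    """Orthologue pairs by reciprocal best local-alignment hit.

    (a, b) is reported iff b is a's highest-scoring hit, a is b's, and both
    alignments reach E <= ``max_evalue``.  Protein mode scores identities
    more sharply (+3/−2) in lieu of a substitution matrix; search space for
    the E-value is the summed length of the opposing set.
    """
    if scoring is None:
        scoring = (
            ScoringScheme(match=3.0, mismatch=-2.0, gap_open=-6.0, gap_extend=-2.0)
            if protein
            else ScoringScheme()
        )
    if params is None:
        freqs = (0.25, 0.25, 0.25, 0.25)
        params = solve_karlin_altschul(scoring, freqs)
    len_a = sum(len(s) for s in set_a.values())
    len_b = sum(len(s) for s in set_b.values())
    scores: dict[tuple[str, str], float] = {}
    for a_id, a_seq in set_a.items():
        for b_id, b_seq in set_b.items():
            scores[(a_id, b_id)] = smith_waterman(a_seq, b_seq, scoring).score
    best_for_a = {
        a_id: max(set_b, key=lambda b_id: scores[(a_id, b_id)]) for a_id in set_a
    }
    best_for_b = {
        b_id: max(set_a, key=lambda a_id: scores[(a_id, b_id)]) for b_id in set_b
    }
    pairs = []
    for a_id, b_id in best_for_a.items():
        if best_for_b[b_id] != a_id:
            continue
        score = scores[(a_id, b_id)]
        e_a = evalue(score, len(set_a[a_id]), len_b, params)
        e_b = evalue(score, len(set_b[b_id]), len_a, params)
        if e_a <= max_evalue and e_b <= max_evalue:
            pairs.append((a_id, b_id))
    return sorted(pairs)


def enrichment_battery(
    list1: set[str],
    named_lists: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One enrichment row per named gene list, BH-adjusted within the battery.

    ``list1`` is typically the predicted targets of lineage-specific
    miRNAs; ``named_lists`` the gene sets to test against (lineage-specific
    genes, caste-biased genes, genes under selection, ...).
    """
    results = [
        hypergeom_enrichment(list1, lst, universe, label=name)
        for name, lst in named_lists.items()
    ]
    adj = bh_adjust([min(r.p_over, r.p_under) * 2 for r in results])
    rows = []
    for r, p_adj in zip(results, adj):
        r.p_adj = min(float(p_adj), 1.0)
        rows.append(
            {
                "label": r.label, "x": r.x, "n": r.n, "D": r.D, "N": r.N,
                "E": r.E, "RF": r.RF, "p_over": r.p_over, "p_under": r.p_under,
                "p_adj": r.p_adj,
            }
        )
    return pd.DataFrame(rows)
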