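"""Copy-number vs sociality association with phylogenetic independent
contrasts (PIC) and Spearman rank correlation.

Felsenstein's contrasts turn leaf trait values on a rooted binary tree
into n−1 statistically independent, variance-standardized differences
under a Brownian-motion model: at each internal node the contrast is
(x_left − x_right)/sqrt(v_left + v_right), the ancestral value is the
variance-weighted mean of the children, and the node's parent branch is
lengthened by v_l·v_r/(v_l+v_r).  Children are ordered deterministically
(by their lexicographically smallest leaf label) so that contrasts of two
traits computed on the same tree pair up sign-consistently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import Phylogeny
from .stats import bh_adjust


@dataclass
class SocialityScore:
    """Ordinal social-organization level of a species: 0 solitary,
    1 facultative basic eusocial, 2 obligate basic eusocial,
    3 obligate complex eusocial."""

    species_id: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"sociality level must be 0-3, got {self.level}")


def pic(phylogeny: Phylogeny, trait: dict[str, float]) -> np.ndarray:
    """Standardized independent contrasts of a leaf trait, post-order.

    Contrasts are emitted in post-order over the deterministically ordered
    tree, so two traits contrasted on the same tree are paired node by
    node.  A leaf without a trait value is a hard error.
    """
    tree = phylogeny.tree
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(leaves - set(trait))
    if missing:
        raise ValueError(f"missing trait values for leaves: {missing}")

    contrasts: list[float] = []

    def visit(node) -> tuple[float, float, str]:
        """Returns (value, variance of value, smallest leaf label below)."""
        edge = node.edge.length if node.edge.length is not None else 0.0
        children = node.child_nodes()
        if not children:
            return trait[node.taxon.label], edge, node.taxon.label
        if len(children) != 2:
            raise ValueError("PIC requires a strictly binary tree")
        results = [visit(c) for c in children]
        results.sort(key=lambda r: r[2])
        (x1, v1, label1), (x2, v2, _label2) = results
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        value = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        return value, edge + v1 * v2 / (v1 + v2), label1

    visit(tree.seed_node)
    n_leaves = len(leaves)
    assert len(contrasts) == n_leaves - 1
    return np.asarray(contrasts)


def contrast_spearman(contrasts_x, contrasts_y) -> tuple[float, float]:
    """Spearman correlation of paired contrasts.

    rho uses average ranks; the two-sided p-value is exact (all n!
    permutations) for n <= 9 and the t-approximation above that.
    """
    x = np.asarray(contrasts_x, dtype=float)
    y = np.asarray(contrasts_y, dtype=float)
    if x.size != y.size:
        raise ValueError("contrast vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    rho = float(sps.spearmanr(x, y).statistic)
    if math.isnan(rho):
        return rho, float("nan")
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        observed = abs(_pearson(rx, ry))
        count = total = 0
        for perm in itertools.permutations(ry):
            if abs(_pearson(rx, np.asarray(perm))) >= observed - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    return rho, float(sps.spearmanr(x, y).pvalue)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom if denom else 0.0


def copy_number_scan(
    matrix: pd.DataFrame,
    phylogeny: Phylogeny,
    sociality: dict[str, int],
    bh: bool = True,
) -> pd.DataFrame:
    """Per-accession association of miRNA copy-number with sociality.

    Both variables are contrasted on the tree, Spearman-correlated, and BH
    corrected across accessions.  Accessions with zero copy-number
    variance across species carry no signal and are skipped with a reason
    (many known miRNAs have one copy in every genome).
    """
    leaves = set(phylogeny.leaf_ids)
    if set(matrix.columns) != leaves:
        raise ValueError("copy-number matrix columns must equal tree leaves")
    soc_contrasts = pic(phylogeny, {s: float(v) for s, v in sociality.items()})
    rows = []
    pvals: list[float] = []
    for accession, copy_numbers in matrix.iterrows():
        values = copy_numbers.astype(float)
        if values.nunique() <= 1:
            rows.append(
                {"accession": accession, "rho": np.nan, "p": np.nan,
                 "skipped": "zero copy-number variance"}
            )
            continue
        cn_contrasts = pic(phylogeny, values.to_dict())
        rho, p = contrast_spearman(cn_contrasts, soc_contrasts)
        rows.append({"accession": accession, "rho": rho, "p": p, "skipped": ""})
        pvals.append(p)
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    if bh and pvals:
        tested = df["skipped"] == ""
        df.loc[tested, "p_adj"] = bh_adjust(pvals)
    return df
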