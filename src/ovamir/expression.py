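"""qPCR quantification and expression statistics.

Quantities are interpolated from 10-fold-dilution standard curves
(Cq = slope * log10(quantity) + intercept), normalized by the geometric
mean of two reference genes, and reported as relative fold changes over
the lowest group mean.  Group differences are assessed by one-way ANOVA
with all-pairs Tukey HSD and a compact letter display (groups sharing no
letter differ at alpha); rank-based comparisons of expression matrices use
the tie-corrected Kruskal-Wallis test on globally ranked values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "NormalizedExpression",
    "fit_standard_curve",
    "quantify_normalize",
    "fold_changes",
    "anova_letters",
    "kw_test",
    "rank_values",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """A qPCR standard curve: Cq = slope * log10(quantity) + intercept."""

    target: str
    slope: float
    intercept: float
    efficiency: float  # percent
    r2: float

    def quantity(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class NormalizedExpression:
    sample: str
    tissue: str
    target: str
    quantity: float
    normalized: float


def fit_standard_curve(target: str, dilution_log10: Sequence[float],
                       cq: Sequence[float]) -> StandardCurve:
    """Least-squares standard curve from a serial-dilution series.

    ``dilution_log10`` is log10 of the relative template quantity.
    Amplification efficiency is (10^(-1/slope) - 1) * 100; a slope of
    -3.3219 (one cycle per template doubling) gives exactly 100%.
    Requires at least 3 points with variation in the dilutions.
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dilutions")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        log.warning("%s: non-negative standard-curve slope %.3f", target, slope)
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return StandardCurve(
        target=target, slope=slope, intercept=float(res.intercept),
        efficiency=float(eff), r2=float(res.rvalue ** 2),
    )


def quantify_normalize(
    cq_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_targets: Sequence[str],
) -> list[NormalizedExpression]:
    """Curve-interpolated quantities normalized to two reference genes.

    ``cq_table`` needs columns sample, tissue, target, cq.  For each
    sample, every non-reference target's quantity is divided by the
    geometric mean of the two reference-gene quantities; samples missing a
    reference Cq are excluded with a warning.
    """
    refs = list(reference_targets)
    if len(refs) != 2:
        raise ValueError("exactly 2 reference targets required")
    out: list[NormalizedExpression] = []
    for sample, grp in cq_table.groupby("sample", sort=True):
        by_target = {}
        for _, row in grp.iterrows():
            q = curves[row["target"]].quantity(float(row["cq"]))
            by_target.setdefault(row["target"], []).append((row["tissue"], q))
        if not all(r in by_target for r in refs):
            log.warning("sample %s: missing reference Cq, excluded", sample)
            continue
        ref_geo = math.sqrt(
            float(np.mean([q for _, q in by_target[refs[0]]]))
            * float(np.mean([q for _, q in by_target[refs[1]]]))
        )
        for target, vals in by_target.items():
            if target in refs:
                continue
            for tissue, q in vals:
                out.append(
                    NormalizedExpression(
                        sample=str(sample), tissue=str(tissue), target=target,
                        quantity=q, normalized=q / ref_geo,
                    )
                )
    return out


def fold_changes(values_by_group: dict[str, Sequence[float]]) -> dict[str, float]:
    """Group means expressed as fold change over the lowest group mean.

    The calibrator (lowest mean) maps to exactly 1.0.
    """
    if not values_by_group:
        raise ValueError("no groups")
    means = {g: float(np.mean(v)) for g, v in values_by_group.items()}
    calib = min(means.values())
    if calib <= 0:
        raise ValueError("non-positive group mean; quantities must be > 0")
    return {g: m / calib for g, m in means.items()}


def _letters_from_graph(groups: Sequence[str], nondiff: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: one letter per maximal clique of the
    not-significantly-different graph."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nondiff)
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(c))
    # order letters by the best (highest-mean-rank) member order given
    order = {name: k for k, name in enumerate(groups)}
    cliques.sort(key=lambda c: min(order[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {name: [] for name in groups}
    for idx, clique in enumerate(cliques):
        letter = alphabet[idx % len(alphabet)]
        for member in clique:
            assigned[member].append(letter)
    return {name: "".join(sorted(set(ls))) for name, ls in assigned.items()}


def anova_letters(
    values_by_group: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA with Tukey HSD letters.

    Returns (F, p, letters).  Groups sharing no letter differ at ``alpha``.
    If every observation is identical the test is degenerate: F is
    reported as nan, p as 1, and all groups share one letter.
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size < 2 and np.ptp(a) == 0:
            raise ValueError(f"group {g}: n < 2 with zero variance")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return float("nan"), 1.0, {g: "a" for g in groups}
    F, p = stats.f_oneway(*arrays)
    # order groups by descending mean for letter assignment
    order = sorted(groups, key=lambda g: -float(np.mean(values_by_group[g])))
    if all(np.ptp(a) == 0 for a in arrays):
        # no within-group variance: every pair with distinct means differs
        nondiff = {
            (a, b)
            for i, a in enumerate(order)
            for b in order[i + 1:]
            if float(np.mean(values_by_group[a])) == float(np.mean(values_by_group[b]))
        }
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[g] * len(values_by_group[g]) for g in groups])
        res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        nondiff = set()
        for (a, b), reject in zip(
            ((res.groupsunique[i], res.groupsunique[j])
             for i, j in zip(*np.triu_indices(len(res.groupsunique), 1))),
            res.reject,
        ):
            if not reject:
                nondiff.add((str(a), str(b)))
    letters = _letters_from_graph(order, nondiff)
    return float(F), float(p), letters


def rank_values(matrix: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Rank expression values over the combined set (average ranks for ties).

    Adds a ``rank`` column; small ranks correspond to low expression.
    """
    out = matrix.copy()
    out["rank"] = stats.rankdata(out[value_col].to_numpy(), method="average")
    return out


def kw_test(
    ranked: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
    group_col: str = "tissue",
) -> tuple[float, float, dict[str, float]]:
    """Tie-corrected Kruskal-Wallis test on globally ranked expression.

    ``ranked`` needs columns gene, ``group_col``, value, rank (see
    :func:`rank_values`).  The test runs on the rank values of
    ``gene_subset`` (all genes when None); returns (H, p, mean rank per
    group).  If every value is identical, H = 0 and p = 1.
    """
    df = ranked
    if gene_subset is not None:
        df = df[df["gene"].isin(set(gene_subset))]
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with values")
    samples = [df.loc[df[group_col] == g, "rank"].to_numpy(dtype=float) for g in groups]
    mean_ranks = {g: float(s.mean()) for g, s in zip(groups, samples)}
    if np.ptp(np.concatenate(samples)) == 0:
        return 0.0, 1.0, mean_ranks
    H, p = stats.kruskal(*samples)
    return float(H), float(p), mean_ranks
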