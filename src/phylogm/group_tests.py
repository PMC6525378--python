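"""Euclidean PERMANOVA of PC scores with pairwise group comparisons.

Because PC scores over all axes preserve Euclidean (Procrustes tangent)
distances, a one-way PERMANOVA on the full score matrix is identical to
one on the flattened shape coordinates.  Pairwise tables are corrected
with Bonferroni by default (Holm available); with ``n_perm`` permutations
the attainable floors are ``1/(n_perm+1)`` raw and ``n_pairs/(n_perm+1)``
adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    df_between: int
    df_within: int
    n_perm: int
    seed: int | None = None


def _f_stat(X: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = X.shape[0]
    grand = X.mean(axis=0)
    sst = float(np.sum((X - grand) ** 2))
    ssw = 0.0
    for g in range(n_groups):
        sub = X[codes == g]
        ssw += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    ssb = sst - ssw
    df_b = n_groups - 1
    df_w = n - n_groups
    if sst <= 0:
        return 0.0, 0.0
    f = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
    return f, ssb / sst


def permanova(
    scores: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances among score rows.

    The pseudo-F partitions the total squared Euclidean distance into
    between- and within-group components (computed equivalently from group
    means); significance by permuting group labels.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] != len(groups):
        raise ValueError("groups length must match score rows")
    labels, codes = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"groups of size 1 not allowed: {small.tolist()}")
    f_obs, r2 = _f_stat(X, codes, len(labels))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        fp, _ = _f_stat(X, codes[rng.permutation(len(codes))], len(labels))
        if fp >= f_obs - 1e-12:
            ge += 1
    p = (ge + 1) / (n_perm + 1)
    return PermanovaResult(
        f_obs, r2, float(p), len(labels) - 1, X.shape[0] - len(labels), n_perm, seed
    )


def pairwise_permanova(
    scores: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """PERMANOVA on every unordered pair of groups, with multiplicity
    correction across pairs (Bonferroni default, Holm by flag)."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    g = np.asarray(groups, dtype=object)
    labels = sorted(set(g.tolist()))
    pairs = list(combinations(labels, 2))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        mask = (g == a) | (g == b)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(X[mask], g[mask], n_perm=n_perm, seed=sub_seed)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "R2": res.R2,
                "p_raw": res.p,
                "n_perm": n_perm,
            }
        )
    cols = ["group_a", "group_b", "pseudo_F", "R2", "p_raw", "n_perm"]
    table = pd.DataFrame(rows, columns=cols)
    m = len(pairs)
    if m == 0:
        table["p_adjusted"] = []
        return table
    if correction == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p_raw"] * m)
    elif correction == "holm":
        order = np.argsort(table["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table


def subset_rerun(
    scores: np.ndarray,
    groups,
    exclude: str,
    test_groups=None,
    n_perm: int = 999,
    seed: int | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Drop one group's specimens and rerun the pairwise table.

    ``test_groups`` optionally supplies a second grouping (e.g. diet) to
    test after excluding specimens by the first (e.g. a clade); by default
    the exclusion grouping itself is retested.
    """
    g = np.asarray(groups, dtype=object)
    if exclude not in set(g.tolist()):
        raise ValueError(f"group {exclude!r} not present")
    keep = g != exclude
    tg = g if test_groups is None else np.asarray(test_groups, dtype=object)
    remaining = tg[keep]
    counts = pd.Series(remaining).value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"exclusion leaves groups with <2 members: {counts[counts < 2].index.tolist()}"
        )
    return pairwise_permanova(
        np.atleast_2d(np.asarray(scores, dtype=float))[keep],
        remaining,
        n_perm=n_perm,
        seed=seed,
        correction=correction,
    )
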