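"""Post-hoc screening statistics.

Rank-based comparisons of the in silico scores against the experimental
screening outcome: the Mann-Whitney U test (exact by enumeration for small
tie-free samples, normal approximation with tie and continuity correction
otherwise), the concordance AUC (probability a positive variant outscores a
negative one, ties counted 0.5 — identically U/(n1*n0)), correlations of
score with sequence identity, and Welch's t test for growth curves.

No multiple-testing correction is applied by default (the comparisons are
reported side by side, uncorrected); ``holm=True`` switches a Holm
correction on in :func:`compare_scorers`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str          # "exact" | "asymptotic"
    alternative: str


def mann_whitney_u(
    x, y, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann-Whitney U test of x against y.

    U is the statistic of ``x``; ``alternative='greater'`` tests whether x
    is stochastically greater than y.  The p-value is exact (full
    enumeration of arrangements) when n_x*n_y <= 400 and there are no
    ties, otherwise a normal approximation with tie and continuity
    correction is used; the method is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(
        u=float(res.statistic), p=float(res.pvalue),
        method="exact" if exact else "asymptotic",
        alternative=alternative,
    )


def auc(scores, labels) -> float:
    """Concordance AUC: the probability that a positive-labelled item
    outscores a negative one, ties counted 0.5.  Equals U/(n1*n0) of the
    Mann-Whitney statistic of the positives."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    n1 = int(lab.sum())
    n0 = int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(s)
    u = ranks[lab].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def score_identity_correlation(
    table: pd.DataFrame, score_col: str, identity_col: str,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation (with p-value) between a score column and a sequence
    identity column; spearman uses exact average-rank tie handling."""
    sub = table[[score_col, identity_col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired values")
    x = sub[score_col].to_numpy(dtype=float)
    y = sub[identity_col].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Double-sided Welch's t test (unequal variances) with the
    Welch-Satterthwaite degrees of freedom; returns (t, dof, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            # no variance and no shift: t = 0, p = 1 by convention
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("degenerate variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    se2 = vx / x.size + vy / y.size
    dof = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(res.statistic), float(dof), float(res.pvalue)


def compare_scorers(
    table: pd.DataFrame,
    score_columns: list[str],
    label_col: str = "in_vitro_positive",
    holm: bool = False,
) -> pd.DataFrame:
    """AUC and one-sided Mann-Whitney p per score column against a boolean
    outcome label (positives hypothesized to score higher).  Rows with a
    missing label are excluded — absence of a label is not a negative.
    P-values are uncorrected unless ``holm=True``."""
    if label_col not in table.columns:
        raise ValueError(f"missing label column {label_col!r}")
    sub = table.dropna(subset=[label_col])
    labels = sub[label_col].astype(bool).to_numpy()
    rows = []
    for col in score_columns:
        if col not in sub.columns:
            raise ValueError(f"missing score column {col!r}")
        scores = sub[col].to_numpy(dtype=float)
        mask = np.isfinite(scores)
        res = mann_whitney_u(
            scores[mask & labels], scores[mask & ~labels], alternative="greater"
        )
        rows.append({
            "score": col,
            "auc": auc(scores[mask], labels[mask]),
            "p_one_sided": res.p,
            "method": res.method,
            "n_positive": int((mask & labels).sum()),
            "n_negative": int((mask & ~labels).sum()),
        })
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p_one_sided"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for k, i in enumerate(order):
            running = max(running, (m - k) * out["p_one_sided"].iloc[i])
            adj[i] = min(running, 1.0)
        out["p_holm"] = adj
    return out
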