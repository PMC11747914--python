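"""Post-hoc battery: partition agreement, phenotype/regional comparisons with
effect sizes, edgewise tests, and false-discovery-rate control.

Agreement between the data-driven clusters and diagnostic labels is
quantified with normalized mutual information (arithmetic-mean
normalization), the adjusted Rand score, homogeneity and completeness.
Continuous variables are routed to a Welch t-test (two groups, all groups
Shapiro-Wilk-normal) or a Kruskal-Wallis test; categorical variables use
Pearson's chi-squared without continuity correction.  Edgewise cluster
differences in association-graph weights use Kruskal-Wallis per region pair
with Benjamini-Hochberg correction across all edges of a measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

logger = logging.getLogger(__name__)


@dataclass
class AgreementScores:
    nmi: float
    adjusted_rand: float
    homogeneity: float
    completeness: float

    def to_dict(self) -> dict:
        return {
            "nmi": self.nmi,
            "adjusted_rand": self.adjusted_rand,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }


@dataclass
class ComparisonResult:
    variable: str
    test: str                   # 't', 'kruskal-wallis' or 'chi-squared'
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    group_summaries: dict | None = None


def _check_lengths(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("label vectors must have equal length >= 2")
    return a, b


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, I/mean(H_a, H_b); 0 if either side is constant."""
    a, b = _check_lengths(labels_a, labels_b)
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        logger.info("single-class partition: NMI defined as 0")
        return 0.0
    return float(skm.normalized_mutual_info_score(a, b, average_method="arithmetic"))


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(skm.adjusted_rand_score(a, b))


def homogeneity_completeness(truth, predicted) -> tuple[float, float]:
    """(homogeneity, completeness) of a predicted partition against a reference."""
    a, b = _check_lengths(truth, predicted)
    h, c, _ = skm.homogeneity_completeness_v_measure(a, b)
    return float(h), float(c)


def agreement_scores(truth, predicted) -> AgreementScores:
    h, c = homogeneity_completeness(truth, predicted)
    return AgreementScores(
        nmi=nmi(truth, predicted),
        adjusted_rand=adjusted_rand(truth, predicted),
        homogeneity=h,
        completeness=c,
    )


def _summaries(groups: dict) -> dict:
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[str(name)] = {"n": int(v.size), "median": float(med), "iqr": float(q3 - q1)}
    return out


def compare_continuous(values, group_labels, variable: str = "", alpha_normality: float = 0.05,
                       force_test: str | None = None) -> ComparisonResult:
    """Two-or-more-group comparison with normality-based test routing.

    With exactly two groups that each pass Shapiro-Wilk at
    ``alpha_normality``, a Welch t-test is used; otherwise Kruskal-Wallis
    with tie correction.  ``force_test`` ('t' or 'kruskal-wallis') overrides
    routing.  Group medians and IQRs are reported either way.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    uniq = np.unique(group_labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    groups = {g: values[group_labels == g] for g in uniq}
    if any(v.size < 3 for v in groups.values()):
        raise ValueError("each group needs at least 3 observations")

    if np.ptp(values) == 0:
        warnings.warn(f"{variable or 'variable'}: all values identical", stacklevel=2)
        return ComparisonResult(variable, "kruskal-wallis", 0.0, 1.0, group_summaries=_summaries(groups))

    test = force_test
    if test is None:
        if uniq.size == 2:
            normal = all(
                v.size >= 3 and np.ptp(v) > 0 and sps.shapiro(v).pvalue > alpha_normality
                for v in groups.values()
            )
            test = "t" if normal else "kruskal-wallis"
        else:
            test = "kruskal-wallis"

    effect = None
    if test == "t":
        g = list(groups.values())
        stat, p = sps.ttest_ind(g[0], g[1], equal_var=False)
        effect = cohens_d(g[0], g[1])
    else:
        try:
            stat, p = sps.kruskal(*groups.values())
        except ValueError:  # all values identical within the KW machinery
            stat, p = 0.0, 1.0
        if uniq.size == 2:
            g = list(groups.values())
            if np.std(np.concatenate(g)) > 0:
                try:
                    effect = cohens_d(g[0], g[1])
                except ValueError:
                    effect = None
    return ComparisonResult(variable, test, float(stat), float(p), effect_size=effect,
                            group_summaries=_summaries(groups))


def compare_categorical(contingency, variable: str = "") -> ComparisonResult:
    """Pearson chi-squared on a counts table, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integer counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0):
        raise ValueError(f"row {int(np.flatnonzero(row == 0)[0])} has zero marginal")
    if np.any(col == 0):
        raise ValueError(f"column {int(np.flatnonzero(col == 0)[0])} has zero marginal")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ComparisonResult(variable, "chi-squared", float(stat), float(p))


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference, pooled SD with n-1 weights; sign = a - b."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2))
    if pooled < 1e-12:
        raise ValueError("pooled SD is zero")
    return float((a.mean() - b.mean()) / pooled)


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    return adjusted, adjusted <= q


def edgewise_comparison(graph_stack: np.ndarray, labels, regions=None, q: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis per region pair on edge weights, BH across the measure.

    Returns a tidy frame: one row per edge with the statistic, raw and
    adjusted p, the sign of the first-cluster-minus-second median difference
    and the Cohen's d of the edge weights (two-cluster case).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    n, r, _ = graph_stack.shape
    if regions is None:
        regions = [f"R{i:03d}" for i in range(r)]
    ia, ib = np.triu_indices(r, k=1)
    rows = []
    for a, b in zip(ia, ib):
        w = graph_stack[:, a, b]
        groups = [w[labels == g] for g in uniq]
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(w) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*groups)
        med_diff = float(np.median(groups[0]) - np.median(groups[1])) if uniq.size == 2 else np.nan
        try:
            d = cohens_d(groups[0], groups[1]) if uniq.size == 2 else np.nan
        except ValueError:
            d = np.nan
        rows.append((regions[a], regions[b], float(stat), float(p), med_diff, d))
    frame = pd.DataFrame(rows, columns=["region_a", "region_b", "statistic", "p", "median_diff", "cohens_d"])
    frame["p_adjusted"], frame["significant"] = bh_fdr(frame["p"].to_numpy(), q)
    return frame


def phenotype_battery(phenotypes: pd.DataFrame, labels, q: float = 0.05) -> pd.DataFrame:
    """Continuous comparisons of every phenotype across clusters, BH-corrected."""
    results = []
    for col in phenotypes.columns:
        res = compare_continuous(phenotypes[col].to_numpy(dtype=float), labels, variable=col)
        results.append(res)
    frame = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "effect_size": [r.effect_size for r in results],
        }
    )
    frame["p_adjusted"], frame["significant"] = bh_fdr(frame["p"].to_numpy(), q)
    return frame
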