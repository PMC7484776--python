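"""Between-group comparisons for the cohort feature table.

Each of the 15 parameters is screened for normality per group with a
one-sample Kolmogorov-Smirnov test against a Gaussian with the sample's
own mean and SD.  Parameters normal in every group are compared by
one-way ANOVA with Tukey HSD post-hoc pairwise tests; a parameter failing
normality in any group is compared by the Dunn rank test.  Pairwise
significance is flagged at alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CohortDataset, FEATURE_NAMES, InvalidInputError

__all__ = [
    "ks_normality",
    "anova_tukey",
    "dunn_test",
    "compare_all",
    "GroupComparison",
    "ALPHA",
]

ALPHA = 0.05


class DegenerateSampleError(ValueError):
    """Sample has no variance: the requested test is undefined."""


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise comparison outcome for one parameter."""

    parameter: str
    test_used: str  # "anova_tukey" | "dunn" | "degenerate"
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    omnibus_p: float | None = None

    @property
    def significant(self) -> dict[tuple[str, str], bool]:
        return {pair: p < ALPHA for pair, p in self.pairwise_p.items()}

    def p_for(self, a: str, b: str) -> float:
        """Pairwise p-value regardless of label order."""
        if (a, b) in self.pairwise_p:
            return self.pairwise_p[(a, b)]
        if (b, a) in self.pairwise_p:
            return self.pairwise_p[(b, a)]
        raise KeyError((a, b))

    def to_rows(self) -> list[dict]:
        return [
            {
                "parameter": self.parameter,
                "pair": f"{a}|{b}",
                "test": self.test_used,
                "p": p,
                "significant": p < ALPHA,
            }
            for (a, b), p in self.pairwise_p.items()
        ]


def ks_normality(sample, *, lilliefors: bool = False) -> float:
    """P-value of a KS test of Gaussianity with estimated mean and SD.

    The default mirrors the plain one-sample KS test with the sample's
    own moments; ``lilliefors=True`` applies the correction for the
    estimated parameters (more powerful, off by default).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise InvalidInputError("normality test requires n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero-variance sample: normality undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InvalidInputError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise InvalidInputError("each group needs n >= 2")
    return gs


def anova_tukey(groups, labels=None, parameter: str = "") -> GroupComparison:
    """One-way ANOVA omnibus plus Tukey HSD pairwise p-values."""
    gs = _as_groups(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(gs))]
    values = np.concatenate(gs)
    if np.all(values == values[0]):
        # all observations identical: no evidence of any difference
        pw = {pair: 1.0 for pair in combinations(labels, 2)}
        return GroupComparison(parameter, "anova_tukey", pw, omnibus_p=1.0)
    f_p = float(sps.f_oneway(*gs).pvalue)
    tk = sps.tukey_hsd(*gs)
    pw = {
        (labels[i], labels[j]): float(tk.pvalue[i, j])
        for i, j in combinations(range(len(gs)), 2)
    }
    return GroupComparison(parameter, "anova_tukey", pw, omnibus_p=f_p)


def dunn_test(
    groups, labels=None, parameter: str = "", *, bonferroni: bool = False
) -> GroupComparison:
    """Dunn's rank-based pairwise test with tie correction.

    All observations are ranked jointly; the pairwise z statistic is the
    mean-rank difference over its standard error,

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  P-values are
    two-sided and unadjusted by default (``bonferroni=True`` multiplies
    by the number of pairs).
    """
    gs = _as_groups(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(gs))]
    values = np.concatenate(gs)
    n_total = values.size
    if np.all(values == values[0]):
        pw = {pair: 1.0 for pair in combinations(labels, 2)}
        return GroupComparison(parameter, "dunn", pw)
    ranks = sps.rankdata(values)
    sizes = [g.size for g in gs]
    idx = np.cumsum([0, *sizes])
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(gs))]

    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(gs) * (len(gs) - 1) // 2
    pw = {}
    for i, j in combinations(range(len(gs)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if bonferroni:
            p = min(p * n_pairs, 1.0)
        pw[(labels[i], labels[j])] = float(p)
    return GroupComparison(parameter, "dunn", pw)


def compare_all(
    dataset: CohortDataset,
    *,
    parameters=None,
    lilliefors: bool = False,
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """Route every parameter through normality screening and comparison.

    A parameter is treated as non-normal (and sent to the Dunn test) if
    the KS test rejects Gaussianity (p < 0.05) in at least one group;
    otherwise ANOVA + Tukey HSD.  A zero-variance parameter is reported
    with ``test_used='degenerate'`` and no p-values; other parameters are
    unaffected.  ``parameters`` restricts the analysis to a subset of the
    canonical feature list (default: all 15).
    """
    table = dataset.table
    labels = dataset.groups
    if len(labels) < 2:
        raise InvalidInputError("need >= 2 groups for comparisons")
    results = []
    for feat in (FEATURE_NAMES if parameters is None else parameters):
        if feat not in table.columns:
            raise InvalidInputError(f"missing feature column: {feat}")
        samples = [table.loc[table["group"] == g, feat].to_numpy() for g in labels]
        try:
            normal = all(
                ks_normality(s, lilliefors=lilliefors) >= ALPHA for s in samples
            )
        except DegenerateSampleError:
            results.append(GroupComparison(feat, "degenerate", {}))
            continue
        if normal:
            results.append(anova_tukey(samples, labels, parameter=feat))
        else:
            results.append(
                dunn_test(samples, labels, parameter=feat, bonferroni=bonferroni)
            )
    return results


def comparisons_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Long-format table: parameter, pair, test, p, significant."""
    rows = [row for r in results for row in r.to_rows()]
    if not rows:
        return pd.DataFrame(columns=["parameter", "pair", "test", "p", "significant"])
    return pd.DataFrame(rows)
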