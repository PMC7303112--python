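"""Nonparametric statistics: rank-sum, Kruskal-Wallis and Dunn post-hoc.

Chosen for the low replicate numbers typical of closed-chamber incubation
designs (n = 3-4 per condition).  The Wilcoxon rank-sum (Mann-Whitney) test
is exact for small untied samples and falls back to the tie-corrected
normal approximation otherwise; the Kruskal-Wallis H uses the chi-squared
reference with k-1 degrees of freedom; pairwise Dunn z statistics use
pooled mid-ranks with the standard tie-corrected variance, with Holm
adjustment by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

#: n + m at or below which the exact rank-sum null distribution is used
#: (in the absence of ties).
EXACT_LIMIT = 16

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class GroupedSamples:
    """Labelled groups of real-valued observations."""

    groups: list[tuple[str, list[float]]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InvalidInputError("need >= 2 groups")
        for label, values in self.groups:
            if len(values) == 0:
                raise InvalidInputError(f"group {label!r} is empty")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value: str, group: str) -> "GroupedSamples":
        pairs = [
            (str(label), sub[value].dropna().tolist())
            for label, sub in frame.groupby(group, sort=True)
        ]
        return cls(pairs)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    @property
    def values(self) -> list[list[float]]:
        return [v for _, v in self.groups]


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" | "normal_approx"


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Exact p by full enumeration of the rank-assignment null distribution
    when n + m <= 16 and the pooled sample has no ties; mid-rank normal
    approximation with tie correction otherwise.

    Raises
    ------
    InvalidInputError
        If either sample is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise InvalidInputError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= EXACT_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    p = float(min(res.pvalue, 1.0))
    return RankSumResult(float(res.statistic), p, "exact" if exact else "normal_approx")


def kruskal_wallis(samples: GroupedSamples) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value.

    H = 0 (p = 1) when all pooled observations are identical.

    Raises
    ------
    InvalidInputError
        If fewer than 2 groups, any group empty, or total n < 3.
    """
    values = samples.values
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in values])
    if pooled.size < 3:
        raise InvalidInputError("Kruskal-Wallis needs total n >= 3")
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*values)
    return float(h), float(p)


def dunn_posthoc(
    samples: GroupedSamples, adjust: str = "holm"
) -> pd.DataFrame:
    """Pairwise Dunn z tests on pooled mid-ranks after Kruskal-Wallis.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j:

        z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)),
        S = N(N+1)/12 - T / (12 (N-1)),   T = sum(t^3 - t) over tie groups.

    Two-sided raw p from the standard normal; adjusted with ``adjust``
    ("holm" default, "bonferroni", "fdr_bh", or "none").  With only two
    groups a post-hoc test is unnecessary: a warning is emitted and the
    rank-sum test is used for that single pair.

    Returns a tidy frame with columns group_1, group_2, z, p_raw,
    p_adjusted.
    """
    labels, values = samples.labels, samples.values
    if len(values) < 3:
        warnings.warn(
            "post-hoc test unnecessary for < 3 groups; falling back to the "
            "rank-sum test",
            stacklevel=2,
        )
        rs = wilcoxon_rank_sum(values[0], values[1])
        return pd.DataFrame(
            [
                {
                    "group_1": labels[0],
                    "group_2": labels[1],
                    "z": np.nan,
                    "p_raw": rs.p_value,
                    "p_adjusted": rs.p_value,
                }
            ]
        )
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in values])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [len(v) for v in values]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(values))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, j in combinations(range(len(values)), 2):
        se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group_1": labels[i], "group_2": labels[j], "z": z, "p_raw": p_raw}
        )
    out = pd.DataFrame(rows)
    if adjust in (None, "none"):
        out["p_adjusted"] = out["p_raw"]
    else:
        out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method=adjust)[1]
    out["p_adjusted"] = np.minimum(
        1.0, np.maximum(out["p_adjusted"], out["p_raw"])
    )
    return out


def compare_groups(
    frame: pd.DataFrame,
    value: str,
    group: str,
    adjust: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the test battery on one value column grouped by ``group``.

    Emits a tidy comparison table: the omnibus Kruskal-Wallis row followed
    by pairwise Dunn (>= 3 groups) or rank-sum (2 groups) rows.
    """
    samples = GroupedSamples.from_frame(frame, value, group)
    rows = []
    if len(samples.groups) >= 3:
        h, p = kruskal_wallis(samples)
        rows.append(
            {
                "test": "kruskal_wallis",
                "groups": "|".join(samples.labels),
                "statistic": h,
                "p": p,
                "p_adjusted": np.nan,
                "significant": p < alpha,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dunn = dunn_posthoc(samples, adjust=adjust)
        for _, r in dunn.iterrows():
            rows.append(
                {
                    "test": "dunn",
                    "groups": f"{r.group_1}|{r.group_2}",
                    "statistic": r.z,
                    "p": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.p_adjusted < alpha,
                }
            )
    else:
        rs = wilcoxon_rank_sum(*samples.values)
        rows.append(
            {
                "test": "wilcoxon_rank_sum",
                "groups": "|".join(samples.labels),
                "statistic": rs.statistic,
                "p": rs.p_value,
                "p_adjusted": np.nan,
                "significant": rs.p_value < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "value", value)
    return out
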