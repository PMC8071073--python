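"""Descriptive statistics and the nonparametric comparison chain.

Per-lineage descriptive summaries of the four click parameters, the
tie-corrected Kruskal-Wallis test across lineages, and the Dunn post hoc
z-tests with Bonferroni adjustment — the statistics used to ask whether
boto lineages differ in their click parameters.  The rank statistics are
computed from the formulas (midranks via ``scipy.stats.rankdata``):

    H  = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2,
    Hc = H / (1 - sum(t^3 - t) / (N^3 - N)),

with p from the chi-square upper tail on k-1 df, and

    z_ij = (Rbar_i - Rbar_j) /
           sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)],

two-sided normal p-values multiplied by the number of pairs k(k-1)/2 and
capped at 1.  ICI is summarized descriptively but excluded from the post
hoc discrimination: inter-click intervals track behavioural context
(range, prey proximity), not lineage identity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "DescriptiveStats",
    "KWResult",
    "DunnResult",
    "describe",
    "kruskal_wallis",
    "dunn_bonferroni",
    "stats_report",
    "POSTHOC_PARAMETERS",
]

#: Parameters entering the pairwise post hoc tests (frequency domain only).
POSTHOC_PARAMETERS = ["fp_khz", "bw10_khz", "bw3_khz"]
#: Parameters summarized descriptively.
DESCRIBE_PARAMETERS = ["ici_ms", "bw10_khz", "bw3_khz", "fp_khz"]


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    q1: float
    q3: float
    sd_defined: bool = True


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class DunnResult:
    pair: tuple[str, str]
    z: float
    p_adj: float


def describe(values) -> DescriptiveStats:
    """Summary statistics; quartiles by linear interpolation at 1+(n-1)p."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    sd_defined = x.size > 1
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # 'linear' = 1+(n-1)p
    return DescriptiveStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if sd_defined else 0.0,
        min=float(np.min(x)),
        max=float(np.max(x)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        sd_defined=sd_defined,
    )


def _ranked(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Pooled midranks split back per group, plus the tie sum Σ(t³−t)."""
    pooled = np.concatenate(groups)
    ranks = ss.rankdata(pooled)  # midranks
    out, i = [], 0
    for g in groups:
        out.append(ranks[i : i + g.size])
        i += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, out, tie_sum


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 1 for g in gs):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: rank statistic undefined")
    return gs


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across k groups."""
    gs = _check_groups(groups)
    N = sum(g.size for g in gs)
    _, per_group, tie_sum = _ranked(gs)
    mean_rank = (N + 1) / 2
    H = 12.0 / (N * (N + 1)) * sum(
        g.size * (np.mean(r) - mean_rank) ** 2 for g, r in zip(gs, per_group)
    )
    correction = 1.0 - tie_sum / (N**3 - N)
    H /= correction
    df = len(gs) - 1
    return KWResult(H=float(H), df=df, p=float(ss.chi2.sf(H, df)))


def dunn_bonferroni(groups, labels: list[str] | None = None) -> list[DunnResult]:
    """Dunn's pairwise z-tests on mean ranks, Bonferroni-adjusted.

    The adjustment multiplies each two-sided p by the number of pairs and
    caps at 1.
    """
    gs = _check_groups(groups)
    k = len(gs)
    labels = labels if labels is not None else [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per group required")
    N = sum(g.size for g in gs)
    _, per_group, tie_sum = _ranked(gs)
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    m = k * (k - 1) // 2
    results = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_term * (1.0 / gs[i].size + 1.0 / gs[j].size))
        z = (float(np.mean(per_group[i])) - float(np.mean(per_group[j]))) / se
        p = min(1.0, 2.0 * float(ss.norm.sf(abs(z))) * m)
        results.append(DunnResult(pair=(labels[i], labels[j]), z=z, p_adj=p))
    return results


def stats_report(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive table plus KW/Dunn p-value tables from a feature table.

    ``features`` is the long per-click table produced by the extractor
    (columns lineage, fp_khz, bw3_khz, bw10_khz, ici_ms).  Returns
    ``{"descriptive": ..., "kruskal_wallis": ..., "dunn": ...}``:
    the descriptive frame mirrors the published per-lineage summary, the
    Dunn frame the pairwise p-value table for the frequency parameters.
    """
    lineages = sorted(features["lineage"].dropna().unique())
    desc_rows = []
    for lineage in lineages:
        sub = features[features["lineage"] == lineage]
        for param in DESCRIBE_PARAMETERS:
            vals = sub[param].dropna().to_numpy()
            if vals.size == 0:
                continue
            d = describe(vals)
            desc_rows.append(
                {
                    "lineage": lineage,
                    "parameter": param,
                    "n": d.n,
                    "mean": d.mean,
                    "sd": d.sd,
                    "min": d.min,
                    "max": d.max,
                    "median": d.median,
                    "q1": d.q1,
                    "q3": d.q3,
                }
            )

    kw_rows, dunn_rows = [], []
    for param in POSTHOC_PARAMETERS:
        groups = [
            features.loc[features["lineage"] == l, param].dropna().to_numpy()
            for l in lineages
        ]
        keep = [(l, g) for l, g in zip(lineages, groups) if g.size]
        if len(keep) < 2:
            continue
        labs, gs = zip(*keep)
        kw = kruskal_wallis(gs)
        kw_rows.append({"parameter": param, "H": kw.H, "df": kw.df, "p": kw.p})
        for r in dunn_bonferroni(gs, list(labs)):
            dunn_rows.append(
                {
                    "parameter": param,
                    "group_a": r.pair[0],
                    "group_b": r.pair[1],
                    "z": r.z,
                    "p_adj": r.p_adj,
                }
            )
    return {
        "descriptive": pd.DataFrame(desc_rows),
        "kruskal_wallis": pd.DataFrame(kw_rows),
        "dunn": pd.DataFrame(dunn_rows),
    }
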