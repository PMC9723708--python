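"""Dissimilarity, rarefaction, removal-rate and turnover statistics.

Bray-Curtis is computed on rarefied counts by default (rarefaction comes
first in the workflow); a relative-abundance mode simply passes
proportions to the same functions.  The rank-sum test switches between
exhaustive enumeration (small samples) and the tie-corrected normal
approximation, so its small-sample p-values are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .io import CommunityTable, sort_batches

logger = logging.getLogger(__name__)

#: pooled sizes up to which the rank-sum null is enumerated exhaustively
EXACT_ENUMERATION_LIMIT = 12


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Multivariate-hypergeometric draw per sample; zero entries stay zero
    and each rarefied sample sums exactly to ``depth``.
    """
    totals = table.counts.sum(axis=1)
    low = totals.index[totals < depth].tolist()
    if low:
        raise ValidationError(
            f"samples below rarefaction depth {depth}: {low}")
    rng = np.random.default_rng(seed)
    out = np.vstack([
        rng.multivariate_hypergeometric(row, depth)
        for row in table.counts.to_numpy()
    ])
    counts = pd.DataFrame(out, index=table.counts.index,
                          columns=table.counts.columns)
    return CommunityTable(counts, table.metadata.copy())


def removal_rate(chem: pd.DataFrame, final_day: int = 5) -> pd.DataFrame:
    """Percent removal per (microcosm, compound, batch).

    ``100 * (C_day0 - C_final) / C_day0``; negative values (apparent
    production) are reported as-is.  Records with a zero day-0
    concentration are skipped with a warning.
    """
    records = []
    grouped = chem.groupby(["microcosm_id", "compound", "batch"], sort=True)
    for (microcosm, compound, batch), grp in grouped:
        by_day = grp.set_index("day")["concentration_ugL"]
        if 0 not in by_day.index or final_day not in by_day.index:
            raise ValidationError(
                f"missing day-0 or day-{final_day} record for "
                f"({microcosm}, {compound}, {batch})")
        c0 = float(by_day.loc[0])
        c5 = float(by_day.loc[final_day])
        if c0 == 0:
            logger.warning("skipping %s/%s/%s: day-0 concentration is zero",
                           microcosm, compound, batch)
            continue
        records.append((microcosm, compound, batch,
                        100.0 * (c0 - c5) / c0))
    return pd.DataFrame(records, columns=["microcosm_id", "compound", "batch",
                                          "removal_percent"])


# -- nonparametric tests --------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a over b, ties counted half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def rank_sum_test(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney rank-sum test (Wilcoxon two-sample).

    Exact by exhaustive enumeration of all C(n_a+n_b, n_a) group
    assignments when the pooled size is at most 12, otherwise the
    tie-corrected normal approximation with continuity correction.
    ``alternative`` is "two-sided", "greater" (a tends larger) or "less".
    Returns (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    u_obs = _u_statistic(a, b)
    if np.unique(np.concatenate([a, b])).size == 1:
        return u_obs, 1.0  # everything tied: no evidence by convention
    n_a, n_b = a.size, b.size
    if n_a + n_b <= EXACT_ENUMERATION_LIMIT:
        # U = (rank sum of group a) - n_a(n_a+1)/2 with midranks, which
        # equals the gt + 0.5*eq pair count, so ties are handled exactly
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2
        combos = np.array(list(combinations(range(n_a + n_b), n_a)))
        u_all = ranks[combos].sum(axis=1) - offset
        p_greater = float((u_all >= u_obs - 1e-9).mean())
        p_less = float((u_all <= u_obs + 1e-9).mean())
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups; all-tied input -> p = 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 nonempty groups")
    if np.unique(np.concatenate(groups)).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# -- turnover vs control --------------------------------------------------

@dataclass
class TurnoverSeries:
    """Treatment-vs-control Bray-Curtis dissimilarity over time."""

    treatment: str
    points: pd.DataFrame        # batch, day, treatment_sample, control_sample, bc
    slope: float                # dissimilarity units per day
    intercept: float
    slope_pvalue: float
    wilcoxon_vs_first: pd.DataFrame  # batch, statistic, pvalue (vs first batch)


def turnover_regression(table: CommunityTable, treatment: str,
                        control_label: str = "Control",
                        matched_only: bool = False) -> TurnoverSeries:
    """OLS of treatment-vs-control dissimilarity against incubation day.

    Response: Bray-Curtis between every treatment sample and every
    contemporaneous control sample (or replicate-matched pairs only with
    ``matched_only``).  Also runs rank-sum comparisons of the first
    batch's dissimilarities against each later batch.
    """
    md = table.metadata
    batches = sort_batches(md.loc[md["treatment"] == treatment, "batch"])
    if not batches:
        raise ValidationError(f"no samples for treatment {treatment!r}")
    counts = table.counts
    rows = []
    for batch in batches:
        t_ids = table.samples_for(treatment, [batch])
        c_ids = table.samples_for(control_label, [batch])
        if not c_ids:
            raise ValidationError(
                f"no control samples for batch {batch}")
        day = int(md.loc[t_ids[0], "day"])
        for t_id in t_ids:
            for c_id in c_ids:
                if matched_only and (md.loc[t_id, "replicate"]
                                     != md.loc[c_id, "replicate"]):
                    continue
                bc = bray_curtis(counts.loc[t_id], counts.loc[c_id])
                rows.append((batch, day, t_id, c_id, bc))
    points = pd.DataFrame(rows, columns=["batch", "day", "treatment_sample",
                                         "control_sample", "bc"])
    if points["day"].nunique() < 3:
        raise DegenerateDataError(
            "slope undefined: fewer than 3 distinct days")
    if np.allclose(points["bc"].to_numpy(), points["bc"].iloc[0]):
        slope, intercept, pval = 0.0, float(points["bc"].iloc[0]), 1.0
    else:
        fit = stats.linregress(points["day"], points["bc"])
        slope, intercept, pval = (float(fit.slope), float(fit.intercept),
                                  float(fit.pvalue))
    first = batches[0]
    base = points.loc[points["batch"] == first, "bc"].to_numpy()
    wil_rows = []
    for batch in batches[1:]:
        later = points.loc[points["batch"] == batch, "bc"].to_numpy()
        u, p = rank_sum_test(base, later, alternative="two-sided")
        wil_rows.append((batch, u, p))
    wilcoxon = pd.DataFrame(wil_rows, columns=["batch", "statistic", "pvalue"])
    return TurnoverSeries(treatment=treatment, points=points, slope=slope,
                          intercept=intercept, slope_pvalue=pval,
                          wilcoxon_vs_first=wilcoxon)
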