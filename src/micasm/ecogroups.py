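"""Ecological grouping of OTUs by growth-phase differential abundance.

Within one treatment, each OTU is tested for phase-directed abundance
shifts on size-factor-normalized counts and classified as:

* sensitive      -- significantly higher in phase 1 than in phases 2 and 3
* opportunistic  -- significantly higher in phase 2 than in phases 1 and 3
* tolerant       -- significantly higher in phase 3 than in phases 1 and 2
* unclassified   -- otherwise

Significance means Benjamini-Hochberg-adjusted p < alpha, with BH
applied jointly over every (OTU x contrast) test in the treatment.  The
default per-contrast test is a one-sided rank-sum on median-of-ratios
normalized counts; a caller may plug in any function mapping two value
arrays to a p-value (for example a negative-binomial GLM Wald test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .community import rank_sum_test
from .copynum import PhaseAssignment
from .errors import ValidationError
from .io import CommunityTable

CATEGORIES = ("sensitive", "opportunistic", "tolerant")
#: category -> the two one-sided contrasts (winner, loser) that define it
CATEGORY_CONTRASTS = {
    "sensitive": ((1, 2), (1, 3)),
    "opportunistic": ((2, 1), (2, 3)),
    "tolerant": ((3, 1), (3, 2)),
}


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the geometric mean of each OTU across samples,
    restricted to OTUs with a strictly positive geometric mean (i.e.
    present everywhere unless a pseudocount is supplied); each sample's
    factor is the median ratio of its counts to that reference.
    """
    arr = counts.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    finite = np.isfinite(log_arr).all(axis=0)
    if not finite.any():
        raise ValidationError(
            "no OTU is present in every sample; retry with a pseudocount")
    geo = np.exp(log_arr[:, finite].mean(axis=0))
    ratios = arr[:, finite] / geo
    factors = np.median(ratios, axis=1)
    if (factors <= 0).any():
        raise ValidationError("non-positive size factor computed")
    return pd.Series(factors, index=counts.index, name="size_factor")


def phase_contrast_test(values: pd.Series, phase_labels: pd.Series,
                        contrast: tuple[int, int],
                        test: Callable | None = None) -> float:
    """One-sided p-value that phase ``contrast[0]`` exceeds ``contrast[1]``.

    ``values`` are normalized abundances for one OTU indexed by sample;
    ``phase_labels`` gives each sample's phase.
    """
    a_phase, b_phase = contrast
    a = values[phase_labels == a_phase].to_numpy(dtype=float)
    b = values[phase_labels == b_phase].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"phase {a_phase if a.size < 2 else b_phase} has fewer "
            "than 2 samples")
    if test is not None:
        return float(test(a, b))
    _, p = rank_sum_test(a, b, alternative="greater")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class OTUGroupCall:
    otu_id: str
    treatment: str
    category: str
    adjusted_p: dict[tuple[int, int], float]
    phase_mean_abundance: dict[int, float]


def classify_otus(table: CommunityTable, phases: PhaseAssignment,
                  treatment: str, alpha: float = 0.05,
                  prevalence_min: float = 0.1,
                  test: Callable | None = None,
                  pseudocount: float = 0.0) -> pd.DataFrame:
    """Sensitive / opportunistic / tolerant calls for one treatment.

    Returns one row per tested OTU with its category, the six adjusted
    contrast p-values and per-phase mean relative abundance.  OTUs
    present in fewer than ``prevalence_min`` of the treatment's samples
    are skipped.
    """
    if phases.n_phases != 3:
        raise ValidationError("ecological grouping needs exactly 3 phases")
    ids = table.samples_for(treatment)
    if not ids:
        raise ValidationError(f"no samples for treatment {treatment!r}")
    sub = table.subset_samples(ids)
    phase_labels = sub.metadata["batch"].map(phases.mapping)
    factors = size_factors(sub.counts, pseudocount=pseudocount)
    normalized = sub.counts.div(factors, axis=0)
    rel = sub.relative_abundance()

    prevalence = (sub.counts > 0).mean(axis=0)
    tested = [o for o in sub.otu_ids if prevalence[o] >= prevalence_min]
    contrasts = sorted({c for pair in CATEGORY_CONTRASTS.values()
                        for c in pair})
    raw, keys = [], []
    for otu in tested:
        for contrast in contrasts:
            raw.append(phase_contrast_test(normalized[otu], phase_labels,
                                           contrast, test=test))
            keys.append((otu, contrast))
    adjusted = bh_adjust(raw)
    adj_map = dict(zip(keys, adjusted))

    rows = []
    for otu in tested:
        hits = [cat for cat, (c1, c2) in CATEGORY_CONTRASTS.items()
                if adj_map[(otu, c1)] < alpha and adj_map[(otu, c2)] < alpha]
        # directional contrasts conflict, so at most one category can fire
        assert len(hits) <= 1, f"conflicting category calls for {otu}"
        category = hits[0] if hits else "unclassified"
        row = {"otu_id": otu, "treatment": treatment, "category": category}
        for contrast in contrasts:
            row[f"padj_{contrast[0]}gt{contrast[1]}"] = adj_map[(otu, contrast)]
        for phase in (1, 2, 3):
            sel = phase_labels.index[phase_labels == phase]
            row[f"mean_rel_abundance_phase{phase}"] = float(
                rel.loc[sel, otu].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def category_counts(calls: pd.DataFrame) -> pd.Series:
    """Summary table: number of OTUs per ecological category."""
    counts = calls["category"].value_counts()
    return counts.reindex([*CATEGORIES, "unclassified"], fill_value=0)
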