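"""Dissimilarity-overlap (DOC) analysis within a treatment over time.

For every unordered sample pair the overlap is the mean relative
abundance mass carried by the taxa the two samples share, and the
dissimilarity is the root Jensen-Shannon divergence of the shared
fractions renormalized to sum to 1.  A linear slope is fitted to the
high-overlap region (above the median overlap by default) and the
fraction of bootstrap slope refits that come out negative is reported --
a negative relation at high overlap is the signature of shared
("universal") taxon dynamics across the communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .io import CommunityTable


def overlap(x, y) -> float:
    """Shared-taxon abundance mass O = 0.5 * sum_{i in S} (x_i + y_i).

    ``x`` and ``y`` are relative-abundance vectors (each summing to 1);
    S is the set of taxa present in both.  Disjoint supports give 0 and
    the pair is excluded from DOC analysis upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    shared = (x > 0) & (y > 0)
    return float(0.5 * (x[shared].sum() + y[shared].sum()))


def rjsd(x, y) -> float:
    """Root Jensen-Shannon divergence, base-2 logs, range [0, 1].

    rJSD = sqrt(0.5 KL(x||M) + 0.5 KL(y||M)) with M = (x+y)/2 and the
    convention 0*log(0/.) = 0.  Inputs must be distributions on the same
    support (each sums to 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if abs(x.sum() - 1) > 1e-8 or abs(y.sum() - 1) > 1e-8:
        raise ValidationError("each vector must sum to 1")
    m = 0.5 * (x + y)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_x = np.where(x > 0, x * np.log2(x / m), 0.0).sum()
        kl_y = np.where(y > 0, y * np.log2(y / m), 0.0).sum()
    return float(np.sqrt(max(0.0, 0.5 * kl_x + 0.5 * kl_y)))


def _pair_point(xi: np.ndarray, yi: np.ndarray) -> tuple[float, float] | None:
    shared = (xi > 0) & (yi > 0)
    if not shared.any():
        return None
    o = 0.5 * (xi[shared].sum() + yi[shared].sum())
    xs = xi[shared] / xi[shared].sum()
    ys = yi[shared] / yi[shared].sum()
    return o, rjsd(xs, ys)


def _fit_slope(points: np.ndarray, cutoff: float) -> tuple[float, float]:
    sel = points[points[:, 0] > cutoff]
    if sel.shape[0] < 3:
        raise DegenerateDataError(
            f"fewer than 3 points above overlap cutoff {cutoff:.4f}")
    if np.allclose(sel[:, 0], sel[0, 0]) or np.allclose(sel[:, 1], sel[0, 1]):
        raise DegenerateDataError(
            "slope undefined: zero variance above the overlap cutoff")
    fit = stats.linregress(sel[:, 0], sel[:, 1])
    return float(fit.slope), float(fit.intercept)


@dataclass
class DOCResult:
    treatment: str
    points: pd.DataFrame        # sample_a, sample_b, overlap, dissimilarity
    cutoff: float
    slope: float                # dissimilarity per unit overlap
    intercept: float
    fraction_negative: float    # share of bootstrap slopes < 0
    n_boot: int                 # successful bootstrap refits
    n_excluded: int             # pairs with no shared taxa


def doc_analysis(table: CommunityTable, treatment: str,
                 cutoff: float | None = None, n_boot: int = 1000,
                 seed: int = 0) -> DOCResult:
    """DOC statistic for all within-treatment sample pairs.

    ``cutoff=None`` uses the median overlap of the included pairs.  The
    bootstrap resamples SAMPLES with replacement (pairs sharing a sample
    are not independent), rebuilds the pair cloud with the original
    cutoff and refits; pairs formed by two copies of the same original
    sample are skipped.
    """
    ids = table.samples_for(treatment)
    if len(ids) < 3:
        raise ValidationError(
            f"need >= 3 samples in treatment {treatment!r}")
    rel = table.subset_samples(ids).relative_abundance().to_numpy()
    n = len(ids)
    rows, arr = [], []
    n_excluded = 0
    for i, j in combinations(range(n), 2):
        point = _pair_point(rel[i], rel[j])
        if point is None:
            n_excluded += 1
            continue
        rows.append((ids[i], ids[j], point[0], point[1]))
        arr.append(point)
    points = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                         "overlap", "dissimilarity"])
    arr = np.asarray(arr)
    if cutoff is None:
        cutoff = float(np.median(arr[:, 0]))
    slope, intercept = _fit_slope(arr, cutoff)

    rng = np.random.default_rng(seed)
    neg = 0
    ok = 0
    for _ in range(n_boot):
        draw = rng.integers(0, n, size=n)
        boot = []
        for ii, jj in combinations(range(n), 2):
            a, b = draw[ii], draw[jj]
            if a == b:
                continue
            point = _pair_point(rel[a], rel[b])
            if point is not None:
                boot.append(point)
        try:
            b_slope, _ = _fit_slope(np.asarray(boot), cutoff)
        except (DegenerateDataError, IndexError):
            continue
        ok += 1
        if b_slope < 0:
            neg += 1
    if ok == 0:
        raise DegenerateDataError("every bootstrap refit was degenerate")
    return DOCResult(treatment=treatment, points=points, cutoff=cutoff,
                     slope=slope, intercept=intercept,
                     fraction_negative=neg / ok, n_boot=ok,
                     n_excluded=n_excluded)
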