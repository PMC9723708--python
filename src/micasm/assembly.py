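"""Null-model partitioning of community assembly processes.

Implements the standard five-process framework: phylogenetic turnover is
measured by the abundance-weighted beta mean nearest taxon distance
(betaMNTD) and standardized against a tip-shuffle null into betaNTI;
taxonomic turnover is positioned within a probabilistic assembly null by
the Raup-Crick metric computed with Bray-Curtis (RC_bray).  Each sample
pair is then classified as variable selection, homogeneous selection,
dispersal limitation, homogenizing dispersal, or drift, and per-phase
process fractions are tallied for every treatment-vs-control comparison.

betaNTI is the standardized deviate (observed - null mean) / null sd;
the +/-2 thresholds are z-score thresholds.  The default sign convention
maps betaNTI > +2 (observed phylogenetic turnover exceeding the null) to
variable selection and betaNTI < -2 to homogeneous selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import bray_curtis
from .errors import DegenerateDataError, ValidationError
from .io import CommunityTable

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "drift")

_NULL_CHUNK = 250  # permutation replicates processed per vectorized block


def bmntd(x, y, D) -> float:
    """Abundance-weighted beta mean nearest taxon distance.

    ``x`` and ``y`` are abundance vectors aligned to the rows/columns of
    the patristic matrix ``D``; abundances are normalized over their own
    support.  For each taxon present in one community the distance to its
    nearest relative present in the other community is averaged with
    abundance weights, and the two directions are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    if x.shape[0] != D.shape[0] or y.shape[0] != D.shape[0]:
        raise ValidationError("vectors must align with the distance matrix")
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValidationError("betaMNTD undefined for an empty community")
    wx = x[ix] / x[ix].sum()
    wy = y[iy] / y[iy].sum()
    block = D[np.ix_(ix, iy)]
    return float(0.5 * (wx @ block.min(axis=1) + wy @ block.min(axis=0)))


@dataclass
class BntiResult:
    bnti: float
    observed: float
    null_mean: float
    null_sd: float
    n_null: int


def bnti(x, y, D, n_null: int = 999, seed: int = 0) -> BntiResult:
    """betaNTI of one sample pair against a tip-shuffle null.

    Each null replicate applies one random permutation to the taxa of the
    regional pool (rows and columns of ``D`` simultaneously) and
    recomputes betaMNTD with the observed abundances.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    observed = bmntd(x, y, D)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    wx = x[ix] / x[ix].sum()
    wy = y[iy] / y[iy].sum()
    p = D.shape[0]
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    done = 0
    while done < n_null:
        m = min(_NULL_CHUNK, n_null - done)
        perms = np.vstack([rng.permutation(p) for _ in range(m)])
        rows = perms[:, ix]              # m x |x|
        cols = perms[:, iy]              # m x |y|
        block = D[rows[:, :, None], cols[:, None, :]]  # m x |x| x |y|
        nulls[done:done + m] = 0.5 * (block.min(axis=2) @ wx
                                      + block.min(axis=1) @ wy)
        done += m
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd < 1e-12:
        raise DegenerateDataError(
            "betaNTI undefined: tip-shuffle null has zero spread")
    return BntiResult(bnti=(observed - mu) / sd, observed=observed,
                      null_mean=mu, null_sd=sd, n_null=n_null)


def raup_crick_bray(x_counts, y_counts, occupancy, regional_abundance,
                    n_null: int = 999, seed: int = 0) -> float:
    """Raup-Crick metric on Bray-Curtis, rescaled to [-1, 1].

    Null replicate: for each of the two samples, draw its observed
    richness of taxa from the regional pool without replacement with
    probability proportional to occupancy frequency, then allocate the
    sample's observed total count across the drawn taxa: one individual
    per drawn taxon (so null richness matches observed richness), the
    remainder by a multinomial proportional to regional relative
    abundance.  RC_bray positions the observed Bray-Curtis within the
    null distribution (ties half-weighted).
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    ab = np.asarray(regional_abundance, dtype=float)
    p = occ.shape[0]
    if x.shape[0] != p or y.shape[0] != p or ab.shape[0] != p:
        raise ValidationError("all vectors must align with the pool")
    for v in (x, y):
        present = v > 0
        if not present.any():
            raise ValidationError("each sample needs richness >= 1")
        if (occ[present] <= 0).any() or (ab[present] <= 0).any():
            raise ValidationError("pool is missing observed taxa")
    obs = bray_curtis(x, y)
    rich = (int((x > 0).sum()), int((y > 0).sum()))
    totals = (int(round(x.sum())), int(round(y.sum())))
    rng = np.random.default_rng(seed)
    log_occ = np.log(np.where(occ > 0, occ, np.nan))
    nulls = np.empty((n_null, 2, p))
    for s in range(2):
        k, tot = rich[s], totals[s]
        # Gumbel top-k = weighted sampling without replacement, vectorized
        keys = np.where(np.isnan(log_occ), -np.inf, log_occ)[None, :] \
            + rng.gumbel(size=(n_null, p))
        chosen = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        sample = np.zeros((n_null, p))
        for r in range(n_null):
            idx = chosen[r]
            w = ab[idx]
            sample[r, idx] = 1 + rng.multinomial(tot - k, w / w.sum())
        nulls[:, s, :] = sample
    diff = np.abs(nulls[:, 0, :] - nulls[:, 1, :]).sum(axis=1)
    tot_sum = (nulls[:, 0, :] + nulls[:, 1, :]).sum(axis=1)
    null_bc = diff / tot_sum
    eps = 1e-12
    below = (null_bc < obs - eps).sum()
    ties = (np.abs(null_bc - obs) <= eps).sum()
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    return float(rc)


def classify_pair(bnti_value: float, rc_bray: float,
                  convention: str = "framework") -> str:
    """Map (betaNTI, RC_bray) to one of the five assembly processes.

    ``convention='framework'`` (default): betaNTI > +2 -> variable
    selection, < -2 -> homogeneous selection.  ``convention='inverted'``
    swaps the two selection labels.
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc_bray)):
        raise ValidationError("betaNTI and RC_bray must be finite")
    if convention not in ("framework", "inverted"):
        raise ValidationError(f"unknown sign convention {convention!r}")
    hi, lo = ("variable_selection", "homogeneous_selection")
    if convention == "inverted":
        hi, lo = lo, hi
    if bnti_value > 2:
        return hi
    if bnti_value < -2:
        return lo
    if rc_bray > 0.95:
        return "dispersal_limitation"
    if rc_bray < -0.95:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessFractions:
    """Per-phase process fractions plus the per-pair records behind them."""

    treatment: str
    fractions: pd.DataFrame   # index phase, columns PROCESSES, rows sum to 1
    pairs: pd.DataFrame       # one row per sample pair with bnti/rc/label


def process_fractions(table: CommunityTable, D: pd.DataFrame,
                      phases: dict[str, int], treatment: str,
                      control_label: str = "Control", n_null: int = 999,
                      seed: int = 0, convention: str = "framework",
                      pool: str = "phase") -> ProcessFractions:
    """Assembly-process fractions for one treatment-vs-control comparison.

    Pairs are all (treatment sample x control sample) combinations whose
    batches fall in the same growth phase.  The regional pool for both
    null models is the union of taxa observed in the two groups within
    the phase (``pool='phase'``) or across the whole experiment
    (``pool='global'``).
    """
    md = table.metadata
    unknown = set(md["batch"]) - set(phases)
    if unknown:
        raise ValidationError(f"batches without a phase: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    counts = table.counts
    if list(D.index) != list(D.columns):
        raise ValidationError("distance matrix must be square and aligned")
    missing = set(counts.columns) - set(D.index)
    if missing:
        raise ValidationError(f"OTU ids absent from tree: {sorted(missing)}")

    if pool == "global":
        pool_samples_all = table.samples_for(treatment) + \
            table.samples_for(control_label)
    elif pool != "phase":
        raise ValidationError(f"unknown pool mode {pool!r}")

    rows = []
    phase_ids = sorted(set(phases.values()))
    pair_seeds = iter(ss.spawn(2 * sum(
        len(table.samples_for(treatment,
                              [b for b, ph in phases.items() if ph == k]))
        * len(table.samples_for(control_label,
                                [b for b, ph in phases.items() if ph == k]))
        for k in phase_ids)))
    for phase in phase_ids:
        batches = [b for b, ph in phases.items() if ph == phase]
        t_ids = table.samples_for(treatment, batches)
        c_ids = table.samples_for(control_label, batches)
        if not t_ids or not c_ids:
            raise ValidationError(f"empty pair set for phase {phase}")
        if pool == "phase":
            pool_samples = t_ids + c_ids
        else:
            pool_samples = pool_samples_all
        sub = counts.loc[pool_samples]
        taxa = sub.columns[(sub > 0).any(axis=0)]
        occ = (sub[taxa] > 0).mean(axis=0).to_numpy()
        rel = sub[taxa].div(sub[taxa].sum(axis=1), axis=0)
        regional = rel.mean(axis=0).to_numpy()
        Dsub = D.loc[taxa, taxa].to_numpy()
        for t_id in t_ids:
            for c_id in c_ids:
                xv = counts.loc[t_id, taxa].to_numpy(dtype=float)
                yv = counts.loc[c_id, taxa].to_numpy(dtype=float)
                s1 = int(next(pair_seeds).generate_state(1)[0] % (2**31))
                s2 = int(next(pair_seeds).generate_state(1)[0] % (2**31))
                res = bnti(xv / xv.sum(), yv / yv.sum(), Dsub,
                           n_null=n_null, seed=s1)
                rc = raup_crick_bray(xv, yv, occ, regional,
                                     n_null=n_null, seed=s2)
                label = classify_pair(res.bnti, rc, convention=convention)
                rows.append((phase, t_id, c_id, res.observed, res.null_mean,
                             res.null_sd, res.bnti,
                             bray_curtis(xv, yv), rc, label))
    pairs = pd.DataFrame(rows, columns=[
        "phase", "treatment_sample", "control_sample", "bmntd_obs",
        "bmntd_null_mean", "bmntd_null_sd", "bnti", "bc_obs", "rc_bray",
        "process"])
    frac = (pairs.groupby("phase")["process"].value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=list(PROCESSES), fill_value=0.0))
    frac.columns.name = None
    return ProcessFractions(treatment=treatment, fractions=frac, pairs=pairs)
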