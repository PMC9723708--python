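"""Community 16S copy number and growth-phase inference.

The abundance-weighted mean 16S rRNA gene copy number of a sample is a
proxy for the community's growth strategy (fast responders carry more
rRNA operons), so its trajectory across serial-transfer batches tracks
the growth progression of the whole experiment.  Batches are grouped
into K contiguous growth phases by complete-linkage hierarchical
clustering of their copy-number profiles, with an explicit
time-contiguity constraint resolved by exhaustive search over contiguous
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .io import CommunityTable, sort_batches


def weighted_mean_copy_number(sample_counts: pd.Series,
                              copy_numbers: pd.Series) -> float:
    """Abundance-weighted mean copy number over the assigned OTUs.

    OTUs without a copy-number assignment are dropped and the remaining
    relative abundances renormalized to sum to 1 (the map may be partial).
    """
    counts = sample_counts[sample_counts > 0]
    assigned = counts.index.intersection(copy_numbers.index)
    if assigned.empty:
        raise ValidationError(
            "no OTU in this sample has a copy-number assignment")
    w = counts.loc[assigned].to_numpy(dtype=float)
    c = copy_numbers.loc[assigned].to_numpy(dtype=float)
    return float((w / w.sum()) @ c)


def sample_copy_numbers(table: CommunityTable,
                        copy_numbers: pd.Series,
                        corrected: bool = False) -> pd.Series:
    """Weighted mean copy number for every sample in the table.

    ``corrected=True`` divides read counts by copy number first (gene
    counts -> cell counts) before weighting; the default weights by
    read-based relative abundance, matching the usual community-trait
    calculation.
    """
    out = {}
    for sid in table.sample_ids:
        counts = table.counts.loc[sid]
        if corrected:
            assigned = counts.index.intersection(copy_numbers.index)
            counts = counts.loc[assigned] / copy_numbers.loc[assigned]
        out[sid] = weighted_mean_copy_number(counts, copy_numbers)
    return pd.Series(out, name="mean_copy_number")


@dataclass
class PhaseAssignment:
    """Contiguous mapping of batch labels to growth phases 1..K."""

    mapping: dict[str, int]

    def __post_init__(self) -> None:
        batches = sort_batches(self.mapping)
        phases = [self.mapping[b] for b in batches]
        if sorted(set(phases)) != list(range(1, max(phases) + 1)):
            raise ValidationError("phases must be numbered 1..K")
        for a, b in zip(phases, phases[1:]):
            if b not in (a, a + 1):
                raise ValidationError(
                    "phases must be contiguous in batch order")

    @property
    def n_phases(self) -> int:
        return max(self.mapping.values())

    def batches_in(self, phase: int) -> list[str]:
        return [b for b in sort_batches(self.mapping)
                if self.mapping[b] == phase]


def _contiguous_partitions(n: int, k: int):
    """All ways to cut positions 0..n-1 into k contiguous blocks."""
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        yield [list(range(bounds[i], bounds[i + 1])) for i in range(k)]


def _partition_score(profiles: np.ndarray, blocks) -> float:
    score = 0.0
    for block in blocks:
        sub = profiles[block]
        score += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return score


def best_contiguous_partition(profiles: np.ndarray, k: int) -> list[list[int]]:
    """Minimal within-phase-variance contiguous partition.

    Ties are broken toward equal-as-possible phase sizes, then toward
    the lexicographically smallest cut positions, so the result is
    deterministic.
    """
    n = profiles.shape[0]
    best, best_key = None, None
    for blocks in _contiguous_partitions(n, k):
        sizes = [len(b) for b in blocks]
        key = (round(_partition_score(profiles, blocks), 12),
               max(sizes) - min(sizes),
               tuple(b[0] for b in blocks[1:]))
        if best_key is None or key < best_key:
            best, best_key = blocks, key
    return best


def phase_clustering(batch_profiles: pd.DataFrame | pd.Series,
                     k: int = 3) -> PhaseAssignment:
    """Group batches into K contiguous growth phases.

    ``batch_profiles`` holds one row per batch (indexed by batch label)
    of per-microcosm mean copy numbers from the treated arms; a Series
    of scalars is accepted for a single profile value per batch.
    Complete-linkage hierarchical clustering with Bray-Curtis
    dissimilarity is cut at K groups; if the cut is not contiguous in
    batch order (or is degenerate), the assignment falls back to the
    exhaustive minimal-variance contiguous partition.
    """
    if isinstance(batch_profiles, pd.Series):
        batch_profiles = batch_profiles.to_frame("profile")
    batches = sort_batches(batch_profiles.index)
    if k > len(batches):
        raise ValidationError("more phases requested than batches")
    profiles = batch_profiles.loc[batches].to_numpy(dtype=float)
    dist = pdist(profiles, metric="braycurtis")
    labels = None
    if np.all(np.isfinite(dist)) and dist.max() > 0:
        z = linkage(dist, method="complete")
        raw = fcluster(z, t=k, criterion="maxclust")
        if len(set(raw)) == k and _is_contiguous(raw):
            labels = raw
    if labels is None:
        blocks = best_contiguous_partition(profiles, k)
        labels = np.empty(len(batches), dtype=int)
        for phase, block in enumerate(blocks, start=1):
            labels[block] = phase
    # renumber phases in batch order 1..K
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    return PhaseAssignment({b: order[lab] for b, lab in zip(batches, labels)})


def _is_contiguous(labels) -> bool:
    seen = []
    for lab in labels:
        if seen and lab == seen[-1]:
            continue
        if lab in seen:
            return False
        seen.append(lab)
    return True
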