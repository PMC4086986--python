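"""Barcode-gap discovery over a series of prior divergence thresholds.

The scan follows the automatic barcode gap discovery logic: for each prior
maximal intraspecific divergence P in a geometric series, find the first
significant gap in the sorted list of pairwise distances at or beyond P,
partition the specimens by single linkage below the gap, then recursively
re-scan within each resulting cluster until nothing splits further. The
most inclusive (lumper) and least inclusive (splitter) partitions across
the whole series are the products consumed downstream.

Gap statistic
-------------
Sorted distances d_1 <= ... <= d_m define consecutive gaps
w_i = d_{i+1} - d_i. A gap is *eligible* for prior P when (a) its upper
end d_{i+1} >= P (the prior caps plausible intraspecific distances, so a
gap closing below P cannot be the barcode gap) and (b) at least 0.5% of
the distances lie on each side of it -- a species boundary separates
distance mass, whereas the extreme tails of any continuous sample contain
large spacings with negligible mass beyond them. The first eligible gap
with

    w_i > X * max(mean of the preceding `window` gaps, P)

is reported; the partition threshold is the gap midpoint (any value inside
the gap yields the same single-linkage components; the midpoint is
deterministic). X is the relative gap width: the factor by which the
barcode gap must dominate both the local spacing of the distance
distribution and the prior scale itself. Its default (10) is calibrated so
that distances drawn from one continuous unimodal distribution essentially
never produce a gap, while genuine bimodal barcode structure always does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistMatrix
from .errors import InputError, NoStructureError
from .io_formats import Partition

__all__ = [
    "PriorSeries",
    "GapScanResult",
    "PriorResult",
    "prior_series",
    "find_gap",
    "partition_at",
    "abgd_scan",
    "lumper_splitter",
    "DEFAULT_PMIN",
    "DEFAULT_PMAX",
    "DEFAULT_STEPS",
    "DEFAULT_REL_WIDTH",
    "DEFAULT_MIN_GROUP",
]

DEFAULT_PMIN = 0.001
DEFAULT_PMAX = 0.2
DEFAULT_STEPS = 10
DEFAULT_REL_WIDTH = 10.0
DEFAULT_MIN_GROUP = 4
MAX_RECURSION_DEPTH = 10


@dataclass(frozen=True)
class PriorSeries:
    """Geometric (log-even) series of prior intraspecific divergences."""

    values: tuple[float, ...]

    @property
    def pmin(self) -> float:
        return self.values[0]

    @property
    def pmax(self) -> float:
        return self.values[-1]

    @property
    def steps(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def prior_series(pmin: float, pmax: float, steps: int) -> PriorSeries:
    """Geometric sequence from pmin to pmax inclusive with `steps` values."""
    if pmin <= 0 or pmax <= 0:
        raise InputError("prior bounds must be positive")
    if pmin > pmax:
        raise InputError(f"inverted prior bounds: pmin={pmin} > pmax={pmax}")
    if steps < 1:
        raise InputError("steps must be >= 1")
    if steps == 1:
        if not math.isclose(pmin, pmax):
            raise InputError("steps=1 requires pmin == pmax")
        return PriorSeries(values=(pmin,))
    ratio = pmax / pmin
    vals = tuple(pmin * ratio ** (i / (steps - 1)) for i in range(steps))
    return PriorSeries(values=vals)


def default_window(n_distances: int) -> int:
    """Window = ceil(5% of the distance count), clamped to [10, 1000]."""
    return int(np.clip(math.ceil(0.05 * n_distances), 10, 1000))


def find_gap(
    dists, prior: float, rel_width: float = DEFAULT_REL_WIDTH,
    window: int | None = None,
) -> float | None:
    """Locate the barcode gap in an ascending list of pairwise distances.

    Returns the midpoint of the first eligible significant gap, or ``None``
    when no gap qualifies. See the module docstring for the statistic.
    """
    d = np.asarray(dists, dtype=float)
    if d.size == 0:
        raise InputError("empty distance list")
    if np.any(np.diff(d) < 0):
        raise InputError("distance list must be sorted ascending")
    if rel_width <= 0:
        raise InputError("rel_width must be positive")
    if window is None:
        window = default_window(d.size)
    if window < 2:
        raise InputError("window must be >= 2")
    if d.size < 2:
        return None

    w = np.diff(d)
    m = w.size
    # rolling mean of the preceding `window` gaps (0.0 when none precede)
    csum = np.concatenate([[0.0], np.cumsum(w)])
    start = np.maximum(np.arange(m) - window, 0)
    counts = np.arange(m) - start
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(
            counts > 0, (csum[np.arange(m)] - csum[start]) / np.maximum(counts, 1), 0.0
        )
    bar = rel_width * np.maximum(local_mean, prior)
    # a species gap must leave distance mass on both sides
    min_side = max(1, math.ceil(0.005 * d.size))
    side_ok = (np.arange(m) + 1 >= min_side) & (m - np.arange(m) >= min_side)
    eligible = (d[1:] >= prior) & side_ok & (w > bar)
    hits = np.nonzero(eligible)[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    return float((d[i] + d[i + 1]) / 2.0)


def partition_at(dist: DistMatrix, threshold: float) -> Partition:
    """Single-linkage partition: connected components of distances < t.

    Missing (NaN) distances never connect; saturated sentinel distances
    behave as large distances. Cluster labels are deterministic, numbered
    by order of the first member in the matrix id order.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        adj = dist.values < threshold  # NaN compares False
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    # relabel components in order of first appearance
    order: dict[int, int] = {}
    for lab in labels:
        order.setdefault(int(lab), len(order) + 1)
    assignment = {
        sid: f"psh_{order[int(lab)]:03d}" for sid, lab in zip(dist.ids, labels)
    }
    return Partition(assignment)


@dataclass(frozen=True)
class PriorResult:
    """Scan outcome for a single prior threshold."""

    prior: float
    gap_threshold: float | None
    initial: Partition
    recursive: Partition

    @property
    def no_gap(self) -> bool:
        return self.gap_threshold is None


@dataclass(frozen=True)
class GapScanResult:
    """Per-prior partitions plus the scan's provenance parameters."""

    results: tuple[PriorResult, ...]
    rel_width: float
    window: int
    model: str
    min_group: int = DEFAULT_MIN_GROUP

    def __iter__(self):
        return iter(self.results)

    def gapped(self) -> tuple[PriorResult, ...]:
        return tuple(r for r in self.results if not r.no_gap)


def _recursive_refine(
    dist: DistMatrix,
    partition: Partition,
    prior: float,
    rel_width: float,
    min_group: int,
) -> Partition:
    """Re-scan within each cluster until no cluster of size >= min_group
    splits further (depth capped)."""
    current = partition
    for _depth in range(MAX_RECURSION_DEPTH):
        changed = False
        new_clusters: list[list[str]] = []
        for cluster in current.clusters:
            members = [sid for sid in dist.ids if sid in cluster]
            if len(members) < min_group:
                new_clusters.append(members)
                continue
            sub = dist.submatrix(members)
            cond = np.sort(sub.condensed())
            if cond.size < 2:
                new_clusters.append(members)
                continue
            t = find_gap(
                cond, prior, rel_width, window=default_window(cond.size)
            )
            if t is None:
                new_clusters.append(members)
                continue
            subpart = partition_at(sub, t)
            if subpart.n_clusters <= 1:
                new_clusters.append(members)
                continue
            changed = True
            for sc in subpart.clusters:
                new_clusters.append([s for s in members if s in sc])
        if not changed:
            break
        current = Partition.from_clusters(new_clusters)
    # renumber deterministically by matrix id order of first members
    ordered = sorted(
        (c for c in current.clusters),
        key=lambda c: min(dist.ids.index(s) for s in c),
    )
    return Partition.from_clusters(ordered)


def abgd_scan(
    dist: DistMatrix,
    priors: PriorSeries | None = None,
    rel_width: float = DEFAULT_REL_WIDTH,
    min_group: int = DEFAULT_MIN_GROUP,
) -> GapScanResult:
    """Scan the prior series: initial and recursive partition per prior.

    Priors with no detected initial gap yield a flagged single-cluster
    partition (``no_gap``).
    """
    if priors is None:
        priors = prior_series(DEFAULT_PMIN, DEFAULT_PMAX, DEFAULT_STEPS)
    cond = np.sort(dist.condensed())
    if cond.size == 0:
        raise InputError("distance matrix has no comparable pairs")
    window = default_window(cond.size)
    results = []
    one_cluster = Partition({sid: "psh_001" for sid in dist.ids})
    for prior in priors:
        t = find_gap(cond, prior, rel_width, window=window)
        if t is None:
            results.append(
                PriorResult(
                    prior=prior,
                    gap_threshold=None,
                    initial=one_cluster,
                    recursive=one_cluster,
                )
            )
            continue
        initial = partition_at(dist, t)
        recursive = _recursive_refine(dist, initial, prior, rel_width, min_group)
        results.append(
            PriorResult(
                prior=prior, gap_threshold=t, initial=initial,
                recursive=recursive,
            )
        )
    return GapScanResult(
        results=tuple(results),
        rel_width=rel_width,
        window=window,
        model=dist.model,
        min_group=min_group,
    )


def lumper_splitter(scan: GapScanResult) -> tuple[Partition, Partition]:
    """Most inclusive (lumper) and least inclusive (splitter) partitions.

    Only priors with a detected gap participate; both the initial and the
    recursive partition of each such prior are candidates. Ties are broken
    toward the larger prior for the lumper and the smaller prior for the
    splitter. Raises :class:`NoStructureError` when no prior found a gap.
    """
    gapped = scan.gapped()
    if not gapped:
        raise NoStructureError("no prior in the scan produced a barcode gap")
    lumper: Partition | None = None
    splitter: Partition | None = None
    for res in gapped:  # ascending priors
        for part in (res.initial, res.recursive):
            if lumper is None or part.n_clusters <= lumper.n_clusters:
                lumper = part
            if splitter is None or part.n_clusters > splitter.n_clusters:
                splitter = part
    assert lumper is not None and splitter is not None
    return lumper, splitter
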