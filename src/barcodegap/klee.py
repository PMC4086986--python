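"""Indicator vectors, Klee correlation matrices and the >=0.90 merge rule.

An indicator vector is a unit-normalised one-hot encoding of an aligned
sequence: four channels (A, C, G, T) per alignment column, with gaps, N
and IUPAC ambiguity codes contributing zero in all channels. The inner
product of two such vectors is a cosine similarity in [0, 1] that, for
gap-free sequences, equals the fraction of matching columns.

A Klee matrix correlates one representative (the cluster medoid) per
splitter PSH, with rows/columns ordered so splitter PSHs belonging to the
same lumper PSH form contiguous blocks. Within each lumper block, splitter
PSHs whose representatives correlate at or above the merge threshold
(default 0.90) are joined into connected components: components of size
greater than one are proposals to merge the corresponding splits back.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distances import DistMatrix
from .errors import InputError
from .io_formats import AlignedSeqSet, Partition

__all__ = [
    "IndicatorVector",
    "KleeMatrix",
    "indicator_vector",
    "correlation",
    "representatives",
    "klee_matrix",
    "merge_candidates",
    "render_klee",
    "MERGE_THRESHOLD",
]

MERGE_THRESHOLD = 0.90


@dataclass(frozen=True)
class IndicatorVector:
    """Unit-norm one-hot encoding of one aligned sequence."""

    specimen_id: str
    vector: np.ndarray  # shape (4 * L,)
    support: int  # number of unambiguous A/C/G/T columns

    @property
    def empty(self) -> bool:
        return self.support == 0


def _onehot(seq: str) -> tuple[np.ndarray, int]:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mat = np.zeros((raw.size, 4), dtype=np.float64)
    for ch, base in enumerate("ACGT"):
        mat[raw == ord(base), ch] = 1.0
    support = int(mat.sum())
    return mat.reshape(-1), support


def indicator_vector(seq: str, specimen_id: str = "") -> IndicatorVector:
    """Encode an aligned sequence as a unit-norm indicator vector.

    An all-gap/ambiguous sequence yields a zero vector flagged empty.
    """
    vec, support = _onehot(seq.upper())
    if support > 0:
        vec = vec / np.sqrt(support)
    return IndicatorVector(specimen_id=specimen_id, vector=vec, support=support)


def correlation(u: IndicatorVector, v: IndicatorVector) -> float:
    """Inner product of two unit-norm indicator vectors, in [0, 1].

    Returns NaN when either operand is empty; raises on length mismatch.
    """
    if u.vector.shape != v.vector.shape:
        raise InputError("indicator vectors encode different alignment lengths")
    if u.empty or v.empty:
        return float("nan")
    return float(np.clip(np.dot(u.vector, v.vector), 0.0, 1.0))


def representatives(
    partition: Partition, dist: DistMatrix
) -> dict[str, str]:
    """Pick one representative specimen per cluster: the medoid.

    The medoid minimises the mean within-cluster distance; ties are broken
    by matrix input order. Missing (NaN) distances count as maximal.
    """
    ids = set(dist.ids)
    unknown = [s for s in partition.specimen_ids if s not in ids]
    if unknown:
        raise InputError(f"specimens absent from distance matrix: {unknown[:5]}")
    reps: dict[str, str] = {}
    finite = dist.values[np.isfinite(dist.values)]
    penalty = (finite.max() if finite.size else 1.0) * 10 + 1.0
    for label in partition.labels:
        members = [s for s in dist.ids if s in partition.members(label)]
        if len(members) == 1:
            reps[label] = members[0]
            continue
        sub = dist.submatrix(members).values.copy()
        sub[np.isnan(sub)] = penalty
        mean_d = sub.sum(axis=1) / (len(members) - 1)
        reps[label] = members[int(np.argmin(mean_d))]
    return reps


@dataclass(frozen=True)
class KleeMatrix:
    """Correlation matrix of splitter-PSH representatives, block-ordered."""

    psh_labels: tuple[str, ...]
    representatives: dict[str, str]
    values: np.ndarray
    block_order: tuple[tuple[str, tuple[str, ...]], ...]  # (lumper, splitters)

    @property
    def n(self) -> int:
        return len(self.psh_labels)

    def block_of(self, psh_label: str) -> str:
        for lumper_label, members in self.block_order:
            if psh_label in members:
                return lumper_label
        raise KeyError(psh_label)

    def value(self, a: str, b: str) -> float:
        ia = self.psh_labels.index(a)
        ib = self.psh_labels.index(b)
        return float(self.values[ia, ib])

    def block_sizes(self) -> tuple[int, ...]:
        return tuple(len(members) for _, members in self.block_order)


def klee_matrix(
    aln: AlignedSeqSet,
    splitter: Partition,
    lumper: Partition,
    dist: DistMatrix,
) -> KleeMatrix:
    """Build the representative correlation matrix for a splitter partition.

    Requires the splitter to refine (or equal) the lumper on shared
    specimens; rows/columns are ordered so splitter PSHs within the same
    lumper PSH are adjacent, blocks following lumper first-appearance.
    """
    shared = [s for s in splitter.specimen_ids if s in lumper.assignment]
    if not splitter.restrict(shared).refines(lumper.restrict(shared)):
        raise InputError("splitter partition does not refine the lumper")

    reps = representatives(splitter, dist)
    # order splitter labels by lumper block, then first appearance
    blocks: dict[str, list[str]] = {}
    for lum_label in lumper.labels:
        blocks[lum_label] = []
    for spl_label in splitter.labels:
        member = next(iter(splitter.members(spl_label)))
        lum_label = lumper.assignment.get(member)
        if lum_label is None:
            raise InputError(
                f"splitter PSH {spl_label!r} has no lumper assignment"
            )
        blocks[lum_label].append(spl_label)
    block_order = tuple(
        (lum, tuple(spls)) for lum, spls in blocks.items() if spls
    )
    ordered = [spl for _, spls in block_order for spl in spls]

    vectors = []
    for label in ordered:
        iv = indicator_vector(aln[reps[label]], specimen_id=reps[label])
        if iv.empty:
            raise InputError(f"representative of {label!r} has empty sequence")
        vectors.append(iv.vector)
    V = np.vstack(vectors)
    corr = np.clip(V @ V.T, 0.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return KleeMatrix(
        psh_labels=tuple(ordered),
        representatives={lab: reps[lab] for lab in ordered},
        values=corr,
        block_order=block_order,
    )


def merge_candidates(
    km: KleeMatrix, threshold: float = MERGE_THRESHOLD
) -> dict[str, list[list[str]]]:
    """Connected components of the >=threshold correlation graph per block.

    Only splitter PSHs in the same lumper block may join a component
    (conflicts are evaluated inside each lumper PSH, never globally).
    Returns lumper label -> list of components (each a list of splitter
    labels); components of size > 1 are merge proposals.
    """
    index = {lab: i for i, lab in enumerate(km.psh_labels)}
    out: dict[str, list[list[str]]] = {}
    for lumper_label, members in km.block_order:
        labels = list(members)
        parent = {lab: lab for lab in labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if km.values[index[a], index[b]] >= threshold:
                    parent[find(a)] = find(b)
        comps: dict[str, list[str]] = {}
        for lab in labels:
            comps.setdefault(find(lab), []).append(lab)
        out[lumper_label] = [comps[root] for root in sorted(
            comps, key=lambda r: labels.index(comps[r][0])
        )]
    return out


def render_klee(
    km: KleeMatrix, path: str | Path, csv_path: str | Path | None = None
) -> None:
    """Render the Klee heatmap (white -> red over [0, 1]) with block lines.

    Also writes the numeric matrix as CSV (default: same stem, .csv).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if csv_path is None:
        csv_path = path.with_suffix(".csv")

    fig, ax = plt.subplots(
        figsize=(max(4.0, km.n / 12.0), max(4.0, km.n / 12.0))
    )
    ax.imshow(km.values, cmap="Reds", vmin=0.0, vmax=1.0, interpolation="nearest")
    edge = 0
    for size in km.block_sizes()[:-1]:
        edge += size
        ax.axhline(edge - 0.5, color="black", linewidth=0.5)
        ax.axvline(edge - 0.5, color="black", linewidth=0.5)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"Klee diagram ({km.n} PSHs)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    import pandas as pd

    pd.DataFrame(
        km.values, index=km.psh_labels, columns=km.psh_labels
    ).to_csv(csv_path)
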