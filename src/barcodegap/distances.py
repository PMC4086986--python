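"""Pairwise genetic distances under simple substitution models.

Models
------
``p``    uncorrected proportion of mismatching comparable sites
``jc69`` Jukes-Cantor 1969:  d = -(3/4) ln(1 - (4/3) p)
``k2p``  Kimura 2-parameter: d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q))
         with P, Q the transition and transversion proportions

Comparison uses pairwise deletion: a column is comparable for a pair only
when both sequences carry an unambiguous A/C/G/T there; gaps, N and IUPAC
ambiguity codes are excluded for that pair. Pairs whose log argument is
non-positive are saturated: they are flagged and set to a sentinel value
just above the largest finite distance so that rank-based gap scanning
stays well defined. Pairs with zero comparable sites are flagged missing
(NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import AlignedSeqSet

__all__ = ["DistMatrix", "pairwise_distances", "encode_alignment"]

MODELS = ("p", "jc69", "k2p")

# Nucleotide codes: A=0, C=1, G=2, T=3; transitions are 0<->2 and 1<->3
# (partner = code XOR 2). Anything else is missing (255).
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


def encode_alignment(aln: AlignedSeqSet) -> np.ndarray:
    """Encode an alignment as an (n, L) uint8 matrix (255 = missing)."""
    raw = np.frombuffer(
        "".join(aln.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    return _CODE_TABLE[raw]


@dataclass
class DistMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str
    comparable_sites: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {sid: i for i, sid in enumerate(self.ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def submatrix(self, ids: Sequence[str]) -> "DistMatrix":
        idx = self.index_of(ids)
        return DistMatrix(
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
            saturated=self.saturated[np.ix_(idx, idx)],
        )

    def condensed(self, include_missing: bool = False) -> np.ndarray:
        """Upper-triangle pairwise distances (i < j), NaN dropped by default."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        if not include_missing:
            vals = vals[~np.isnan(vals)]
        return vals

    def to_csv(self, path: str | Path) -> None:
        """Export the lower triangle as (id_i, id_j, distance, sites)."""
        rows = []
        for i in range(1, self.n):
            for j in range(i):
                rows.append(
                    (
                        self.ids[i],
                        self.ids[j],
                        self.values[i, j],
                        int(self.comparable_sites[i, j]),
                    )
                )
        pd.DataFrame(
            rows, columns=["id_i", "id_j", "distance", "sites"]
        ).to_csv(path, index=False)


def _apply_model(
    model: str, mismatch: np.ndarray, transitions: np.ndarray, sites: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (distances, saturated mask); NaN where sites == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mismatch / sites
        if model == "p":
            return p, np.zeros_like(p, dtype=bool)
        if model == "jc69":
            arg = 1.0 - (4.0 / 3.0) * p
            saturated = (arg <= 0) & (sites > 0)
            d = np.where(arg > 0, -(3.0 / 4.0) * np.log(np.abs(arg) + 1e-300), np.inf)
            d[np.isnan(p)] = np.nan
            return d, saturated
        if model == "k2p":
            P = transitions / sites
            Q = (mismatch - transitions) / sites
            arg1 = 1.0 - 2.0 * P - Q
            arg2 = 1.0 - 2.0 * Q
            ok = (arg1 > 0) & (arg2 > 0)
            saturated = ~ok & (sites > 0)
            d = np.where(
                ok,
                -0.5 * np.log(np.abs(arg1) + 1e-300)
                - 0.25 * np.log(np.abs(arg2) + 1e-300),
                np.inf,
            )
            d[np.isnan(p)] = np.nan
            return d, saturated
    raise InputError(f"unknown distance model {model!r}")


def pairwise_distances(aln: AlignedSeqSet, model: str = "k2p") -> DistMatrix:
    """Compute the pairwise distance matrix for an alignment.

    K2P is the default: it is the conventional model for COI barcode gap
    analysis. Requires at least two sequences.
    """
    if model not in MODELS:
        raise InputError(f"unknown distance model {model!r}")
    if len(aln) < 2:
        raise InputError("need at least 2 sequences for pairwise distances")

    codes = encode_alignment(aln)
    valid = (codes != 255).astype(np.float64)
    onehot = [(codes == b).astype(np.float64) for b in range(4)]

    sites = valid @ valid.T
    matches = sum(oh @ oh.T for oh in onehot)
    # transitions: A<->G (0,2) and C<->T (1,3)
    transitions = (
        onehot[0] @ onehot[2].T
        + onehot[2] @ onehot[0].T
        + onehot[1] @ onehot[3].T
        + onehot[3] @ onehot[1].T
    )
    mismatch = sites - matches

    values, saturated = _apply_model(model, mismatch, transitions, sites)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(saturated, False)

    finite = np.isfinite(values)
    if saturated.any():
        ceiling = values[finite].max() if finite.any() else 1.0
        values[saturated] = ceiling * 1.01

    # exact symmetry (matmul round-off is sub-1e-12 but normalise anyway)
    values = np.where(
        np.isnan(values), values, (values + values.T) / 2.0
    )
    return DistMatrix(
        ids=aln.ids,
        values=values,
        model=model,
        comparable_sites=sites.astype(np.int64),
        saturated=saturated | saturated.T,
    )
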