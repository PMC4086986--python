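"""Partition congruence, lumper/splitter conflict resolution and consensus.

The congruence engine compares the cluster sets produced by independent
delimitation methods, resolves each lumper/splitter conflict with the Klee
merge rule plus tree-based corroboration, and assembles a consensus
partition of primary species hypotheses (PSHs). From the consensus it
derives cryptic-species counts (morphospecies split across several PSHs)
and sympatry annotations (split PSH pairs sharing at least one collection
area).

Corroboration rule: a split between two Klee components is retained only
when at least one tree-based partition (typically GMYC single-threshold or
PTP) also separates those specimens; otherwise the components merge back
into the lumper PSH. GMYC multiple-threshold output is deliberately not
used for corroboration (multi-threshold methods systematically
over-split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import InputError
from .io_formats import Partition, SpecimenTable
from .klee import KleeMatrix, merge_candidates

__all__ = [
    "ConflictCase",
    "CongruenceReport",
    "CrypticResult",
    "shared_clusters",
    "conflict_cases",
    "resolve_consensus",
    "cryptic_species",
    "sympatry_status",
    "partition_similarity",
]


def shared_clusters(
    partitions: Mapping[str, Partition]
) -> tuple[int, list[frozenset[str]]]:
    """Clusters present identically in every partition.

    All partitions must cover the same specimen set.
    """
    if not partitions:
        raise InputError("no partitions given")
    parts = list(partitions.values())
    universe = set(parts[0].specimen_ids)
    for name, part in partitions.items():
        if set(part.specimen_ids) != universe:
            raise InputError(
                f"partition {name!r} covers a different specimen set"
            )
    common = set(parts[0].cluster_sets())
    for part in parts[1:]:
        common &= part.cluster_sets()
    # deterministic order: by first appearance in the first partition
    ordered = [c for c in parts[0].clusters if c in common]
    return len(ordered), ordered


@dataclass
class ConflictCase:
    """One lumper PSH split into several splitter PSHs, and its resolution."""

    lumper_label: str
    splitter_labels: tuple[str, ...]
    klee_components: tuple[tuple[str, ...], ...] = ()
    corroboration: dict[str, bool] = field(default_factory=dict)
    resolution: str | None = None  # keep_lumper | accept_split | partial_split
    final_clusters: tuple[frozenset[str], ...] = ()


def conflict_cases(
    lumper: Partition, splitter: Partition
) -> tuple[list[ConflictCase], list[str]]:
    """One case per lumper cluster containing more than one splitter cluster.

    Returns (cases, exceptions): splitter clusters spanning several lumper
    clusters violate refinement and are reported, not silently fixed.
    """
    exceptions: list[str] = []
    for spl_label in splitter.labels:
        lum_hits = {
            lumper.assignment.get(s) for s in splitter.members(spl_label)
        }
        if len(lum_hits) > 1:
            exceptions.append(
                f"splitter PSH {spl_label!r} spans lumper PSHs {sorted(map(str, lum_hits))}"
            )
    cases: list[ConflictCase] = []
    for lum_label in lumper.labels:
        members = lumper.members(lum_label)
        spl_labels: list[str] = []
        for spl_label in splitter.labels:
            if splitter.members(spl_label) & members:
                spl_labels.append(spl_label)
        if len(spl_labels) > 1:
            cases.append(
                ConflictCase(
                    lumper_label=lum_label,
                    splitter_labels=tuple(spl_labels),
                )
            )
    return cases, exceptions


@dataclass
class CongruenceReport:
    """Audit of conflict resolution plus the consensus partition."""

    cases: list[ConflictCase]
    consensus: Partition
    klee_only: bool = False
    exceptions: list[str] = field(default_factory=list)

    @property
    def n_consensus(self) -> int:
        return self.consensus.n_clusters

    def case_table(self) -> pd.DataFrame:
        rows = []
        for case in self.cases:
            rows.append(
                {
                    "lumper_psh": case.lumper_label,
                    "n_splitter_pshs": len(case.splitter_labels),
                    "n_klee_components": len(case.klee_components),
                    "n_final_clusters": len(case.final_clusters),
                    "resolution": case.resolution,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "lumper_psh",
                "n_splitter_pshs",
                "n_klee_components",
                "n_final_clusters",
                "resolution",
            ],
        )


def _separates(
    partition: Partition, group_a: frozenset[str], group_b: frozenset[str]
) -> bool:
    """True when no cluster of `partition` mixes specimens of both groups."""
    labels_a = {partition.assignment.get(s) for s in group_a}
    labels_b = {partition.assignment.get(s) for s in group_b}
    labels_a.discard(None)
    labels_b.discard(None)
    if not labels_a or not labels_b:
        return False
    return labels_a.isdisjoint(labels_b)


def resolve_consensus(
    cases: Sequence[ConflictCase],
    km: KleeMatrix,
    tree_partitions: Mapping[str, Partition],
    lumper: Partition,
    splitter: Partition,
    threshold: float = 0.90,
) -> CongruenceReport:
    """Resolve each conflict case and assemble the consensus partition.

    Per case: Klee components at `threshold`; a single component keeps the
    lumper PSH; with several components, each pair of components stays
    split only if at least one tree-based partition separates it, else the
    pair merges back (transitively). When no tree partitions are supplied
    the Klee components are accepted as-is and the report is flagged
    ``klee_only``.
    """
    km_labels = set(km.psh_labels)
    for case in cases:
        missing = [l for l in case.splitter_labels if l not in km_labels]
        if missing:
            raise InputError(
                f"case {case.lumper_label!r}: splitter PSHs missing from "
                f"Klee matrix: {missing}"
            )
    components_by_block = merge_candidates(km, threshold)
    klee_only = not tree_partitions

    conflicted_lumper = {case.lumper_label for case in cases}
    consensus_clusters: list[frozenset[str]] = []
    for lum_label in lumper.labels:
        if lum_label not in conflicted_lumper:
            consensus_clusters.append(lumper.members(lum_label))

    for case in cases:
        comps = [
            tuple(c)
            for c in components_by_block.get(case.lumper_label, [])
            if set(c) & set(case.splitter_labels)
        ]
        case.klee_components = tuple(comps)
        comp_members = [
            frozenset().union(*(splitter.members(l) for l in comp))
            for comp in comps
        ]
        if len(comps) == 1:
            case.resolution = "keep_lumper"
            final = [comp_members[0]]
        elif klee_only:
            case.resolution = (
                "accept_split"
                if len(comps) == len(case.splitter_labels)
                else "partial_split"
            )
            final = comp_members
        else:
            # union-merge component pairs that no tree method separates
            parent = list(range(len(comps)))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(comps)):
                for j in range(i + 1, len(comps)):
                    separated = any(
                        _separates(part, comp_members[i], comp_members[j])
                        for part in tree_partitions.values()
                    )
                    if not separated:
                        parent[find(i)] = find(j)
            groups: dict[int, list[int]] = {}
            for i in range(len(comps)):
                groups.setdefault(find(i), []).append(i)
            final = [
                frozenset().union(*(comp_members[i] for i in idxs))
                for idxs in groups.values()
            ]
            case.corroboration = {
                name: any(
                    _separates(part, a, b)
                    for k, a in enumerate(comp_members)
                    for b in comp_members[k + 1:]
                )
                for name, part in tree_partitions.items()
            }
            if len(final) == 1:
                case.resolution = "partial_split"  # Klee split, uncorroborated
            elif len(final) == len(case.splitter_labels):
                case.resolution = "accept_split"
            else:
                case.resolution = "partial_split"
        case.final_clusters = tuple(final)
        consensus_clusters.extend(final)

    # deterministic labels by first member in the lumper's specimen order
    order = {sid: i for i, sid in enumerate(lumper.specimen_ids)}
    consensus_clusters.sort(key=lambda c: min(order[s] for s in c))
    consensus = Partition.from_clusters(consensus_clusters, prefix="PSH")
    return CongruenceReport(
        cases=list(cases), consensus=consensus, klee_only=klee_only
    )


@dataclass
class CrypticResult:
    """Cryptic-species accounting from consensus vs morphospecies."""

    count: int
    per_morphospecies: pd.DataFrame  # morphospecies, n_pshs, psh_labels
    merged_morphospecies: pd.DataFrame  # PSHs joining >1 morphospecies
    n_consensus: int
    n_morphospecies: int

    @property
    def difference(self) -> int:
        """n_consensus - n_morphospecies; equals count when nothing merges."""
        return self.n_consensus - self.n_morphospecies


def cryptic_species(
    consensus: Partition, table: SpecimenTable
) -> CrypticResult:
    """Count cryptic candidates: sum of (k - 1) over morphospecies split
    into k >= 2 consensus PSHs. Also reports any PSH joining several
    morphospecies (expected none for a clean dataset)."""
    morpho = table.morphospecies()
    unlabeled = [
        s for s in consensus.specimen_ids
        if s not in morpho.index or pd.isna(morpho.get(s))
    ]
    if unlabeled:
        raise InputError(
            f"specimens without morphospecies label: {unlabeled[:10]}"
        )
    by_morpho: dict[str, set[str]] = {}
    for sid in consensus.specimen_ids:
        by_morpho.setdefault(str(morpho[sid]), set()).add(
            consensus.assignment[sid]
        )
    rows = [
        {
            "morphospecies": m,
            "n_pshs": len(pshs),
            "psh_labels": ";".join(sorted(pshs)),
        }
        for m, pshs in sorted(by_morpho.items())
    ]
    per_morpho = pd.DataFrame(
        rows, columns=["morphospecies", "n_pshs", "psh_labels"]
    )
    count = int((per_morpho["n_pshs"] - 1).clip(lower=0).sum())

    merged_rows = []
    for label in consensus.labels:
        morphos = sorted(
            {str(morpho[s]) for s in consensus.members(label)}
        )
        if len(morphos) > 1:
            merged_rows.append(
                {"psh": label, "morphospecies": ";".join(morphos)}
            )
    merged = pd.DataFrame(merged_rows, columns=["psh", "morphospecies"])
    return CrypticResult(
        count=count,
        per_morphospecies=per_morpho,
        merged_morphospecies=merged,
        n_consensus=consensus.n_clusters,
        n_morphospecies=len(by_morpho),
    )


def _locality_set(table: SpecimenTable, specimens: frozenset[str]) -> set[str]:
    loc = table.localities()
    out = set()
    for sid in specimens:
        if sid in loc.index and not pd.isna(loc[sid]):
            out.add(str(loc[sid]).strip().casefold())
    return out


def sympatry_status(
    consensus: Partition, table: SpecimenTable
) -> pd.DataFrame:
    """Label each same-morphospecies PSH pair sympatric/allopatric/unknown.

    Two PSHs sharing a morphospecies are sympatric iff their locality sets
    intersect, allopatric iff both are non-empty and disjoint, unknown
    otherwise. Locality labels are matched exactly after case-folding and
    trimming.
    """
    morpho = table.morphospecies()
    by_morpho: dict[str, list[str]] = {}
    for sid in consensus.specimen_ids:
        if sid in morpho.index and not pd.isna(morpho[sid]):
            m = str(morpho[sid])
            lab = consensus.assignment[sid]
            by_morpho.setdefault(m, [])
            if lab not in by_morpho[m]:
                by_morpho[m].append(lab)
    rows = []
    for m, pshs in sorted(by_morpho.items()):
        if len(pshs) < 2:
            continue
        for i, a in enumerate(pshs):
            for b in pshs[i + 1:]:
                loc_a = _locality_set(table, consensus.members(a))
                loc_b = _locality_set(table, consensus.members(b))
                if loc_a & loc_b:
                    status = "sympatric"
                elif loc_a and loc_b:
                    status = "allopatric"
                else:
                    status = "unknown"
                rows.append(
                    {
                        "morphospecies": m,
                        "psh_a": a,
                        "psh_b": b,
                        "status": status,
                    }
                )
    return pd.DataFrame(
        rows, columns=["morphospecies", "psh_a", "psh_b", "status"]
    )


def partition_similarity(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same specimens."""
    if set(a.specimen_ids) != set(b.specimen_ids):
        raise InputError("partitions cover different specimen sets")
    ids = list(a.specimen_ids)
    la = [a.assignment[s] for s in ids]
    lb = [b.assignment[s] for s in ids]
    return float(adjusted_rand_score(la, lb))
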