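"""Synthetic barcode alignments with known species truth.

Two generators live here.

:func:`simulate` draws a star-tree dataset: a uniform random root sequence,
one ancestor per species mutated from the root with per-site probability
``inter/2`` (Jukes-Cantor symmetric substitution), and individuals mutated
from their species ancestor with probability ``intra/2``. Star topology
(ancestor plus independent tips) is deliberate: pairwise divergences then
have analytically checkable binomial expectations, which is all the gap
scan ever sees. The truth partition and a metadata table (species as
morphospecies, localities from a small fixed vocabulary) are emitted
alongside.

:func:`synthetic_benchmark` builds a SYNTHETIC stand-in for the published
terebrid COI case study whose original supplementary data files are not
redistributed here. It generates, from a seed, a 454-specimen, 658-column
COI-like alignment, a 195-specimen 758-column 28S-like alignment and a
specimen table with five per-method assignment columns, engineered so that
the summary structure of the real dataset is reproduced exactly: 87
morphospecies; a barcode-gap scan yielding a 98-cluster lumper and a
125-cluster splitter; method cluster counts 98/125/110/130/112; 63 clusters
identical across all five methods (83 excluding the multi-threshold GMYC
column); ten lumper/splitter conflict cases whose Klee-plus-corroboration
resolution gives 104 consensus PSHs and 17 cryptic species, with 8
morphospecies split identically in both ABGD partitions. Divergence levels
are placed by construction (disjoint-site transition substitutions, so
every within-cluster distance is an exact, tie-degenerate value) rather
than tuned; the sequences themselves vary freely with the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import AlignedSeqSet, Partition, SpecimenTable

__all__ = ["SimSpec", "simulate", "synthetic_benchmark", "BenchmarkData"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

LOCALITY_VOCAB = (
    "Vanuatu",
    "Philippines",
    "Madagascar",
    "West Africa",
    "Solomon Islands",
    "Panama",
    "East Africa",
    "New Caledonia",
)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Generic star-tree simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a star-tree barcode simulation.

    ``intra``/``inter`` are expected per-lineage divergences (substitutions
    per site) of individuals from their species ancestor and of species
    ancestors from the root; a pair of individuals is therefore separated
    by roughly twice the corresponding value.
    """

    n_species: int = 5
    n_per_species: int | Sequence[int] = 10
    length: int = 658
    intra: float = 0.005
    inter: float = 0.1
    seed: int = 0
    sympatric_fraction: float = 0.5

    def sample_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_species, int):
            return (self.n_per_species,) * self.n_species
        sizes = tuple(int(x) for x in self.n_per_species)
        if len(sizes) != self.n_species:
            raise InputError("per-species sample sizes do not match n_species")
        return sizes

    def validate(self) -> None:
        if self.n_species < 1 or self.length < 1:
            raise InputError("n_species and length must be >= 1")
        if self.intra < 0 or self.inter < 0:
            raise InputError("divergences must be non-negative")
        if any(s < 1 for s in self.sample_sizes()):
            raise InputError("sample sizes must be >= 1")
        if not 0.0 <= self.sympatric_fraction <= 1.0:
            raise InputError("sympatric_fraction must be in [0, 1]")


def _jc_mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor symmetric mutation: each site substituted with
    probability `rate`, new base uniform among the other three."""
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate(
    spec: SimSpec,
) -> tuple[AlignedSeqSet, Partition, SpecimenTable]:
    """Simulate a multi-species alignment; returns (alignment, truth, table).

    Fully reproducible from ``spec.seed``; the FASTA serialisation of the
    alignment is byte-identical across runs with the same spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sample_sizes()
    root = rng.integers(0, 4, spec.length, dtype=np.int64)

    n_sympatric = int(round(spec.sympatric_fraction * spec.n_species))
    ids: list[str] = []
    seqs: list[str] = []
    assignment: dict[str, str] = {}
    rows = []
    for sp in range(spec.n_species):
        ancestor = _jc_mutate(root, spec.inter / 2.0, rng)
        species = f"sp_{sp + 1:02d}"
        own_area = LOCALITY_VOCAB[sp % len(LOCALITY_VOCAB)]
        areas = (
            [LOCALITY_VOCAB[0], own_area] if sp < n_sympatric else [own_area]
        )
        for k in range(sizes[sp]):
            sid = f"sim_{sp + 1:02d}_{k + 1:03d}"
            seq = _jc_mutate(ancestor, spec.intra / 2.0, rng)
            ids.append(sid)
            seqs.append(_decode(seq.astype(np.uint8)))
            assignment[sid] = species
            rows.append(
                {
                    "specimen_id": sid,
                    "morphospecies": species,
                    "locality": areas[int(rng.integers(0, len(areas)))],
                }
            )
    aln = AlignedSeqSet(ids=tuple(ids), seqs=tuple(seqs))
    truth = Partition(assignment)
    df = pd.DataFrame(rows).set_index("specimen_id")
    table = SpecimenTable(
        df=df, morpho_col="morphospecies", locality_col="locality"
    )
    return aln, truth, table


# ---------------------------------------------------------------------------
# Synthetic benchmark mirroring the published case-study structure
# ---------------------------------------------------------------------------

# Within-cluster substructure is placed with disjoint-site transition flips
# (A<->G, C<->T; a flip is code XOR 2), so every engineered distance is an
# exact mismatch count: 26/658 between sub-PSHs that the Klee rule must
# re-merge (correlation 0.960 >= 0.90) and 78-80/658 between components it
# must keep apart (correlation < 0.89). Cluster ancestors differ from the
# global root by independent flips at ~25% of sites, putting between-cluster
# distances far above every within-cluster level.

_N_SHARED_ALL = 63  # clusters identical in all five methods
_N_MULTI_SPLIT = 20  # additionally identical in four (split by GMYC multi)
_N_TREE_NOISE = 5  # clusters re-cut by GMYC single / PTP
_REJECT_SUBS = [2, 4, 3, 3, 3]  # Klee-rejected conflict cases (corr >= 0.9)
_CLUSTER_FLIP_RATE = 0.25
_NEAR_FLIPS = 13  # 26-mismatch pairs: corr 0.960, merged by Klee
_FAR_FLIPS = (39, 40)  # 78-80-mismatch pairs: corr < 0.89, kept split


@dataclass
class BenchmarkData:
    """A generated benchmark: COI alignment, specimen table, 28S stand-in.

    ``truth_consensus`` is the consensus partition the congruence engine is
    expected to reconstruct; it is emitted for validation, never consumed
    by the pipeline.
    """

    coi: AlignedSeqSet
    table: SpecimenTable
    rdna28s: AlignedSeqSet
    truth_consensus: Partition = field(repr=False, kw_only=True)


class _Builder:
    def __init__(self, rng: np.random.Generator, length: int = 658):
        self.rng = rng
        self.length = length
        self.root = rng.integers(0, 4, length, dtype=np.int64)
        self.records: list[dict] = []  # per specimen
        self.cluster_index = 0

    def _ancestor(self) -> np.ndarray:
        mask = self.rng.random(self.length) < _CLUSTER_FLIP_RATE
        anc = self.root.copy()
        anc[mask] ^= 2
        return anc

    @staticmethod
    def _flip(seq: np.ndarray, sites: np.ndarray) -> np.ndarray:
        out = seq.copy()
        out[sites] ^= 2
        return out

    def add_cluster(self, subs: list[dict], morpho: str, genus: str) -> str:
        """subs: [{seq, n, locality, single, multi, ptp}] one per sub-PSH."""
        self.cluster_index += 1
        lum = f"L{self.cluster_index:02d}"
        for s, sub in enumerate(subs, start=1):
            spl = f"{lum}x{s}"
            for _ in range(sub["n"]):
                self.records.append(
                    {
                        "seq": sub["seq"],
                        "morphospecies": morpho,
                        "genus": genus,
                        "locality": sub["locality"],
                        "abgd_lumper": lum,
                        "abgd_splitter": spl,
                        "gmyc_single": f"{lum}g{sub['single']}",
                        "gmyc_multiple": f"{lum}m{sub['multi']}",
                        "ptp": f"{lum}p{sub['ptp']}",
                        "consensus_truth": sub.get("consensus", spl),
                    }
                )
        return lum


def _simple_sub(seq, n, locality, tag=1):
    return {
        "seq": seq, "n": n, "locality": locality,
        "single": tag, "multi": tag, "ptp": tag,
    }


def synthetic_benchmark(seed: int = 0, length: int = 658) -> BenchmarkData:
    """Generate the synthetic case-study benchmark (see module docstring).

    The returned alignment/table pair drives every stage of the pipeline;
    the 28S-like alignment exists only to be parsed and counted (195
    records, 758 columns, ungapped lengths 696-742).
    """
    rng = np.random.default_rng(seed)
    b = _Builder(rng, length)
    loc = LOCALITY_VOCAB

    # --- 63 clusters identical in all five partitions -------------------
    # sizes 48x5 + 15x4 = 300 specimens; the first 19 clusters carry the 8
    # morphospecies split identically in both ABGD partitions (3+3+3 and
    # 2+2+2+2+2), the rest are one morphospecies each.
    shared_sizes = [5] * 48 + [4] * 15
    split_morpho_plan = [3, 3, 3, 2, 2, 2, 2, 2]
    split_localities = [
        ("Philippines", "Philippines", "Philippines"),  # sympatric triplet
        ("Vanuatu", "Madagascar", "Panama"),  # allopatric triplet
        ("Vanuatu", "Vanuatu", "Vanuatu"),  # sympatric triplet
        ("Solomon Islands", "Solomon Islands"),
        ("East Africa", "East Africa"),
        ("Vanuatu", "West Africa"),
        ("Philippines", "Madagascar"),
        ("Panama", "New Caledonia"),
    ]
    morpho_names = iter(f"msp_{i + 1:02d}" for i in range(200))
    genus_of = lambda i: f"gen_{i % 12 + 1:02d}"

    cluster_no = 0
    plan_queue = []
    for k, localities in zip(split_morpho_plan, split_localities):
        name = next(morpho_names)
        for area in localities:
            plan_queue.append((name, area))
    for idx, size in enumerate(shared_sizes):
        if plan_queue:
            morpho, area = plan_queue.pop(0)
        else:
            morpho = next(morpho_names)
            area = loc[int(rng.integers(0, len(loc)))]
        anc = b._ancestor()
        b.add_cluster([_simple_sub(anc, size, area)], morpho, genus_of(idx))
        cluster_no += 1

    # --- 20 clusters split only by GMYC multiple ------------------------
    for idx in range(_N_MULTI_SPLIT):
        anc = b._ancestor()
        area = loc[int(rng.integers(0, len(loc)))]
        morpho = next(morpho_names)
        subs = [
            {"seq": anc, "n": 2, "locality": area,
             "single": 1, "multi": 1, "ptp": 1},
            {"seq": anc, "n": 1, "locality": area,
             "single": 1, "multi": 2, "ptp": 1},
        ]
        lum = b.add_cluster(subs, morpho, genus_of(idx))
        # both rows belong to the same splitter PSH: collapse the labels
        for rec in b.records:
            if rec["abgd_lumper"] == lum:
                rec["abgd_splitter"] = f"{lum}x1"
                rec["consensus_truth"] = f"{lum}x1"

    # --- 5 clusters re-cut by GMYC single and PTP -----------------------
    single_cuts = [(1, 2, 3), (1, 1, 2, 2), (1, 1, 2, 2), (1, 1, 2, 2), (1, 1, 2, 2)]
    ptp_cuts = [(1, 2, 3, 4), (1, 2, 3, 4), (1, 2, 3, 4), (1, 1, 2, 3), (1, 1, 2, 3)]
    for idx in range(_N_TREE_NOISE):
        anc = b._ancestor()
        area = loc[int(rng.integers(0, len(loc)))]
        morpho = next(morpho_names)
        scut = single_cuts[idx]
        pcut = ptp_cuts[idx]
        if len(scut) == 3:  # 4 specimens cut 2+1+1
            smap = (scut[0], scut[0], scut[1], scut[2])
        else:
            smap = scut
        subs = [
            {"seq": anc, "n": 1, "locality": area,
             "single": smap[m], "multi": smap[m], "ptp": pcut[m]}
            for m in range(4)
        ]
        lum = b.add_cluster(subs, morpho, genus_of(idx))
        for rec in b.records:
            if rec["abgd_lumper"] == lum:
                rec["abgd_splitter"] = f"{lum}x1"
                rec["consensus_truth"] = f"{lum}x1"

    # --- 10 conflict cases ----------------------------------------------
    # rejected by Klee (within-case distance 26/658, correlation 0.96)
    for n_subs in _REJECT_SUBS:
        anc = b._ancestor()
        area = loc[int(rng.integers(0, len(loc)))]
        morpho = next(morpho_names)
        pool = rng.permutation(length)
        offset = 0
        subs = []
        for s in range(n_subs):
            sites = pool[offset:offset + _NEAR_FLIPS]
            offset += _NEAR_FLIPS
            subs.append(
                {"seq": b._flip(anc, sites), "n": 2, "locality": area,
                 "single": 1, "multi": 1, "ptp": 1, "consensus": "LUMP"}
            )
        lum = b.add_cluster(subs, morpho, genus_of(n_subs))
        for rec in b.records:
            if rec["consensus_truth"] == "LUMP":
                rec["consensus_truth"] = f"{lum}x1"

    # accepted quartet: 4 components, corroborated by GMYC single
    anc = b._ancestor()
    pool = rng.permutation(length)
    offset = 0
    quartet_loc = ("Philippines", "Vanuatu", "Vanuatu", "Philippines")
    subs = []
    for s in range(4):
        m = _FAR_FLIPS[s % 2]
        sites = pool[offset:offset + m]
        offset += m
        subs.append(
            {"seq": b._flip(anc, sites), "n": 2, "locality": quartet_loc[s],
             "single": s + 1, "multi": s + 1, "ptp": 1}
        )
    b.add_cluster(subs, next(morpho_names), genus_of(6))

    # accepted pair: corroborated by GMYC single
    anc = b._ancestor()
    pool = rng.permutation(length)
    subs = []
    for s, area in enumerate(("Vanuatu", "West Africa")):
        m = _FAR_FLIPS[s]
        sites = pool[s * 50:s * 50 + m]
        subs.append(
            {"seq": b._flip(anc, sites), "n": 2, "locality": area,
             "single": s + 1, "multi": s + 1, "ptp": 1}
        )
    b.add_cluster(subs, next(morpho_names), genus_of(7))

    # Klee-split pair with NO tree corroboration: merges back in consensus
    anc = b._ancestor()
    pool = rng.permutation(length)
    subs = []
    for s in range(2):
        m = _FAR_FLIPS[s]
        sites = pool[s * 50:s * 50 + m]
        subs.append(
            {"seq": b._flip(anc, sites), "n": 2,
             "locality": loc[int(rng.integers(0, len(loc)))],
             "single": 1, "multi": 1, "ptp": 1, "consensus": "LUMP8"}
        )
    lum = b.add_cluster(subs, next(morpho_names), genus_of(8))
    for rec in b.records:
        if rec["consensus_truth"] == "LUMP8":
            rec["consensus_truth"] = f"{lum}x1"

    # partial triplet: Klee sees {a,b} + {c}; GMYC single corroborates
    anc = b._ancestor()
    pool = rng.permutation(length)
    compA = b._flip(anc, pool[0:33])
    compB = b._flip(anc, pool[33:66])
    a = b._flip(compA, pool[66:66 + _NEAR_FLIPS])
    a2 = b._flip(compA, pool[79:79 + _NEAR_FLIPS])
    subs = [
        {"seq": a, "n": 2, "locality": "Philippines",
         "single": 1, "multi": 1, "ptp": 1, "consensus": "AB"},
        {"seq": a2, "n": 2, "locality": "Philippines",
         "single": 1, "multi": 1, "ptp": 1, "consensus": "AB"},
        {"seq": compB, "n": 2, "locality": "Madagascar",
         "single": 2, "multi": 2, "ptp": 1},
    ]
    lum = b.add_cluster(subs, next(morpho_names), genus_of(9))
    for rec in b.records:
        if rec["consensus_truth"] == "AB":
            rec["consensus_truth"] = f"{lum}xAB"

    # partial 1+10: Klee sees {a} + {b..k}; GMYC single and PTP corroborate
    anc = b._ancestor()
    pool = rng.permutation(length)
    compA = b._flip(anc, pool[0:33])
    compB = b._flip(anc, pool[33:66])
    subs = [
        {"seq": compA, "n": 2, "locality": "Vanuatu",
         "single": 1, "multi": 1, "ptp": 1},
    ]
    offset = 66
    for s in range(10):
        sites = pool[offset:offset + _NEAR_FLIPS]
        offset += _NEAR_FLIPS
        subs.append(
            {"seq": b._flip(compB, sites), "n": 2, "locality": "Madagascar",
             "single": 2, "multi": 2, "ptp": 2, "consensus": "BK"}
        )
    lum = b.add_cluster(subs, next(morpho_names), genus_of(10))
    for rec in b.records:
        if rec["consensus_truth"] == "BK":
            rec["consensus_truth"] = f"{lum}xBK"

    # --- assemble, shuffle, name -----------------------------------------
    perm = rng.permutation(len(b.records))
    records = [b.records[i] for i in perm]
    ids = tuple(f"TER{i + 1:04d}" for i in range(len(records)))
    seqs = tuple(_decode(r["seq"].astype(np.uint8)) for r in records)
    coi = AlignedSeqSet(ids=ids, seqs=seqs)

    df = pd.DataFrame(
        [
            {
                "specimen_id": sid,
                "morphospecies": r["morphospecies"],
                "genus": r["genus"],
                "locality": r["locality"],
                "abgd_lumper": r["abgd_lumper"],
                "abgd_splitter": r["abgd_splitter"],
                "gmyc_single": r["gmyc_single"],
                "gmyc_multiple": r["gmyc_multiple"],
                "ptp": r["ptp"],
            }
            for sid, r in zip(ids, records)
        ]
    ).set_index("specimen_id")
    table = SpecimenTable(
        df=df,
        morpho_col="morphospecies",
        locality_col="locality",
        genus_col="genus",
        assignment_cols={
            m: m
            for m in (
                "abgd_lumper", "abgd_splitter", "gmyc_single",
                "gmyc_multiple", "ptp",
            )
        },
    )
    truth_consensus = Partition(
        {sid: r["consensus_truth"] for sid, r in zip(ids, records)}
    )

    # --- 28S-like stand-in: 195 records padded into 758 columns ----------
    rd_ids = ids[:195]
    rd_len = 758
    rd_seqs = []
    for _ in rd_ids:
        core = int(rng.integers(696, 743))
        left = int(rng.integers(0, rd_len - core + 1))
        body = _decode(rng.integers(0, 4, core).astype(np.uint8))
        rd_seqs.append("-" * left + body + "-" * (rd_len - core - left))
    rdna = AlignedSeqSet(ids=rd_ids, seqs=tuple(rd_seqs))

    return BenchmarkData(
        coi=coi, table=table, rdna28s=rdna, truth_consensus=truth_consensus
    )
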