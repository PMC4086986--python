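"""End-to-end workflow: distances -> gap scan -> Klee -> consensus -> report.

:func:`analyze` runs the whole delimitation chain on in-memory objects and
returns every intermediate product plus a flat JSON-able summary.
:func:`run_workflow` is the file-level wrapper: it reads the inputs named
in a :class:`RunConfig`, calls :func:`analyze`, and writes partitions, the
Klee diagram (PNG + CSV), merge proposals, per-stage tables and a
versioned ``summary.json`` into the output directory, logging every
parameter to console and ``run.log`` (the workflow is parameter-sensitive;
provenance is part of the product).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import gap_discovery as gd
from .congruence import (
    CongruenceReport,
    conflict_cases,
    cryptic_species,
    resolve_consensus,
    shared_clusters,
    sympatry_status,
)
from .distances import DistMatrix, pairwise_distances
from .errors import InputError
from .io_formats import (
    AlignedSeqSet,
    Partition,
    SpecimenTable,
    partitions_from_table,
    read_alignment,
    read_specimen_table,
    write_partition,
)
from .klee import KleeMatrix, klee_matrix, merge_candidates, render_klee

__all__ = ["RunConfig", "WorkflowResult", "analyze", "run_workflow"]

SCHEMA_VERSION = 1
log = logging.getLogger("barcodegap")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (YAML-mappable)."""

    alignment: str
    outdir: str
    table: str | None = None
    id_col: str = "specimen_id"
    morpho_col: str | None = "morphospecies"
    locality_col: str | None = "locality"
    assignment_cols: dict[str, str] = field(default_factory=dict)
    tree_methods: tuple[str, ...] = ("gmyc_single", "ptp")
    model: str = "k2p"
    pmin: float = gd.DEFAULT_PMIN
    pmax: float = gd.DEFAULT_PMAX
    steps: int = gd.DEFAULT_STEPS
    rel_width: float = gd.DEFAULT_REL_WIDTH
    min_group: int = gd.DEFAULT_MIN_GROUP
    klee_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.klee_threshold <= 1.0:
            raise InputError("klee_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tree_methods" in data:
            data["tree_methods"] = tuple(data["tree_methods"])
        return cls(**data)


@dataclass
class WorkflowResult:
    """Every product of one pipeline run."""

    dist: DistMatrix
    scan: gd.GapScanResult
    lumper: Partition
    splitter: Partition
    km: KleeMatrix
    merges: dict[str, list[list[str]]]
    report: CongruenceReport
    cryptic: object | None
    sympatry: pd.DataFrame | None
    summary: dict


def _split_in_both_count(
    table: SpecimenTable, lumper: Partition, splitter: Partition
) -> int | None:
    """Morphospecies split into >= 2 PSHs in BOTH ABGD partitions."""
    if table is None or table.morpho_col is None:
        return None
    morpho = table.morphospecies()
    count = 0
    by_m: dict[str, list[str]] = {}
    for sid in lumper.specimen_ids:
        if sid in morpho.index and not pd.isna(morpho[sid]):
            by_m.setdefault(str(morpho[sid]), []).append(sid)
    for _m, sids in by_m.items():
        n_lum = len({lumper.assignment[s] for s in sids})
        n_spl = len({splitter.assignment.get(s) for s in sids} - {None})
        if n_lum >= 2 and n_spl >= 2:
            count += 1
    return count


def analyze(
    aln: AlignedSeqSet,
    table: SpecimenTable | None = None,
    *,
    model: str = "k2p",
    pmin: float = gd.DEFAULT_PMIN,
    pmax: float = gd.DEFAULT_PMAX,
    steps: int = gd.DEFAULT_STEPS,
    rel_width: float = gd.DEFAULT_REL_WIDTH,
    min_group: int = gd.DEFAULT_MIN_GROUP,
    klee_threshold: float = 0.90,
    tree_methods: tuple[str, ...] = ("gmyc_single", "ptp"),
) -> WorkflowResult:
    """Run the full delimitation chain on in-memory inputs.

    With no table (or no tree-method assignment columns) the consensus
    falls back to Klee-only resolution, flagged in the summary.
    """
    log.info(
        "analyze: n=%d, L=%d, model=%s, priors=geometric(%g, %g, %d), "
        "X=%g, min_group=%d, klee_threshold=%.2f",
        len(aln), aln.length, model, pmin, pmax, steps, rel_width,
        min_group, klee_threshold,
    )
    if table is not None:
        missing = [s for s in aln.ids if s not in set(table.specimen_ids)]
        if missing:
            raise InputError(
                f"alignment specimens absent from table: {missing[:5]}"
            )

    dist = pairwise_distances(aln, model=model)
    priors = gd.prior_series(pmin, pmax, steps)
    scan = gd.abgd_scan(
        dist, priors, rel_width=rel_width, min_group=min_group
    )
    lumper, splitter = gd.lumper_splitter(scan)
    log.info(
        "scan: lumper %d clusters, splitter %d clusters",
        lumper.n_clusters, splitter.n_clusters,
    )

    km = klee_matrix(aln, splitter, lumper, dist)
    merges = merge_candidates(km, threshold=klee_threshold)
    cases, exceptions = conflict_cases(lumper, splitter)
    for exc in exceptions:
        log.warning("refinement exception: %s", exc)

    tree_partitions: dict[str, Partition] = {}
    table_partitions: dict[str, Partition] = {}
    if table is not None and table.assignment_cols:
        table_partitions = partitions_from_table(
            table, list(table.assignment_cols)
        )
        tree_partitions = {
            m: p for m, p in table_partitions.items() if m in tree_methods
        }
    report = resolve_consensus(
        cases, km, tree_partitions, lumper, splitter,
        threshold=klee_threshold,
    )
    report.exceptions = exceptions
    log.info(
        "consensus: %d PSHs from %d conflict cases (klee_only=%s)",
        report.n_consensus, len(cases), report.klee_only,
    )

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "n_specimens": len(aln),
        "alignment_length": aln.length,
        "model": model,
        "priors": {"pmin": pmin, "pmax": pmax, "steps": steps},
        "rel_width": rel_width,
        "min_group": min_group,
        "klee_threshold": klee_threshold,
        "n_lumper": lumper.n_clusters,
        "n_splitter": splitter.n_clusters,
        "n_conflict_cases": len(cases),
        "n_consensus": report.n_consensus,
        "klee_only": report.klee_only,
        "n_morphospecies": None,
        "n_cryptic": None,
        "n_shared_all": None,
    }

    cryptic = None
    sympatry = None
    if table is not None and table.morpho_col is not None:
        cryptic = cryptic_species(report.consensus, table)
        summary["n_morphospecies"] = cryptic.n_morphospecies
        summary["n_cryptic"] = cryptic.count
        summary["n_morpho_split_both_abgd"] = _split_in_both_count(
            table, lumper, splitter
        )
        if table.locality_col is not None:
            sympatry = sympatry_status(report.consensus, table)
            summary["n_sympatric_pairs"] = int(
                (sympatry["status"] == "sympatric").sum()
            )
            summary["n_allopatric_pairs"] = int(
                (sympatry["status"] == "allopatric").sum()
            )

    if table_partitions:
        n_shared, _ = shared_clusters(table_partitions)
        summary["n_shared_all"] = n_shared
        no_multi = {
            m: p for m, p in table_partitions.items() if m != "gmyc_multiple"
        }
        if len(no_multi) != len(table_partitions):
            n_shared_nm, _ = shared_clusters(no_multi)
            summary["n_shared_excl_gmyc_multiple"] = n_shared_nm
        for m, p in table_partitions.items():
            summary[f"n_clusters_{m}"] = p.n_clusters
    else:
        n_shared, _ = shared_clusters(
            {"abgd_lumper": lumper, "abgd_splitter": splitter}
        )
        summary["n_shared_all"] = n_shared

    return WorkflowResult(
        dist=dist,
        scan=scan,
        lumper=lumper,
        splitter=splitter,
        km=km,
        merges=merges,
        report=report,
        cryptic=cryptic,
        sympatry=sympatry,
        summary=summary,
    )


def run_workflow(config: RunConfig) -> dict:
    """Execute a configured run from files; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config: %s", json.dumps(asdict(config), default=str))
        aln = read_alignment(config.alignment)
        table = None
        if config.table is not None:
            table = read_specimen_table(
                config.table,
                id_col=config.id_col,
                morpho_col=config.morpho_col,
                locality_col=config.locality_col,
                assignment_cols=config.assignment_cols or None,
            )
        result = analyze(
            aln,
            table,
            model=config.model,
            pmin=config.pmin,
            pmax=config.pmax,
            steps=config.steps,
            rel_width=config.rel_width,
            min_group=config.min_group,
            klee_threshold=config.klee_threshold,
            tree_methods=tuple(config.tree_methods),
        )

        write_partition(result.lumper, outdir / "lumper.csv")
        write_partition(result.splitter, outdir / "splitter.csv")
        write_partition(result.report.consensus, outdir / "consensus.csv")
        render_klee(result.km, outdir / "klee.png", outdir / "klee.csv")
        with open(outdir / "merges.json", "w") as fh:
            json.dump(result.merges, fh, indent=2, sort_keys=True)
        result.report.case_table().to_csv(
            outdir / "conflict_cases.csv", index=False
        )
        if result.cryptic is not None:
            result.cryptic.per_morphospecies.to_csv(
                outdir / "cryptic_species.csv", index=False
            )
        if result.sympatry is not None:
            result.sympatry.to_csv(outdir / "sympatry.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
        log.info("outputs written to %s", outdir)
        return result.summary
    finally:
        log.removeHandler(handler)
        handler.close()
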