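"""End-to-end orchestration: simulate → call → infer → stats → scan → enrich.

Every stage is a pure function over in-memory objects; this module wires
them together, keeps exhaustive drop accounting at each boundary, and
writes the tabular reports.  All output tables carry the run seed and a
configuration hash in a leading comment line so runs are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import branch_stats, calling, enrichment, origins, parsimony, simulate, tfbm
from .errors import CpgDescentError
from .phylo import (
    BRANCH_NAMES,
    FOCAL_TAXON,
    PRE_MAMMAL,
    BranchSegment,
    PhyloTree,
    SiteRecord,
    default_segments,
    default_tree,
    write_site_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on simulated inputs."""

    seed: int = 0
    out_dir: str = "cpg_descent_run"
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    n_matrices: int = 5
    matrix_width: int = 8
    matrix_conservation: float = 0.9
    core_threshold: float = tfbm.DEFAULT_CORE_THRESHOLD
    mat_threshold: float = tfbm.DEFAULT_MAT_THRESHOLD
    tiers: tuple[float, ...] = tfbm.TIER_CUTOFFS
    n_terms: int = 20
    annotation_base_rate: float = 0.1

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: Path, seed: int, config_hash: str
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_sha={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunReport:
    """In-memory results of one pipeline run."""

    manifest: list[SiteRecord]
    truth: list[simulate.TruthRecord]
    retained_vectors: list[calling.PresenceVector]
    call_drops: list[calling.DropRecord]
    parsimony_results: list[parsimony.ParsimonyResult]
    parsimony_drops: list[tuple[str, str]]
    assignments_all: list[origins.OriginAssignment]
    assignments_ptsd: list[origins.OriginAssignment]
    cumulative_all: dict[str, float]
    cumulative_ptsd: dict[str, float]
    counts_all: dict[str, int]
    counts_ptsd: dict[str, int]
    rates_all: dict[str, float]
    rates_ptsd: dict[str, float]
    chisq: dict[str, branch_stats.ChiSquareResult | None]
    pairwise: dict[str, list[branch_stats.PairwiseResult]]
    scaling: branch_stats.ScalingFit | None
    hits: list[tfbm.MotifHit]
    tfbm_summary: tfbm.TfbmSummary
    enrichment_results: list[enrichment.EnrichmentResult]


def _on_path_counts(counts: Mapping[str, int]) -> list[int]:
    return [counts[name] for name in BRANCH_NAMES]


def run_pipeline(
    config: RunConfig,
    tree: PhyloTree | None = None,
    segments: Sequence[BranchSegment] | None = None,
    out_dir: Path | None = None,
) -> RunReport:
    """Run every stage on freshly simulated data; optionally write reports."""
    tree = tree or default_tree()
    segments = list(segments or default_segments())

    # 1. simulate
    manifest, windows_a, windows_b, truth = simulate.simulate_sites(
        config.simulation, tree, segments
    )
    windows = {(w.site_id, w.source): w for w in (*windows_a, *windows_b)}

    # 2. call + reconcile (strict dual-source concordance)
    site_ids = [r.site_id for r in manifest]
    retained_vectors, call_drops = calling.reconcile_all(
        windows, site_ids, tree.taxa
    )

    # 3. parsimony + unambiguity filter
    results = [parsimony.reconstruct(tree, v) for v in retained_vectors]
    kept, parsimony_drops = parsimony.filter_unambiguous(results)

    # conservation check at every boundary
    assert len(retained_vectors) + len(call_drops) == len(manifest)
    assert len(kept) + len(parsimony_drops) == len(results)

    # 4. origins + cumulative presence, all sites and flagged subset
    assignments = [origins.assign_origin(r, tree, segments) for r in kept]
    flags = {r.site_id: r.ptsd_flag for r in manifest}
    assignments_all, assignments_ptsd = origins.split_by_flag(assignments, flags)
    cumulative_all = (
        origins.cumulative_presence(assignments_all, segments)
        if assignments_all
        else {}
    )
    cumulative_ptsd = (
        origins.cumulative_presence(assignments_ptsd, segments)
        if assignments_ptsd
        else {}
    )

    counts_all = origins.origin_counts(assignments_all)
    counts_ptsd = origins.origin_counts(assignments_ptsd)
    rates_all = branch_stats.rate_table(counts_all, segments)
    rates_ptsd = branch_stats.rate_table(counts_ptsd, segments)
    durations = {s.name: s.duration for s in segments}

    # 5. chi-square designs (pre_mammal origins excluded: they did not
    # evolve on a human-descent stem)
    on_all = _on_path_counts(counts_all)
    on_ptsd = _on_path_counts(counts_ptsd)
    chisq: dict[str, branch_stats.ChiSquareResult | None] = {
        "even": None,
        "subset_vs_background": None,
    }
    if sum(on_ptsd) > 0:
        chisq["even"] = branch_stats.chisq_even(on_ptsd)
    if all(c > 0 for c in on_all) and sum(on_ptsd) > 0:
        chisq["subset_vs_background"] = branch_stats.chisq_subset_vs_background(
            on_ptsd, on_all
        )
    else:
        logger.info("subset-vs-background test skipped (zero background cell)")
    pairwise = {
        "count": branch_stats.chisq_pairwise(counts_ptsd, durations, "count"),
        "rate": branch_stats.chisq_pairwise(counts_ptsd, durations, "rate"),
    }

    # 6. linear scaling of subset vs total branch counts
    scaling = None
    points = list(zip(on_all, on_ptsd))
    try:
        scaling = branch_stats.scaling_fit(points)
    except CpgDescentError as exc:
        logger.info("scaling fit skipped: %s", exc)

    # 7. motif scan over human windows of flagged retained sites
    pwms = simulate.simulate_matrices(
        config.n_matrices,
        config.matrix_width,
        config.matrix_conservation,
        seed=config.seed + 1,
    )
    ptsd_ids = {a.site_id for a in assignments_ptsd}
    human_windows = {
        w.site_id: w.sequences[FOCAL_TAXON]
        for w in windows_a
        if w.site_id in ptsd_ids
    }
    hits = tfbm.scan_many(
        pwms, human_windows, config.core_threshold, config.mat_threshold
    )
    origin_map = {a.site_id: a.origin for a in assignments}
    summary = tfbm.tier_and_summarize(hits, origin_map, config.tiers)

    # 8. branch-wise enrichment of flagged-site genes vs full background
    genes_universe = {
        r.site_id: r.gene for r in manifest if r.site_id in origin_map and r.gene
    }
    annotations = simulate.simulate_annotations(
        sorted(set(genes_universe.values())),
        n_terms=config.n_terms,
        base_rate=config.annotation_base_rate,
        seed=config.seed + 2,
    )
    enrich_results = enrichment.enrich_by_branch(
        assignments_ptsd,
        manifest,
        annotations,
        universe=set(genes_universe.values()),
    )

    report = RunReport(
        manifest=manifest,
        truth=truth,
        retained_vectors=retained_vectors,
        call_drops=call_drops,
        parsimony_results=results,
        parsimony_drops=parsimony_drops,
        assignments_all=assignments_all,
        assignments_ptsd=assignments_ptsd,
        cumulative_all=cumulative_all,
        cumulative_ptsd=cumulative_ptsd,
        counts_all=counts_all,
        counts_ptsd=counts_ptsd,
        rates_all=rates_all,
        rates_ptsd=rates_ptsd,
        chisq=chisq,
        pairwise=pairwise,
        scaling=scaling,
        hits=hits,
        tfbm_summary=summary,
        enrichment_results=enrich_results,
    )
    if out_dir is not None:
        write_reports(report, config, segments, Path(out_dir))
    return report


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def parsimony_frame(results: Sequence[parsimony.ParsimonyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.site_id,
                r.change_count,
                r.min_changes,
                r.consistency_index,
                int(r.unique_mpr),
                ";".join(f"{a}-{b}" for a, b in sorted(r.change_edges)),
                int(r.retained),
            )
            for r in results
        ],
        columns=["site_id", "s", "m", "ci", "unique_mpr", "change_edges", "retained"],
    )


def write_reports(
    report: RunReport,
    config: RunConfig,
    segments: Sequence[BranchSegment],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed, sha = config.seed, config.config_hash()

    def emit(df: pd.DataFrame, name: str) -> None:
        write_table(df, out_dir / name, seed, sha)

    write_site_manifest(report.manifest, out_dir / "manifest.tsv")
    emit(simulate.truth_table_frame(report.truth), "truth.tsv")

    drops = [("calling", d.site_id, d.reason) for d in report.call_drops]
    drops += [("parsimony", sid, reason) for sid, reason in report.parsimony_drops]
    emit(pd.DataFrame(drops, columns=["stage", "site_id", "reason"]), "drop_log.tsv")

    emit(parsimony_frame(report.parsimony_results), "parsimony.tsv")
    emit(
        pd.DataFrame(
            [(a.site_id, a.origin) for a in report.assignments_all],
            columns=["site_id", "origin"],
        ),
        "origins.tsv",
    )
    for name, curve in (
        ("cumulative_all.tsv", report.cumulative_all),
        ("cumulative_ptsd.tsv", report.cumulative_ptsd),
    ):
        emit(
            pd.DataFrame(curve.items(), columns=["ancestor", "percent_present"]),
            name,
        )

    emit(
        pd.DataFrame(
            [
                (
                    s.name,
                    round(s.duration, 1),
                    report.counts_all[s.name],
                    round(report.rates_all[s.name], 1),
                    report.counts_ptsd[s.name],
                    round(report.rates_ptsd[s.name], 1),
                )
                for s in segments
            ]
            + [
                (
                    PRE_MAMMAL,
                    float("nan"),
                    report.counts_all[PRE_MAMMAL],
                    float("nan"),
                    report.counts_ptsd[PRE_MAMMAL],
                    float("nan"),
                )
            ],
            columns=[
                "branch",
                "duration_myr",
                "count_all",
                "rate_all",
                "count_ptsd",
                "rate_ptsd",
            ],
        ),
        "branch_summary.tsv",
    )

    chi_rows = []
    for design, res in report.chisq.items():
        if res is not None:
            chi_rows.append(
                (design, res.statistic, res.df, res.p, int(res.low_expected))
            )
    emit(
        pd.DataFrame(
            chi_rows, columns=["design", "statistic", "df", "p", "low_expected"]
        ),
        "chisq.tsv",
    )

    pair_rows = []
    for mode, pairs in report.pairwise.items():
        n_tests = sum(1 for p in pairs if p.testable)
        for p in pairs:
            if p.testable and p.result is not None:
                pair_rows.append(
                    (
                        mode,
                        p.branch_a,
                        p.branch_b,
                        p.result.statistic,
                        p.result.df,
                        p.result.p,
                        min(1.0, p.result.p * n_tests),  # Bonferroni column
                    )
                )
            else:
                pair_rows.append(
                    (mode, p.branch_a, p.branch_b, None, None, None, None)
                )
    emit(
        pd.DataFrame(
            pair_rows,
            columns=["mode", "branch_a", "branch_b", "statistic", "df", "p",
                     "p_bonferroni"],
        ),
        "pairwise.tsv",
    )

    if report.scaling is not None:
        emit(
            pd.DataFrame(
                [
                    (
                        report.scaling.slope,
                        report.scaling.intercept,
                        report.scaling.r_squared,
                        report.scaling.n_points,
                    )
                ],
                columns=["slope", "intercept", "r_squared", "n_points"],
            ),
            "scaling.tsv",
        )

    emit(
        pd.DataFrame(
            [
                (
                    h.matrix_id,
                    h.family,
                    h.site_id,
                    h.strand,
                    h.start,
                    h.end,
                    h.mat_sim,
                    h.core_sim,
                    int(h.overlaps_cpg),
                )
                for h in report.hits
            ],
            columns=["matrix_id", "family", "site_id", "strand", "start", "end",
                     "mat_sim", "core_sim", "overlaps_cpg"],
        ),
        "hits.tsv",
    )
    emit(
        pd.DataFrame(
            [
                (tier, report.tfbm_summary.tier_hits[tier],
                 report.tfbm_summary.tier_sites[tier])
                for tier in report.tfbm_summary.tier_hits
            ],
            columns=["tier", "n_hits", "n_unique_sites"],
        ),
        "tfbm_tiers.tsv",
    )

    emit(
        pd.DataFrame(
            [
                (r.branch, r.term, r.overlap, r.selection_size, r.term_size,
                 r.universe_size, r.p, r.fdr)
                for r in report.enrichment_results
            ],
            columns=["branch", "term", "k", "n", "K", "N", "p", "fdr"],
        ),
        "enrichment.tsv",
    )
    logger.info("reports written to %s", out_dir)
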