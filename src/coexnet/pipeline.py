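"""Full-analysis orchestration: tables -> hits -> networks -> scores -> reports.

Runs both regulation directions end-to-end the way the individual modules
compose by hand: average replicates, rank, select hits, build and export
the coexpression network, score the predicted genes (CoRegScore) against a
random-gene-list null, profile every marked cluster across the configured
experiments (UpRegScore + null), and evaluate clusters against an optional
genome-wide target-class ranking.  All outputs are plain TSV/SIF/JSON in
the configured output directory, with a manifest recording parameters and
seed; identical configurations and seeds reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coexdb, enrichment, expression, network, scores, significance

logger = logging.getLogger("coexnet")


@dataclass
class RunConfig:
    """Parameters of one full analysis run.

    Defaults mirror the study design this pipeline automates: 250 hits per
    direction, 40 coexpression partners per gene, 50 predicted genes, a
    100-list random null.
    """

    expression: str
    partner_db: str
    out_dir: str
    target_ranking: str | None = None
    experiments: dict[str, str] = field(default_factory=dict)
    n_hits: int = 250
    K: int = 40
    m_predicted: int = 50
    n_null_lists: int = 100
    seed: int = 1
    min_cluster_size: int = 3
    refine_clusters: bool = False
    directions: tuple[str, ...] = ("up", "down")
    cluster_override: str | None = None


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "directions" in cfg:
        cfg["directions"] = tuple(cfg["directions"])
    if "experiments" in cfg and cfg["experiments"] is None:
        cfg["experiments"] = {}
    return RunConfig(**cfg)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violated invariants (empty means the config is ok)."""
    violations: list[str] = []
    if config.n_hits <= 0:
        violations.append(f"n_hits must be positive, got {config.n_hits}")
    if config.K <= 0:
        violations.append(f"K must be positive, got {config.K}")
    if config.m_predicted < 1:
        violations.append(f"m_predicted must be >= 1, got {config.m_predicted}")
    if config.n_null_lists < 2:
        violations.append(f"n_null_lists must be >= 2, got {config.n_null_lists}")
    if config.min_cluster_size < 1:
        violations.append("min_cluster_size must be >= 1")
    for direction in config.directions:
        if direction not in ("up", "down"):
            violations.append(f"unknown direction {direction!r}")
    for name in ("expression", "partner_db"):
        path = getattr(config, name)
        if not Path(path).is_file():
            violations.append(f"{name} path does not exist: {path}")
    for label, path in config.experiments.items():
        if not Path(path).is_file():
            violations.append(f"experiment {label!r} path does not exist: {path}")
    if config.target_ranking and not Path(config.target_ranking).is_file():
        violations.append(f"target_ranking path does not exist: {config.target_ranking}")
    if config.cluster_override and not Path(config.cluster_override).is_file():
        violations.append(f"cluster_override path does not exist: {config.cluster_override}")
    return violations


def _null_from_values(values: Sequence[float], seed: int) -> significance.NullDistribution:
    arr = np.asarray(values, dtype=float)
    return significance.NullDistribution(
        values=tuple(float(v) for v in values),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        seed=seed,
    )


def _direction_analysis(
    direction: str,
    summaries: Sequence[expression.GeneSummary],
    coding: pd.Series,
    db: coexdb.CoexpressionDatabase,
    config: RunConfig,
    out_dir: Path,
    override: Mapping[str, str] | None,
) -> dict:
    """One regulation direction: hits, network, prediction, nulls, export."""
    ranking = expression.rank_genes(summaries, direction)  # type: ignore[arg-type]
    hits = expression.select_hits(ranking, config.n_hits, coding)
    logger.info("[%s] %d hits retained of top-%d", direction, len(hits), config.n_hits)

    net = network.build_network(hits, db)
    incl = network.hit_inclusion_fraction(net)
    conn = network.connections_per_hit(net)
    predicted, shortfall = network.predict_genes(hits, db, config.m_predicted)
    observed_score = scores.co_reg_score(predicted, ranking, config.n_hits) if predicted else None

    # identical analysis on random same-sized gene lists
    universe = [s.gene for s in summaries]
    rand_lists = significance.random_gene_lists(
        universe, size=len(hits), n_lists=config.n_null_lists, seed=config.seed
    )
    null_incl, null_conn, null_score = [], [], []
    for genes in rand_lists:
        rnet = network.build_network(genes, db)
        null_incl.append(network.hit_inclusion_fraction(rnet))
        null_conn.append(network.connections_per_hit(rnet))
        rpred, _ = network.predict_genes(genes, db, config.m_predicted)
        if rpred:
            null_score.append(scores.co_reg_score(rpred, ranking, config.n_hits).score)

    sig_rows = []
    for name, observed, values in (
        ("hit_inclusion_pct", incl, null_incl),
        ("connections_per_hit", conn, null_conn),
        ("co_reg_score", observed_score.score if observed_score else None, null_score),
    ):
        if observed is None or len(values) < 2:
            continue
        null = _null_from_values(values, config.seed)
        if null.sd == 0:
            logger.warning("[%s] degenerate null for %s; skipping", direction, name)
            continue
        res = significance.significance(observed, null, direction="upper")
        sig_rows.append(
            {
                "metric": name,
                "observed": res.observed,
                "null_mean": null.mean,
                "null_sd": null.sd,
                "z": res.z,
                "p": res.p,
                "n_lists": null.n_lists,
                "seed": config.seed,
            }
        )
    pd.DataFrame(sig_rows).to_csv(
        out_dir / f"{direction}.significance.tsv", sep="\t", index=False
    )

    network.integrate_predicted(net, predicted, hits, db)
    clusters = network.assign_clusters(
        net, config.min_cluster_size, refine=config.refine_clusters, override=override
    )
    means = {s.gene: s.mean for s in summaries}
    network.export_network(
        net,
        clusters,
        out_dir / f"{direction}.network",
        node_means=means,
        manifest={"direction": direction, "seed": config.seed, "n_hits": config.n_hits},
    )
    if observed_score is not None:
        report = scores.score_report({"co_reg_score": observed_score})
        report.to_csv(out_dir / f"{direction}.co_reg_score.tsv", sep="\t")
    return {
        "direction": direction,
        "ranking": ranking,
        "hits": hits,
        "network": net,
        "clusters": clusters,
        "hit_inclusion_pct": incl,
        "connections_per_hit": conn,
        "predicted": predicted,
        "predicted_shortfall": shortfall,
        "co_reg_score": observed_score,
    }


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory results keyed by stage."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = expression.read_expression_table(config.expression)
    summaries = expression.average_replicates(table)
    expression.summary_frame(summaries).to_csv(out_dir / "summary.tsv", sep="\t")
    db = coexdb.load_partner_db(config.partner_db, K=config.K)

    override: dict[str, str] | None = None
    if config.cluster_override:
        odf = pd.read_csv(config.cluster_override, sep="\t", dtype=str)
        override = dict(zip(odf.iloc[:, 0], odf.iloc[:, 1]))

    results: dict = {"config": config, "directions": {}}
    for direction in config.directions:
        results["directions"][direction] = _direction_analysis(
            direction, summaries, table.coding, db, config, out_dir, override
        )

    # cluster x experiment regulation profile
    exp_rankings: list[tuple[str, expression.Ranking]] = [
        ("main", expression.rank_genes(summaries, "up"))
    ]
    for label in sorted(config.experiments):
        etab = expression.read_expression_table(config.experiments[label])
        esum = expression.average_replicates(etab)
        exp_rankings.append((label, expression.rank_genes(esum, "up")))
    profile_frames = []
    for direction, dres in results["directions"].items():
        clusters = dres["clusters"]
        if not clusters.numbered_labels():
            continue
        matrix, cells = scores.cluster_profile(clusters, exp_rankings)
        matrix.index = [f"{direction}_{lab}" for lab in matrix.index]
        profile_frames.append(matrix)
        dres["cluster_profile"] = (matrix, cells)
    if profile_frames:
        profile = pd.concat(profile_frames)
        profile.to_csv(out_dir / "cluster_profile.tsv", sep="\t", index_label="cluster")
        results["cluster_profile"] = profile

    # per-cluster UpRegScore significance against random same-sized lists
    sig_rows = []
    universe = [s.gene for s in summaries]
    for direction, dres in results["directions"].items():
        clusters = dres["clusters"]
        for lab in clusters.numbered_labels():
            members = clusters.members(lab)
            for exp_label, ranking in exp_rankings:
                try:
                    observed = scores.up_reg_score(members, ranking).score
                except ValueError:
                    continue
                rand = significance.random_gene_lists(
                    universe, size=len(members), n_lists=config.n_null_lists, seed=config.seed
                )
                null = significance.null_distribution(
                    lambda genes, r=ranking: scores.up_reg_score(genes, r).score,
                    rand,
                    seed=config.seed,
                )
                res = significance.significance(observed, null, direction="upper")
                sig_rows.append(
                    {
                        "cluster": f"{direction}_{lab}",
                        "experiment": exp_label,
                        "up_reg_score": res.observed,
                        "null_mean": null.mean,
                        "null_sd": null.sd,
                        "z": res.z,
                        "p": res.p,
                    }
                )
    if sig_rows:
        pd.DataFrame(sig_rows).to_csv(
            out_dir / "cluster_significance.tsv", sep="\t", index=False
        )

    # target-class ranking enrichment
    if config.target_ranking:
        tr = enrichment.load_target_ranking(config.target_ranking)
        rows = []
        for direction, dres in results["directions"].items():
            clusters = dres["clusters"]
            for lab in clusters.numbered_labels():
                members = clusters.members(lab)
                try:
                    er = enrichment.target_fraction_enrichment(members, tr)
                except ValueError:
                    continue
                rows.append(
                    {
                        "cluster": f"{direction}_{lab}",
                        "observed_pct": er.observed_pct,
                        "expected_pct": er.expected_pct,
                        "p": er.p,
                        "n_found": er.n_found,
                        "n_class1": er.n_class1,
                        "n_class2": er.n_class2,
                        "n_missing": er.n_missing,
                    }
                )
        enr = pd.DataFrame(rows)
        enr.to_csv(out_dir / "target_enrichment.tsv", sep="\t", index=False)
        results["target_enrichment"] = enr

    manifest = {
        "parameters": {
            "n_hits": config.n_hits,
            "K": config.K,
            "m_predicted": config.m_predicted,
            "n_null_lists": config.n_null_lists,
            "seed": config.seed,
            "min_cluster_size": config.min_cluster_size,
            "refine_clusters": config.refine_clusters,
            "directions": list(config.directions),
        },
        "counts": {
            direction: {
                "hits_retained": len(dres["hits"]),
                "db_absent_hits": sum(
                    1
                    for n, d in dres["network"].graph.nodes(data=True)
                    if d["role"] == network.ROLE_HIT and d.get("db_absent")
                ),
                "considered_pairs": dres["network"].considered_pairs,
                "predicted": len(dres["predicted"]),
            }
            for direction, dres in results["directions"].items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
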