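"""End-to-end orchestration: simulate -> AEC -> build -> metrics -> stats.

`run_full_analysis` drives every stage of the connectome analysis from a
single configuration and writes a machine-readable report plus TSV tables
under one output directory.  Runs are deterministic given the seed; the
resolved configuration is echoed into the report so any run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aec as aec_mod
from .connectome import (
    ConnectivityMatrix,
    build_connectivity_matrix,
    count_possible_connections,
    default_node_table,
)
from .metrics import detect_hubs, global_metrics
from .stats import (
    compare_edges,
    compare_global_metrics,
    compare_nodes,
    correlate_with_cognition,
    icc_matrices,
)
from .synthetic import (
    Cohort,
    SyntheticConfig,
    generate_cohort,
    generate_retest_pair,
    generate_streamline_bundle,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger("strucnet")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "export_connectogram_edgelist"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Exactly one input mode: either ``manifest_path`` points at an existing
    cohort, or ``synthetic`` parameterizes a simulated one.
    """

    synthetic: SyntheticConfig | None = None
    manifest_path: str | None = None
    q_level: float = 0.05
    alpha: float = 0.05
    aec_fraction: float = 0.01
    cognitive_scores: tuple[str, ...] = ("zPASAT", "zSDMT", "zAttention")
    n_retest_subjects: int = 5
    n_aec_demo_pairs: int = 30
    out_dir: str = "strucnet_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest_path is None):
            raise ValueError(
                "exactly one input mode: set synthetic or manifest_path"
            )
        for name in ("q_level", "alpha", "aec_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        scores = raw.pop("cognitive_scores", None)
        cfg = cls(synthetic=syn, **raw)
        if scores is not None:
            cfg.cognitive_scores = tuple(scores)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cognitive_scores"] = list(self.cognitive_scores)
        return d


@dataclass
class AnalysisReport:
    """All result tables of one run plus a provenance block."""

    global_table: pd.DataFrame
    node_table: pd.DataFrame
    edge_table: pd.DataFrame
    hubs: dict[str, dict]
    cognition: dict[str, dict[str, pd.DataFrame]]
    icc: list[dict]
    aec_demo: dict
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        return {
            "provenance": self.provenance,
            "global": {
                row.element: {
                    "t": None if pd.isna(row.statistic) else float(row.statistic),
                    "p": None if pd.isna(row.p) else float(row.p),
                    "significant": bool(row.significant),
                }
                for row in self.global_table.itertuples(index=False)
            },
            "n_nodes_decreased": int(
                ((self.node_table.direction < 0)
                 & self.node_table.significant).sum()
            ),
            "n_edges_decreased": int(
                ((self.edge_table.direction < 0)
                 & self.edge_table.significant).sum()
            ),
            "n_edges_increased": int(
                ((self.edge_table.direction > 0)
                 & self.edge_table.significant).sum()
            ),
            "hubs": self.hubs,
            "cognition": {
                score: {
                    fam: int(tab.significant.sum())
                    for fam, tab in fams.items()
                }
                for score, fams in self.cognition.items()
            },
            "icc": self.icc,
            "aec_demo": self.aec_demo,
        }


def _aec_build_demo(
    cohort: Cohort, config: AnalysisConfig, rng: np.random.Generator
) -> dict:
    """Exercise the streamline stages on a subset of one subject's edges.

    Bundles are generated from the first subject's FA values for up to
    ``n_aec_demo_pairs`` connections, contaminated, AEC-filtered, and
    rebuilt into matrix entries; the digest reports how closely the rebuilt
    entries track the subject's matrix (mean-of-streamlines sampling error).
    """
    subject = cohort.subjects[0]
    w = subject.matrix.weights
    n = subject.matrix.n
    iu = np.triu_indices(n, k=1)
    nz = np.flatnonzero(w[iu] > 0)
    take = nz[: config.n_aec_demo_pairs]
    filtered = {}
    n_raw = n_kept = 0
    for k in take:
        a, b = int(iu[0][k]), int(iu[1][k])
        bundle = generate_streamline_bundle(
            (a, b), n_true=20, n_offpath=5, n_lowweight=3,
            fa_value=float(w[a, b]), seed=int(rng.integers(2**31)), n_nodes=n,
        )
        survivors = aec_mod.apply_aec(bundle, (a, b), config.aec_fraction)
        filtered[(a, b)] = survivors
        n_raw += len(bundle)
        n_kept += len(survivors)
    matrix = build_connectivity_matrix(filtered, n, subject.matrix.node_labels)
    rebuilt = matrix.weights[iu][take]
    designed = w[iu][take]
    return {
        "n_connections": int(take.size),
        "n_streamlines_in": n_raw,
        "n_streamlines_surviving": n_kept,
        "max_abs_error_vs_subject_fa": float(np.abs(rebuilt - designed).max())
        if take.size else None,
    }


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run every stage on the configured input and write all outputs.

    Stages: cohort simulation (or loading), AEC demonstration on streamline
    bundles, matrix construction, whole-brain/node/edge group comparisons,
    hub detection per group, cognition correlations, and test-retest ICC.
    """
    logging.basicConfig(level=config.log_level)
    rng = np.random.default_rng(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        logger.info("simulating cohort (seed=%d)", config.synthetic.seed)
        cohort, truth = generate_cohort(config.synthetic)
        write_cohort(cohort, truth, out / "cohort")
    else:
        logger.info("loading cohort from %s", config.manifest_path)
        cohort = read_cohort(config.manifest_path)

    logger.info("AEC demonstration on %d connections", config.n_aec_demo_pairs)
    aec_demo = _aec_build_demo(cohort, config, rng)

    logger.info("group comparisons")
    global_table = compare_global_metrics(cohort, config.alpha)
    node_table = compare_nodes(cohort, config.q_level)
    edge_table = compare_edges(cohort, config.q_level)
    assert len(edge_table) == count_possible_connections(cohort.n_nodes)

    hubs = {}
    for grp in ("HV", "MS"):
        flags, threshold, strength = detect_hubs(
            [s.matrix for s in cohort.group(grp)]
        )
        hubs[grp] = {
            "hub_nodes": np.flatnonzero(flags).tolist(),
            "threshold": float(threshold),
        }

    cognition: dict[str, dict[str, pd.DataFrame]] = {}
    for score in config.cognitive_scores:
        try:
            nodes, edges = correlate_with_cognition(cohort, score, config.q_level)
        except ValueError as exc:
            logger.warning("skipping %s correlations: %s", score, exc)
            continue
        cognition[score] = {"nodes": nodes, "edges": edges}

    logger.info("test-retest ICC on %d subjects", config.n_retest_subjects)
    retest_sd = (
        config.synthetic.retest_noise_sd if config.synthetic is not None else 0.02
    )
    icc_rows = []
    for s in cohort.subjects[: config.n_retest_subjects]:
        m1, m2 = generate_retest_pair(
            s.matrix, retest_sd, seed=int(rng.integers(2**31))
        )
        res = icc_matrices(m1, m2)
        icc_rows.append({
            "subject_id": s.subject_id,
            "icc": res.estimate,
            "variant": res.variant,
            "n_items": res.n_items,
        })

    report = AnalysisReport(
        global_table=global_table,
        node_table=node_table,
        edge_table=edge_table,
        hubs=hubs,
        cognition=cognition,
        icc=icc_rows,
        aec_demo=aec_demo,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "package": "strucnet",
            "version": _version(),
        },
    )
    _write_report(report, out, cohort)
    return report


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("strucnet")
    except Exception:
        return "unknown"


def _write_report(report: AnalysisReport, out: Path, cohort: Cohort) -> None:
    report.global_table.to_csv(out / "global_comparison.tsv", sep="\t", index=False)
    report.node_table.to_csv(out / "node_comparison.tsv", sep="\t", index=False)
    report.edge_table.to_csv(out / "edge_comparison.tsv", sep="\t", index=False)
    for score, fams in report.cognition.items():
        for fam, tab in fams.items():
            tab.to_csv(out / f"correlation_{score}_{fam}.tsv", sep="\t", index=False)
    node_table = default_node_table() if cohort.n_nodes == 84 else pd.DataFrame({
        "index": np.arange(cohort.n_nodes),
        "label": cohort.node_labels,
        "hemisphere": "",
        "class": "",
    })
    export_connectogram_edgelist(
        report.edge_table, node_table, out / "significant_edges.tsv"
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)


def export_connectogram_edgelist(
    edge_table: pd.DataFrame, node_table: pd.DataFrame, path
) -> pd.DataFrame:
    """TSV of significant edges with labels, sign and q, for circular plots.

    One row per significant edge of the StatTable; suitable as input to
    external connectogram tools (this package draws nothing itself).
    """
    labels = node_table.set_index("index")["label"]
    n = len(labels)
    rows = []
    for row in edge_table.itertuples(index=False):
        if not row.significant:
            continue
        a, b = row.element
        if a >= n or b >= n:
            raise ValueError(f"edge ({a}, {b}) outside the node table")
        rows.append((
            labels.loc[a], labels.loc[b], float(row.statistic),
            int(row.direction), float(row.q),
        ))
    df = pd.DataFrame(
        rows,
        columns=["node_a_label", "node_b_label", "statistic", "direction", "q"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
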