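"""Synthetic FA-weighted connectome cohorts with MS-like group structure.

No public diffusion-MRI cohort underlies this package, so the statistical
machinery is exercised on simulated data whose structure mirrors the study
design it implements:

* an 84-node FA-weighted base network with designated hub nodes (modular
  random topology with preferential extra attachment to hubs, reproducing
  the heavy-tailed strength distribution the hub rule presupposes);
* a patient group whose matrices carry FA reductions on many edges and
  increases on a few, applied to the shared base before per-subject noise
  (so all patients share effect loci, as lesion topography partially does);
* cognitive z-scores for patients only, linearly coupled to the mean FA of a
  designated circuit of edges plus noise;
* same-day retest sessions as independently re-noised copies of a matrix;
* per-connection streamline bundles contaminated with off-path and
  low-weight streamlines, for exercising the anatomical-exclusion filter.

All noise is additive Gaussian on edge FA, truncated to [0, 1] — the
simplest model consistent with FA bounds.  Every generator is a pure
function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .aec import StreamlineRecord
from .connectome import ConnectivityMatrix, count_possible_connections

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Subject",
    "Cohort",
    "generate_base_connectome",
    "generate_cohort",
    "generate_retest_pair",
    "generate_streamline_bundle",
]

_HUB_BOOST = 1.6  # extra attachment factor for hub-incident pairs
_MODULE_RATIO = 1.5  # within-module vs between-module edge probability


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the scale of the study design this package targets:
    38 healthy volunteers vs 72 patients on 84-node networks, FA reductions
    on 793 edges and increases on 24, with nine designated hub regions.
    """

    n_nodes: int = 84
    n_hv: int = 38
    n_ms: int = 72
    edge_density: float = 0.6
    fa_mean: float = 0.45
    fa_sd: float = 0.04
    n_hub_nodes: int = 9
    n_edges_decreased: int = 793
    n_edges_increased: int = 24
    delta_decrease: float = 0.08
    delta_increase: float = 0.08
    subject_noise_sd: float = 0.03
    coupling_strength: float = 0.8
    cognition_noise_sd: float = 0.8
    retest_noise_sd: float = 0.02
    n_circuit_edges: int = 73
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 < self.fa_mean < 1:
            raise ValueError("fa_mean must be in (0, 1)")
        for name in (
            "fa_sd", "delta_decrease", "delta_increase", "subject_noise_sd",
            "coupling_strength", "cognition_noise_sd", "retest_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_pairs = count_possible_connections(self.n_nodes)
        if self.n_edges_decreased + self.n_edges_increased > n_pairs:
            raise ValueError(
                "effect masks exceed the number of possible connections"
            )
        if self.n_hub_nodes > self.n_nodes:
            raise ValueError("n_hub_nodes must be <= n_nodes")


@dataclass
class GroundTruth:
    """Designed effect loci of a synthetic cohort (node pairs, a < b)."""

    decreased_edge_mask: set[tuple[int, int]]
    increased_edge_mask: set[tuple[int, int]]
    circuit_edges: set[tuple[int, int]]
    true_coupling: float
    hub_nodes: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.decreased_edge_mask & self.increased_edge_mask:
            raise ValueError("decreased and increased masks must be disjoint")
        for mask in (self.decreased_edge_mask, self.increased_edge_mask,
                     self.circuit_edges):
            for a, b in mask:
                if not a < b:
                    raise ValueError(f"pair ({a}, {b}) not in a < b order")

    def to_json(self, path) -> None:
        payload = {
            "decreased_edge_mask": sorted(self.decreased_edge_mask),
            "increased_edge_mask": sorted(self.increased_edge_mask),
            "circuit_edges": sorted(self.circuit_edges),
            "true_coupling": self.true_coupling,
            "hub_nodes": sorted(self.hub_nodes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class Subject:
    subject_id: str
    group: str  # "HV" or "MS"
    matrix: ConnectivityMatrix
    zpasat: float | None = None
    zsdmt: float | None = None
    zattention: float | None = None


@dataclass
class Cohort:
    """A two-group collection of subjects sharing one node set."""

    subjects: list[Subject]

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == name]

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].matrix.n

    @property
    def node_labels(self) -> list[str]:
        return self.subjects[0].matrix.node_labels

    def edge_array(self, group: str | None = None) -> np.ndarray:
        """Stacked upper-triangle edge vectors, shape (n_subjects, n_pairs)."""
        subjects = self.subjects if group is None else self.group(group)
        return np.vstack([s.matrix.upper_triangle() for s in subjects])

    def strength_array(self, group: str | None = None) -> np.ndarray:
        """Stacked nodal strengths, shape (n_subjects, n_nodes)."""
        subjects = self.subjects if group is None else self.group(group)
        return np.vstack([s.matrix.weights.sum(axis=1) for s in subjects])

    def manifest(self) -> pd.DataFrame:
        rows = [
            (s.subject_id, s.group, s.zpasat, s.zsdmt, s.zattention)
            for s in self.subjects
        ]
        return pd.DataFrame(
            rows, columns=["subject_id", "group", "zPASAT", "zSDMT", "zAttention"]
        )


def _pair_probabilities(
    n_nodes: int, edge_density: float, hub_nodes: np.ndarray
) -> np.ndarray:
    """Upper-triangle edge probabilities: modular + hub-boosted, calibrated
    so the expected edge count equals ``edge_density * n_pairs`` exactly."""
    half = n_nodes // 2
    module = np.zeros(n_nodes, dtype=int)
    module[half:] = 1
    iu = np.triu_indices(n_nodes, k=1)
    base = np.where(module[iu[0]] == module[iu[1]], _MODULE_RATIO, 1.0)
    is_hub = np.zeros(n_nodes, dtype=bool)
    is_hub[hub_nodes] = True
    base = base * np.where(is_hub[iu[0]] | is_hub[iu[1]], _HUB_BOOST, 1.0)
    target = edge_density * base.size
    # fixed-point rescale with clipping at 1
    c = target / base.sum()
    for _ in range(50):
        p = np.minimum(1.0, base * c)
        total = p.sum()
        if abs(total - target) < 1e-9:
            break
        free = base[base * c < 1.0].sum()
        if free <= 0:
            break
        c += (target - total) / free
    return np.minimum(1.0, base * c)


def generate_base_connectome(
    n_nodes: int = 84,
    edge_density: float = 0.6,
    fa_mean: float = 0.45,
    fa_sd: float = 0.04,
    n_hub_nodes: int = 9,
    seed: int = 0,
    node_labels: Sequence[str] | None = None,
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Generate one healthy-scale FA-weighted network with designated hubs.

    Hub nodes receive systematically more connections (preferential extra
    attachment), so their strength exceeds the across-node mean by well over
    one standard deviation and the hub-detection rule flags them with high
    probability.  Returns ``(matrix, hub_node_indices)``.
    """
    cfg = SyntheticConfig(
        n_nodes=n_nodes, edge_density=edge_density, fa_mean=fa_mean,
        fa_sd=fa_sd, n_hub_nodes=n_hub_nodes, seed=seed,
        n_edges_decreased=0, n_edges_increased=0,  # reuse parameter validation
    )
    rng = np.random.default_rng(seed)
    hub_nodes = np.sort(
        rng.choice(n_nodes, size=cfg.n_hub_nodes, replace=False)
    )
    p = _pair_probabilities(n_nodes, edge_density, hub_nodes)
    present = rng.uniform(size=p.size) < p
    fa = np.clip(rng.normal(fa_mean, fa_sd, size=p.size), 0.01, 1.0)
    iu = np.triu_indices(n_nodes, k=1)
    w = np.zeros((n_nodes, n_nodes))
    w[iu] = np.where(present, fa, 0.0)
    w = w + w.T
    labels = list(node_labels) if node_labels is not None else []
    matrix = ConnectivityMatrix(w, labels)
    matrix.validate()
    return matrix, hub_nodes


def _noisy_copy(
    weights: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian noise on nonzero edges, symmetric, clipped to [0, 1]."""
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = weights[iu]
    noise = rng.normal(0.0, noise_sd, size=vals.size) if noise_sd > 0 else 0.0
    vals = np.where(vals > 0, np.clip(vals + noise, 0.0, 1.0), 0.0)
    out = np.zeros_like(weights)
    out[iu] = vals
    return out + out.T


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Generate an HV/MS cohort plus the ground truth of its designed effects.

    Patient matrices are the shared base minus ``delta_decrease`` on the
    decreased mask, plus ``delta_increase`` on the increased mask, plus
    per-subject noise, clipped to [0, 1].  Patients carry zPASAT and zSDMT
    scores coupled to the standardized mean FA over the circuit edges
    (zAttention is their mean); healthy volunteers carry no cognitive scores.
    """
    rng = np.random.default_rng(config.seed)
    base, hub_nodes = generate_base_connectome(
        config.n_nodes, config.edge_density, config.fa_mean, config.fa_sd,
        config.n_hub_nodes, seed=config.seed,
    )
    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    base_vals = base.weights[iu]
    present_idx = np.flatnonzero(base_vals > 0)
    n_effect = config.n_edges_decreased + config.n_edges_increased
    if n_effect > present_idx.size:
        raise ValueError(
            f"effect masks ({n_effect} edges) exceed the {present_idx.size} "
            "edges present in the base network"
        )
    chosen = rng.choice(present_idx, size=n_effect, replace=False)
    dec_idx = np.sort(chosen[: config.n_edges_decreased])
    inc_idx = np.sort(chosen[config.n_edges_decreased:])
    n_circuit = min(config.n_circuit_edges, dec_idx.size)
    circ_idx = (
        np.sort(rng.choice(dec_idx, size=n_circuit, replace=False))
        if n_circuit > 0
        else np.array([], dtype=int)
    )

    ms_vals = base_vals.copy()
    ms_vals[dec_idx] = np.clip(ms_vals[dec_idx] - config.delta_decrease, 0.0, 1.0)
    ms_vals[inc_idx] = np.clip(ms_vals[inc_idx] + config.delta_increase, 0.0, 1.0)
    ms_base = np.zeros_like(base.weights)
    ms_base[iu] = ms_vals
    ms_base = ms_base + ms_base.T

    subjects: list[Subject] = []
    for i in range(config.n_hv):
        w = _noisy_copy(base.weights, config.subject_noise_sd, rng)
        subjects.append(Subject(f"HV{i + 1:03d}", "HV", ConnectivityMatrix(w)))
    ms_edge_rows = []
    for i in range(config.n_ms):
        w = _noisy_copy(ms_base, config.subject_noise_sd, rng)
        subjects.append(Subject(f"MS{i + 1:03d}", "MS", ConnectivityMatrix(w)))
        ms_edge_rows.append(w[iu])

    # cognition: coupling * standardized circuit-mean FA + noise, MS only
    if config.n_ms > 0 and circ_idx.size > 0:
        circuit_fa = np.vstack(ms_edge_rows)[:, circ_idx].mean(axis=1)
        sd = circuit_fa.std(ddof=1) if config.n_ms > 1 else 0.0
        std_fa = (circuit_fa - circuit_fa.mean()) / sd if sd > 0 else np.zeros_like(circuit_fa)
        zpasat = config.coupling_strength * std_fa + rng.normal(
            0.0, config.cognition_noise_sd, size=config.n_ms
        )
        zsdmt = config.coupling_strength * std_fa + rng.normal(
            0.0, config.cognition_noise_sd, size=config.n_ms
        )
        ms_subjects = [s for s in subjects if s.group == "MS"]
        for s, zp, zs in zip(ms_subjects, zpasat, zsdmt):
            s.zpasat = float(zp)
            s.zsdmt = float(zs)
            s.zattention = float((zp + zs) / 2.0)

    def _pairs(idx: np.ndarray) -> set[tuple[int, int]]:
        return {(int(iu[0][k]), int(iu[1][k])) for k in idx}

    truth = GroundTruth(
        decreased_edge_mask=_pairs(dec_idx),
        increased_edge_mask=_pairs(inc_idx),
        circuit_edges=_pairs(circ_idx),
        true_coupling=config.coupling_strength,
        hub_nodes={int(h) for h in hub_nodes},
    )
    return Cohort(subjects), truth


def generate_retest_pair(
    matrix: ConnectivityMatrix, retest_noise_sd: float, seed: int
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Two same-day sessions of one subject: independent measurement noise
    on the nonzero edges of the input, clipped to [0, 1]."""
    if retest_noise_sd < 0:
        raise ValueError("retest_noise_sd must be >= 0")
    matrix.validate()
    rng = np.random.default_rng(seed)
    a = _noisy_copy(matrix.weights, retest_noise_sd, rng)
    b = _noisy_copy(matrix.weights, retest_noise_sd, rng)
    labels = list(matrix.node_labels)
    return ConnectivityMatrix(a, labels), ConnectivityMatrix(b, list(labels))


def generate_streamline_bundle(
    pair: tuple[int, int],
    n_true: int = 10,
    n_offpath: int = 0,
    n_lowweight: int = 0,
    fa_value: float = 0.45,
    seed: int = 0,
    n_nodes: int = 84,
) -> list[StreamlineRecord]:
    """One connection's candidate streamlines with known contamination.

    * ``n_true`` streamlines visit exactly the two endpoints with weights
      near the bundle maximum — these survive anatomical-exclusion filtering;
    * ``n_offpath`` streamlines visit at least one extra region;
    * ``n_lowweight`` streamlines visit only the endpoints but carry weight
      below 1% of the maximum weight among the true/off-path records (when a
      bundle contains only low-weight records, the per-connection 1% rule is
      relative to themselves and the heaviest of them survives it).
    """
    if min(n_true, n_offpath, n_lowweight) < 0:
        raise ValueError("streamline counts must be >= 0")
    a, b = pair
    if not 0 <= a < b < n_nodes:
        raise ValueError(f"invalid node pair {pair} for n_nodes={n_nodes}")
    rng = np.random.default_rng(seed)
    records: list[StreamlineRecord] = []
    others = [k for k in range(n_nodes) if k not in (a, b)]

    def _fa() -> float:
        return float(np.clip(rng.normal(fa_value, 0.02), 0.0, 1.0))

    for i in range(n_true):
        records.append(StreamlineRecord(
            f"true{i:04d}", a, b,
            weight=float(rng.uniform(0.6, 1.0)),
            mean_fa=_fa(), visited_nodes=frozenset({a, b}),
        ))
    for i in range(n_offpath):
        extra = rng.choice(others, size=int(rng.integers(1, 3)), replace=False)
        records.append(StreamlineRecord(
            f"offpath{i:04d}", a, b,
            weight=float(rng.uniform(0.3, 1.0)),
            mean_fa=_fa(),
            visited_nodes=frozenset({a, b} | {int(e) for e in extra}),
        ))
    ref = max((r.weight for r in records), default=1.0)
    for i in range(n_lowweight):
        records.append(StreamlineRecord(
            f"lowweight{i:04d}", a, b,
            weight=float(rng.uniform(1e-4, 9e-3)) * ref,
            mean_fa=_fa(), visited_nodes=frozenset({a, b}),
        ))
    return records


def write_cohort(cohort: Cohort, truth: GroundTruth, out_dir) -> pd.DataFrame:
    """Write manifest CSV, per-subject matrix TSVs and ground-truth JSON.

    Returns the manifest (with a ``matrix_path`` column) as written.
    """
    from pathlib import Path
    from .connectome import write_matrix

    out = Path(out_dir)
    mat_dir = out / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    paths = []
    for s in cohort.subjects:
        p = mat_dir / f"{s.subject_id}.tsv"
        write_matrix(s.matrix, p)
        paths.append(str(p.relative_to(out)))
    manifest["matrix_path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_json(out / "ground_truth.json")
    return manifest


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a manifest CSV written by :func:`write_cohort`."""
    from pathlib import Path
    from .connectome import read_matrix

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    subjects = []
    for row in df.itertuples(index=False):
        matrix = read_matrix(manifest_path.parent / row.matrix_path)
        def _opt(v):
            return None if pd.isna(v) else float(v)
        subjects.append(Subject(
            str(row.subject_id), str(row.group), matrix,
            zpasat=_opt(row.zPASAT), zsdmt=_opt(row.zSDMT),
            zattention=_opt(row.zAttention),
        ))
    return Cohort(subjects)
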