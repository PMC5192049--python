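"""Anatomical exclusion criteria (AEC) postprocessing of streamline sets.

Probabilistic tractography produces many anatomically implausible streamlines.
AEC cleans the candidate set of every region pair in two fixed steps:

1. *Weight threshold* — discard streamlines whose track weight is below 1%
   (configurable) of the maximum track weight within that connection.
2. *Anatomical exclusion* — discard any streamline that leaves the direct
   link between the two regions, i.e. whose set of visited gray-matter
   regions is not exactly the two endpoints.

Streamlines are abstracted to :class:`StreamlineRecord`: no 3D geometry is
handled here; visited regions are precomputed attributes.  The threshold is
computed per connection (relative to that connection's maximum weight), so the
rule is scale-free within a connection and degenerates gracefully for
single-streamline bundles.

Note the two steps do not commute: a low-weight off-path streamline removed by
the threshold no longer influences anything, but an off-path streamline that
carries the maximum weight still sets the threshold for step 1 before being
removed in step 2.  The implemented order is threshold first, then exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StreamlineRecord",
    "weight_threshold_filter",
    "anatomical_exclusion",
    "apply_aec",
    "read_streamlines",
    "write_streamlines",
    "group_by_pair",
    "DEFAULT_WEIGHT_FRACTION",
]

DEFAULT_WEIGHT_FRACTION = 0.01

#: Adapter contract identifier: an external adapter mapping standard
#: tractogram files plus a parcellation lookup onto the streamline-record
#: table consumed here.  Not implemented in this package.
TRACTOGRAM_ADAPTER_CONTRACT = "strucnet.aec.tractogram_adapter/v1"


@dataclass(frozen=True)
class StreamlineRecord:
    """One candidate streamline of a node-pair connection.

    ``visited_nodes`` contains every gray-matter region the streamline
    touches, endpoints included.
    """

    streamline_id: str
    node_a: int
    node_b: int
    weight: float
    mean_fa: float
    visited_nodes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError(
                f"node_a must be < node_b, got ({self.node_a}, {self.node_b})"
            )
        if self.weight <= 0:
            raise ValueError(f"track weight must be > 0, got {self.weight}")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError(f"mean FA must be in [0, 1], got {self.mean_fa}")
        object.__setattr__(self, "visited_nodes", frozenset(self.visited_nodes))

    @property
    def pair(self) -> tuple[int, int]:
        return (self.node_a, self.node_b)


def _check_single_pair(
    records: Sequence[StreamlineRecord], pair: tuple[int, int] | None = None
) -> None:
    pairs = {r.pair for r in records}
    if pair is not None:
        pairs.add(tuple(pair))
    if len(pairs) > 1:
        raise ValueError(f"records span multiple node pairs: {sorted(pairs)}")


def weight_threshold_filter(
    records: Iterable[StreamlineRecord],
    fraction: float = DEFAULT_WEIGHT_FRACTION,
) -> list[StreamlineRecord]:
    """Keep streamlines with weight >= ``fraction`` of the connection maximum.

    The maximum is taken over the input records (per connection); an empty
    input returns empty.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    records = list(records)
    if not records:
        return []
    _check_single_pair(records)
    w_max = max(r.weight for r in records)
    cutoff = fraction * w_max
    return [r for r in records if r.weight >= cutoff]


def anatomical_exclusion(
    records: Iterable[StreamlineRecord], pair: tuple[int, int]
) -> list[StreamlineRecord]:
    """Keep only streamlines forming the direct link between the pair.

    A streamline survives iff its visited regions are exactly the two
    endpoints: touching any extra gray-matter region, or failing to reach
    both endpoints (truncated streamline), removes it.
    """
    records = list(records)
    _check_single_pair(records, pair)
    endpoint_set = frozenset(pair)
    return [r for r in records if r.visited_nodes == endpoint_set]


def apply_aec(
    records: Iterable[StreamlineRecord],
    pair: tuple[int, int],
    fraction: float = DEFAULT_WEIGHT_FRACTION,
) -> list[StreamlineRecord]:
    """Full AEC: weight threshold first, then anatomical exclusion.

    Output is a subset of the input and the operation is idempotent.
    """
    return anatomical_exclusion(weight_threshold_filter(records, fraction), pair)


# --------------------------------------------------------------------------
# Streamline-record TSV format
#
# Columns: streamline_id, node_a, node_b, weight, mean_fa, visited_nodes
# (semicolon-separated integer list).  One file may hold a single connection
# or a pool of many; group_by_pair splits a pool.

_COLUMNS = ["streamline_id", "node_a", "node_b", "weight", "mean_fa", "visited_nodes"]


def write_streamlines(records: Iterable[StreamlineRecord], path) -> None:
    rows = [
        (
            r.streamline_id,
            r.node_a,
            r.node_b,
            r.weight,
            r.mean_fa,
            ";".join(str(v) for v in sorted(r.visited_nodes)),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_streamlines(path) -> list[StreamlineRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"visited_nodes": str}, float_precision="round_trip"
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"streamline table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        visited = frozenset(
            int(v) for v in str(row.visited_nodes).split(";") if v != ""
        )
        records.append(
            StreamlineRecord(
                streamline_id=str(row.streamline_id),
                node_a=int(row.node_a),
                node_b=int(row.node_b),
                weight=float(row.weight),
                mean_fa=float(row.mean_fa),
                visited_nodes=visited,
            )
        )
    return records


def group_by_pair(
    records: Iterable[StreamlineRecord],
) -> dict[tuple[int, int], list[StreamlineRecord]]:
    """Split a pooled record collection into per-connection sets."""
    out: dict[tuple[int, int], list[StreamlineRecord]] = {}
    for r in records:
        out.setdefault(r.pair, []).append(r)
    return out
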