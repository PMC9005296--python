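"""Density-based screening of dinucleotide property indices.

Published dinucleotide property compilations are highly redundant: many
indices are near-linear transforms of one another, and feeding them all into
auto-cross covariance descriptors inflates the feature dimension quadratically
(109,520 dimensions for 148 indices at a maximum lag of 5). Screening keeps a
small, representative subset: each property is a point in 16-dimensional
dinucleotide-value space, DBSCAN groups the redundant ones, and per-cluster
selection rules cap how many representatives survive.

Selection rules, for a cluster of M points and a threshold N (default 5):

* 0 < M <= N      — keep the whole cluster;
* N < M <= 6N     — keep N members, uniformly at random;
* M > 6N          — recluster the cluster's points with the next, stricter
                    parameter round; if every round is exhausted and the
                    cluster still exceeds 6N, keep 2N members at random.

Noise points are special, hard-to-replace properties and are kept by default
(policy flag ``select_noise``).

DBSCAN here is the classic order-deterministic formulation: a point is a core
point when its closed eps-neighborhood holds at least minPts points; clusters
are maximal density-connected sets; border points join the first cluster that
reaches them when seeds are expanded in input order. Determinism matters
because the selection audit must be reproducible.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .property_index import PropertyTable
from .sequence_io import ConfigError

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    """eps: neighborhood radius; min_pts: core-point density threshold."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ConfigError(f"eps must be positive, got {self.eps}")
        if self.min_pts < 1:
            raise ConfigError(f"min_pts must be >= 1, got {self.min_pts}")


#: Default round schedule: four rounds of strictly decreasing eps (so each
#: round is stricter than the last) at constant density requirement.
DEFAULT_ROUNDS: tuple[DbscanParams, ...] = (
    DbscanParams(4.0, 4),
    DbscanParams(3.0, 4),
    DbscanParams(2.0, 4),
    DbscanParams(1.5, 4),
)


@dataclass(frozen=True)
class ScreeningConfig:
    rounds: tuple[DbscanParams, ...] = DEFAULT_ROUNDS
    threshold: int = 5  # the N of the selection rules
    seed: int = 0
    select_noise: bool = True

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ConfigError("at least one DBSCAN parameter round is required")
        if self.threshold <= 0:
            raise ConfigError(f"threshold N must be positive, got {self.threshold}")


@dataclass
class ClusterRecord:
    round_index: int
    params: DbscanParams
    cluster_id: int
    members: list[str]
    size: int
    rule: str  # "keep_all" | "sample_N" | "recluster" | "sample_2N" | "noise"
    selected: list[str]


@dataclass
class ScreeningResult:
    selected: list[str]
    audit: list[ClusterRecord]

    def to_json(self) -> str:
        payload = {
            "selected": self.selected,
            "audit": [
                {
                    "round": r.round_index,
                    "eps": r.params.eps,
                    "min_pts": r.params.min_pts,
                    "cluster_id": r.cluster_id,
                    "size": r.size,
                    "rule": r.rule,
                    "members": r.members,
                    "selected": r.selected,
                }
                for r in self.audit
            ],
        }
        return json.dumps(payload, indent=2)

    def write(self, audit_path: str | Path, selected_path: str | Path) -> None:
        Path(audit_path).write_text(self.to_json() + "\n")
        Path(selected_path).write_text("\n".join(self.selected) + "\n")


def _euclidean(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def run_dbscan(
    points: Sequence[Sequence[float]] | np.ndarray,
    params: DbscanParams,
    metric: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Cluster points; returns one label per point, noise labeled -1.

    ``metric`` maps the (n, d) point array to an (n, n) symmetric distance
    matrix; Euclidean by default. Core points have >= min_pts points in their
    closed eps-ball (the point itself included). Seeds expand in input order,
    so border points reachable from several clusters join the first cluster
    that reaches them.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    if pts.ndim != 2:
        raise ConfigError(f"points must be a 2-D array, got ndim={pts.ndim}")
    dist = _euclidean(pts) if metric is None else np.asarray(metric(pts), dtype=float)
    n = len(pts)
    neighbors = [np.flatnonzero(dist[i] <= params.eps) for i in range(n)]
    core = np.array([len(nb) >= params.min_pts for nb in neighbors])
    labels = np.full(n, NOISE, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cluster_id = 0
    for seed in range(n):
        if visited[seed] or not core[seed]:
            continue
        # breadth-first expansion through density-reachable points
        queue = deque([seed])
        visited[seed] = True
        labels[seed] = cluster_id
        while queue:
            p = queue.popleft()
            if not core[p]:
                continue  # border points do not propagate reachability
            for q in neighbors[p]:
                if labels[q] == NOISE:
                    labels[q] = cluster_id
                if not visited[q]:
                    visited[q] = True
                    queue.append(q)
        cluster_id += 1
    return labels


def screen_properties(
    table: PropertyTable, config: ScreeningConfig | None = None
) -> ScreeningResult:
    """Reduce a property table to a representative subset via the rules above.

    Each property is its 16-value vector. Round 1 clusters all points; any
    cluster larger than 6N is reclustered with the next round's parameters,
    recursing until the rounds run out (then 2N members are sampled). The
    selected-set *size* is a deterministic function of the cluster sizes;
    the *membership* of sampled clusters depends on the seed.
    """
    if config is None:
        config = ScreeningConfig()
    if len(table) == 0:
        raise ConfigError("property table is empty")
    rng = np.random.default_rng(config.seed)
    big_n = config.threshold
    audit: list[ClusterRecord] = []
    selected: list[str] = []

    def process(indices: np.ndarray, round_idx: int) -> None:
        params = config.rounds[round_idx]
        pts = table.values[indices]
        labels = run_dbscan(pts, params)
        noise_idx = indices[labels == NOISE]
        if len(noise_idx) > 0:
            noise_names = [table.names[i] for i in noise_idx]
            chosen = noise_names if config.select_noise else []
            audit.append(
                ClusterRecord(
                    round_idx, params, NOISE, noise_names, len(noise_names),
                    "noise", list(chosen),
                )
            )
            selected.extend(chosen)
        for cid in range(labels.max() + 1 if labels.size else 0):
            member_idx = indices[labels == cid]
            members = [table.names[i] for i in member_idx]
            m = len(member_idx)
            if m <= big_n:
                rule, chosen = "keep_all", list(members)
            elif m <= 6 * big_n:
                rule = "sample_N"
                pick = rng.choice(m, size=big_n, replace=False)
                chosen = [members[i] for i in sorted(pick)]
            elif round_idx + 1 < len(config.rounds):
                rule, chosen = "recluster", []
            else:
                rule = "sample_2N"
                pick = rng.choice(m, size=2 * big_n, replace=False)
                chosen = [members[i] for i in sorted(pick)]
            audit.append(
                ClusterRecord(round_idx, params, cid, members, m, rule, list(chosen))
            )
            selected.extend(chosen)
            if rule == "recluster":
                process(member_idx, round_idx + 1)

    process(np.arange(len(table)), 0)
    # de-duplicate defensively while preserving table order
    order = {name: i for i, name in enumerate(table.names)}
    selected_unique = sorted(dict.fromkeys(selected), key=order.__getitem__)
    return ScreeningResult(selected_unique, audit)
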