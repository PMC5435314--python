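"""Fruchterman-Reingold force-directed layout.

The classic spring-embedder places nodes in a rectangular frame by
simulating attractive forces between adjacent nodes (magnitude d²/k) and
repulsive forces between all node pairs (magnitude k²/d), where
k = C·sqrt(area/n) is the ideal edge length.  Displacements are capped by a
temperature that cools linearly to zero, and positions are clipped to the
frame after every step.  Because adjacent nodes end up near each other,
modules of a modular network appear as spatially proximate clusters — the
property quantified by :func:`layout_separation_score`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .graph import AnatomicalNetwork, Partition

__all__ = [
    "LayoutConfig",
    "LayoutResult",
    "fruchterman_reingold",
    "layout_separation_score",
]


@dataclass(frozen=True)
class LayoutConfig:
    """Tunables of the layout.

    ``width``/``height`` set the frame (area = width·height), ``C`` scales
    the ideal distance k = C·sqrt(area/n), and the initial temperature is
    width/10, decremented linearly to zero over ``iterations`` steps.
    """

    width: float = 1.0
    height: float = 1.0
    iterations: int = 500
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")


@dataclass(frozen=True)
class LayoutResult:
    """Final node coordinates, all inside the frame."""

    coordinates: dict[int, tuple[float, float]]
    config: LayoutConfig

    def positions(self, order) -> np.ndarray:
        return np.array([self.coordinates[i] for i in order])


def fruchterman_reingold(
    net: AnatomicalNetwork, config: LayoutConfig | None = None
) -> LayoutResult:
    """Deterministic (seeded) Fruchterman-Reingold placement."""
    cfg = config or LayoutConfig()
    ids = list(net.node_ids)
    n = len(ids)
    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform((0.0, 0.0), (cfg.width, cfg.height), size=(n, 2))
    if n == 1:
        return LayoutResult({ids[0]: tuple(pos[0])}, cfg)

    k = cfg.C * np.sqrt(cfg.width * cfg.height / n)
    idx = {v: i for i, v in enumerate(ids)}
    e_u, e_v = (
        np.array([[idx[u], idx[v]] for u, v in net.edges()]).T
        if net.m else (np.array([], dtype=int), np.array([], dtype=int))
    )
    t0 = cfg.width / 10.0
    eps = 1e-9

    for step in range(cfg.iterations):
        t = t0 * (1.0 - step / cfg.iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        # perturb coincident points so the direction is defined
        clash = (dist < eps) & ~np.eye(n, dtype=bool)
        if clash.any():
            pos += rng.uniform(-eps, eps, size=pos.shape) * 1e3
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        # repulsion among all pairs: k^2 / d away from the other node
        disp = (delta / dist[..., None] * (k * k / dist)[..., None]).sum(axis=1)
        # attraction along edges: d^2 / k toward the neighbour
        if net.m:
            dvec = pos[e_u] - pos[e_v]
            d = np.maximum(np.linalg.norm(dvec, axis=-1), eps)
            f = (d / k)[:, None] * dvec  # (d^2/k) * unit vector
            np.add.at(disp, e_u, -f)
            np.add.at(disp, e_v, f)
        # cap by temperature, then clip to frame
        norm = np.maximum(np.linalg.norm(disp, axis=-1), eps)
        pos += disp / norm[:, None] * np.minimum(norm, t)[:, None]
        pos[:, 0] = np.clip(pos[:, 0], 0.0, cfg.width)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, cfg.height)

    return LayoutResult({v: (float(x), float(y)) for v, (x, y) in zip(ids, pos)}, cfg)


def layout_separation_score(
    net: AnatomicalNetwork, layout: LayoutResult, partition: Partition
) -> float:
    """Mean within-module over mean between-module pairwise distance.

    A score below 1 means modules occupy segregated regions of the drawing;
    random placement scores about 1 in expectation.
    """
    partition.validate_on(net)
    if partition.n_modules < 2:
        raise ValueError("separation score needs at least two modules")
    within, between = [], []
    for u, v in combinations(net.node_ids, 2):
        d = float(
            np.hypot(
                layout.coordinates[u][0] - layout.coordinates[v][0],
                layout.coordinates[u][1] - layout.coordinates[v][1],
            )
        )
        if partition.assignment[u] == partition.assignment[v]:
            within.append(d)
        else:
            between.append(d)
    if not within:  # all modules are singletons
        raise ValueError("partition has no within-module pair")
    return float(np.mean(within) / np.mean(between))
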