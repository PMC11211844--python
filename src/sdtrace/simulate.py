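"""Forward simulation: topologies, locations, sequences, and tracked frames.

The generator mirrors the study conditions of the method's evaluation:
diffusion rate sigma = 1.5 (variants 0.5 and 3.0), displacement magnitude
r = 6.68, K = 10 target sites with alphabet {0, 1, 2} (two edit outcomes per
site), edit rate lambda = 0.006 per unit time, and an experiment horizon of
tau_end = 216 frames.  Silencing (nu = 0.001) and dropout (phi = 0.03) add
moderate missingness comparable to imaging-based lineage recorders.
Topologies are pure-birth (Yule) trees rescaled so that all leaves sit
exactly at tau_end; real lineage topologies can be supplied instead of
simulated ones wherever a tree is accepted.

All draws are deterministic per seed, and independent streams are used for
topology, angles, locations, and sequences, so e.g. requesting a different
sequence replicate does not perturb the locations.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import trees
from .sequence_pmm import CharacterMatrix, PMMParams, SiteAlphabet
from .spatial_sd import LeafLocations, SDParams
from .trees import MISSING, LineageTree

__all__ = [
    "SimConfig",
    "PRESETS",
    "simulate_topology",
    "simulate_locations",
    "simulate_sequences",
    "simulate_frames",
    "make_fixture",
]


@dataclass
class SimConfig:
    """One simulated dataset's generating conditions."""

    n_leaves: int = 30
    tau_end: float = 216.0
    sigma: float = 1.5
    r: float = 6.68
    n_sites: int = 10
    m_states: int = 2
    lam: float = 0.006
    nu: float = 0.001
    phi: float = 0.03
    #: imaging-frame resolution of division times; branch lengths are
    #: integer multiples of this (>= 1 frame), as in time-lapse recorders
    time_resolution: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")

    def sd_params(self) -> SDParams:
        return SDParams(sigma=self.sigma, r=self.r)

    def pmm_params(self) -> PMMParams:
        return PMMParams(lam=self.lam, nu=self.nu, phi=self.phi)

    def alphabets(self) -> list[SiteAlphabet]:
        return [SiteAlphabet(n_states=self.m_states)
                for _ in range(self.n_sites)]


#: named study conditions; "default" is the headline condition, the sigma
#: variants probe low/high motility with everything else unchanged.
PRESETS: dict[str, dict] = {
    "default": {},
    "sigma-low": {"sigma": 0.5},
    "sigma-high": {"sigma": 3.0},
}


def _stream(seed: int, label: str) -> np.random.Generator:
    # independent, reproducible stream per purpose (crc32 is stable across
    # processes, unlike str.__hash__)
    key = zlib.crc32(label.encode()) % 2**31
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    )


def simulate_topology(
    n_leaves: int,
    tau_end: float,
    seed: int | np.random.Generator = 0,
    time_resolution: float | None = None,
) -> LineageTree:
    """Pure-birth tree with a unifurcating root, rescaled to ``tau_end``.

    A single progenitor lineage divides at unit rate per extant lineage
    until ``n_leaves`` lineages exist; one further waiting time sets the
    horizon, and all times are rescaled so leaves sit exactly at
    ``tau_end``.  Internal nodes get labels ``i0, i1, ...`` (preorder) and
    leaves ``c01, c02, ...`` so that edges keep their identity through
    Newick round trips.

    With ``time_resolution`` set, division times are snapped to that grid
    (consecutive divisions at least one grid step apart, and at least one
    step before ``tau_end``), emulating time-lapse recorders where branch
    lengths are known to whole-frame resolution; a continuous-time Yule
    tree can otherwise place two divisions arbitrarily close together,
    which no imaging experiment resolves.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else _stream(seed, "topology")
    tree = LineageTree()
    root = tree._add_node(None, None)
    first = tree._add_node(root, None)
    times = {root: 0.0}
    active = [first]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        v = active.pop(int(rng.integers(len(active))))
        times[v] = t
        active.append(tree._add_node(v, None))
        active.append(tree._add_node(v, None))
    t += rng.exponential(1.0 / len(active))
    scale = tau_end / t
    for v in active:
        times[v] = t
    times = {v: tv * scale for v, tv in times.items()}
    if time_resolution is not None:
        q = float(time_resolution)
        # height: longest chain of divisions at or below each internal node
        height = {}
        for v in reversed(tree.preorder()):
            kids = [c for c in tree.children[v] if tree.children[c]]
            height[v] = 1 + max((height[c] for c in kids), default=0)
        if height[tree.root] * q >= tau_end:
            raise ValueError(
                f"time_resolution {q} too coarse for a division chain of "
                f"{height[tree.root]} within tau_end {tau_end}")
        for v in tree.preorder():
            if v == tree.root:
                continue
            if not tree.children[v]:
                times[v] = tau_end
            else:
                snapped = round(times[v] / q) * q
                lo = times[tree.parent[v]] + q
                hi = tau_end - q * height[v]
                times[v] = float(min(max(snapped, lo), hi))
    for v in tree.preorder():
        if v != tree.root:
            tree.branch_length[v] = times[v] - times[tree.parent[v]]
    width = len(str(n_leaves))
    leaf_i = internal_i = 0
    for v in tree.preorder():
        if tree.is_leaf(v):
            leaf_i += 1
            tree.leaf_name[v] = f"c{leaf_i:0{width}d}"
        elif v != tree.root:
            tree.label[v] = f"i{internal_i}"
            internal_i += 1
    tree.label[tree.root] = "root"
    tree.validate()
    return tree


def simulate_locations(
    tree: LineageTree,
    params: SDParams,
    seed: int | np.random.Generator = 0,
    return_internal: bool = False,
):
    """Leaf coordinates under the symmetric-displacement process.

    The root sits at ``(x0, y0)``; at each division the daughters start at
    the parent's position plus/minus ``r (cos theta_u, sin theta_u)``
    (first-listed child gets +) and then diffuse with per-axis variance
    ``sigma^2 * branch time``.  The edge below the unifurcating root
    diffuses only.  Division angles missing from ``params.theta`` are drawn
    uniformly on [0, 2 pi) and reported back.

    Returns ``LeafLocations``; with ``return_internal=True`` returns
    ``(locations, positions, params_used)`` where ``positions`` maps every
    node id to its (x, y).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else _stream(seed, "locations")
    theta = dict(params.theta)
    for u in tree.bifurcations():
        if u not in theta:
            theta[u] = float(rng.uniform(0.0, 2.0 * np.pi))
    pos = {tree.root: (params.x0, params.y0)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        u = tree.parent[v]
        px, py = pos[u]
        if len(tree.children[u]) == 2 and params.r > 0:
            s = 1.0 if tree.children[u][0] == v else -1.0
            px += s * params.r * math.cos(theta[u])
            py += s * params.r * math.sin(theta[u])
        sd = params.sigma * math.sqrt(tree.branch_length[v])
        pos[v] = (px + rng.normal(0.0, sd), py + rng.normal(0.0, sd))
    leaves = tree.leaf_order()
    loc = LeafLocations(
        names=[tree.leaf_name[v] for v in leaves],
        x=np.array([pos[v][0] for v in leaves]),
        y=np.array([pos[v][1] for v in leaves]),
    )
    if return_internal:
        used = SDParams(sigma=params.sigma, r=params.r, theta=theta,
                        x0=params.x0, y0=params.y0)
        return loc, pos, used
    return loc


def simulate_sequences(
    tree: LineageTree,
    pmm: PMMParams,
    alphabets: list[SiteAlphabet],
    seed: int | np.random.Generator = 0,
) -> CharacterMatrix:
    """Character matrix evolved forward under the editing chain.

    The progenitor is unedited at all sites; hidden states evolve edge by
    edge with the chain's closed-form transition probabilities, and leaf
    observations pass through dropout (an unsilenced state is hidden with
    probability phi; a silent state always reads as missing).
    """
    pmm.validate()
    rng = seed if isinstance(seed, np.random.Generator) \
        else _stream(seed, "sequences")
    K = len(alphabets)
    silent_code = -1
    hidden = {tree.root: np.zeros(K, dtype=np.int64)}
    lam, nu = pmm.lam, pmm.nu
    for v in tree.preorder():
        if v == tree.root:
            continue
        d = tree.branch_length[v]
        e1 = math.exp(-(lam + nu) * d)
        en = math.exp(-nu * d)
        parent_state = hidden[tree.parent[v]]
        state = parent_state.copy()
        u01 = rng.random(K)
        for k in range(K):
            s = parent_state[k]
            if s == silent_code:
                continue
            if s == 0:
                # order: stay 0 | edit a | silence
                if u01[k] < e1:
                    continue
                p = e1
                edited = False
                for a, pa in enumerate(alphabets[k].priors, start=1):
                    p += pa * (en - e1)
                    if u01[k] < p:
                        state[k] = a
                        edited = True
                        break
                if not edited:
                    state[k] = silent_code
            else:
                if u01[k] >= en:
                    state[k] = silent_code
        hidden[v] = state
    leaves = tree.leaf_order()
    data = np.empty((len(leaves), K), dtype=np.int64)
    for i, w in enumerate(leaves):
        h = hidden[w]
        drop = rng.random(K) < pmm.phi
        for k in range(K):
            if h[k] == silent_code or drop[k]:
                data[i, k] = MISSING
            else:
                data[i, k] = h[k]
    return CharacterMatrix(
        cells=[tree.leaf_name[v] for v in leaves],
        data=data,
        alphabets=alphabets,
    )


def simulate_frames(
    tree: LineageTree,
    params: SDParams,
    frame_interval: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Frame-by-frame tracked positions along every lineage.

    Positions are Brownian-sampled on the frame grid; at each division the
    daughters start at the parent's final position plus/minus the division
    displacement.  Returns a table with columns (frame, cell, parent, x, y)
    where ``cell`` names the edge's child node and ``parent`` its parent
    cell ("" for the progenitor), providing the lineage links used by the
    division-angle analysis.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else _stream(seed, "frames")
    theta = dict(params.theta)
    for u in tree.bifurcations():
        if u not in theta:
            theta[u] = float(rng.uniform(0.0, 2.0 * np.pi))
    depth = trees.node_depths(tree)
    rows = []

    def name_of(v):
        return tree.leaf_name.get(v) or tree.label.get(v) or f"n{v}"

    def walk(v, start_pos):
        t0, t1 = depth[tree.parent[v]], depth[v]
        f0 = int(math.floor(t0 / frame_interval)) + 1
        if tree.parent[v] == tree.root:
            f0 = 0  # progenitor is on record from frame 0
        f1 = int(math.floor(t1 / frame_interval + 1e-9))
        x, y = start_pos
        t_prev = t0
        pname = "" if tree.parent[v] == tree.root else name_of(tree.parent[v])
        for f in range(f0, f1 + 1):
            tf = f * frame_interval
            sd = params.sigma * math.sqrt(max(tf - t_prev, 0.0))
            x += rng.normal(0.0, sd)
            y += rng.normal(0.0, sd)
            t_prev = tf
            rows.append((f, name_of(v), pname, x, y))
        sd = params.sigma * math.sqrt(max(t1 - t_prev, 0.0))
        x += rng.normal(0.0, sd)
        y += rng.normal(0.0, sd)
        if len(tree.children[v]) == 2:
            dx = params.r * math.cos(theta[v])
            dy = params.r * math.sin(theta[v])
            c1, c2 = tree.children[v]
            walk(c1, (x + dx, y + dy))
            walk(c2, (x - dx, y - dy))

    walk(tree.children[tree.root][0], (params.x0, params.y0))
    return pd.DataFrame(rows, columns=["frame", "cell", "parent", "x", "y"])


def make_fixture(
    preset: str,
    seed: int,
    out_dir,
    overrides: dict | None = None,
    write_frames: bool = False,
) -> dict:
    """Write a complete on-disk dataset for a named study condition.

    Produces ``tree.nwk``, ``matrix.csv``, ``locations.csv`` and
    ``truth.json`` (generating parameters, division angles keyed by
    internal-node label, and node times) under ``out_dir``; optionally a
    ``frames.csv`` track table.  Returns the path map.
    """
    if preset not in PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides or {})
    cfg = SimConfig(seed=seed, **kwargs)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = simulate_topology(cfg.n_leaves, cfg.tau_end,
                             _stream(seed, "topology"),
                             time_resolution=cfg.time_resolution)
    loc, _, sd_used = simulate_locations(
        tree, cfg.sd_params(), _stream(seed, "locations"),
        return_internal=True)
    mat = simulate_sequences(tree, cfg.pmm_params(), cfg.alphabets(),
                             _stream(seed, "sequences"))

    paths = {
        "tree": out / "tree.nwk",
        "matrix": out / "matrix.csv",
        "locations": out / "locations.csv",
        "truth": out / "truth.json",
    }
    paths["tree"].write_text(trees.write_newick(tree) + "\n")
    trees.write_character_matrix(mat, paths["matrix"])
    trees.write_locations(loc, paths["locations"])

    depth = trees.node_depths(tree)
    label_of = {v: tree.leaf_name.get(v) or tree.label.get(v, str(v))
                for v in tree.preorder()}
    truth = {
        "preset": preset,
        "seed": seed,
        "config": asdict(cfg),
        "theta": {label_of[u]: sd_used.theta[u]
                  for u in tree.bifurcations()},
        "node_times": {label_of[v]: depth[v] for v in tree.preorder()},
        "newick": trees.write_newick(tree),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)

    if write_frames:
        frames = simulate_frames(tree, sd_used, 1.0, _stream(seed, "frames"))
        paths["frames"] = out / "frames.csv"
        frames.to_csv(paths["frames"], index=False)
    return {k: str(v) for k, v in paths.items()}
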