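"""Time-scaling cladograms from fossil occurrence dates.

Fossil cladograms carry no branch durations.  Each internal node is first
dated by its oldest descendant taxon (first-appearance dates, FADs), which
necessarily produces zero-duration edges along the "oldest" path through
every node.  Three standard repairs are provided:

``equal_oldest``
    Borrow time from the nearest ancestral edge with positive duration and
    split the borrowed span evenly along the chain of zero edges plus the
    donor, processing edges root-to-tip, left-to-right.  The root stem
    length (e.g. 5 or 10 Ma) participates as the ultimate donor, so its
    choice propagates into the tree.  Tip dates are unchanged.
``mbl``
    Minimum branch length: every edge is forced to at least ``min_length``
    Ma by pushing internal nodes rootward; tip dates are unchanged.
``add``
    A fixed increment is added to every edge of the oldest-descendant
    dating, working root-to-tip, so tip dates shift younger/older as the
    increments accumulate.

Tip dates are taken from the FAD by default; drawing each date uniformly
between FAD and LAD (for sensitivity replicates) is seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import Phylogeny, PhylogenyError

__all__ = ["TaxonAges", "TimescaleConfig", "timescale", "read_ages_csv"]


@dataclass
class TaxonAges:
    """First/last appearance dates per taxon, Ma before present."""

    fad: dict[str, float]
    lad: dict[str, float]

    def __post_init__(self) -> None:
        for taxon, f in self.fad.items():
            l = self.lad.get(taxon, f)
            if l > f:
                raise ValueError(f"{taxon}: LAD {l} older than FAD {f}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonAges":
        if df["taxon"].duplicated().any():
            raise ValueError("duplicate taxa in age table")
        lad = df["lad"] if "lad" in df else df["fad"]
        return cls(
            fad=dict(zip(df["taxon"], df["fad"].astype(float))),
            lad=dict(zip(df["taxon"], lad.astype(float))),
        )


def read_ages_csv(path) -> TaxonAges:
    return TaxonAges.from_frame(pd.read_csv(path))


@dataclass
class TimescaleConfig:
    method: str = "equal_oldest"  # equal_oldest | mbl | add
    root_length: float = 5.0      # stem above the root, Ma
    min_length: float = 2.0       # mbl floor, Ma
    increment: float = 1.0        # add increment, Ma
    tip_date_policy: str = "fad"  # fad | uniform
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in {"equal_oldest", "mbl", "add"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.root_length <= 0 or self.min_length <= 0 or self.increment <= 0:
            raise ValueError("root_length, min_length and increment must be > 0")
        if self.tip_date_policy not in {"fad", "uniform"}:
            raise ValueError(f"unknown tip date policy {self.tip_date_policy!r}")


def _tip_dates(tree: Phylogeny, ages: TaxonAges, cfg: TimescaleConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    dates = np.zeros(tree.n_nodes)
    for i in tree.tips:
        lab = tree.tip_labels[i]
        if lab not in ages.fad:
            raise PhylogenyError(f"no occurrence date for taxon {lab!r}")
        if cfg.tip_date_policy == "fad":
            dates[i] = ages.fad[lab]
        else:
            lo, hi = ages.lad[lab], ages.fad[lab]
            dates[i] = rng.uniform(lo, hi) if hi > lo else hi
    return dates


def _basic_node_ages(tree: Phylogeny, tip_date: np.ndarray) -> np.ndarray:
    """Oldest-descendant dating: age(node) = max over descendant tip dates."""
    age = tip_date.copy()
    for i in tree.postorder():
        kids = tree.children(i)
        if kids:
            age[i] = max(age[c] for c in kids)
    return age


def timescale(tree: Phylogeny, ages: TaxonAges, cfg: TimescaleConfig | None = None) -> Phylogeny:
    """Convert a cladogram plus occurrence dates into a time-scaled tree.

    Returns a new :class:`Phylogeny` with strictly positive edge durations,
    ``root_age`` set, and the configured root stem length attached.
    """
    cfg = cfg or TimescaleConfig()
    tip_date = _tip_dates(tree, ages, cfg)
    age = _basic_node_ages(tree, tip_date)

    if cfg.method == "equal_oldest":
        age = _share_equal(tree, age, cfg.root_length)
        root_stem = cfg.root_length - (age[0] - _basic_node_ages(tree, tip_date)[0])
        root_age = age[0]
    elif cfg.method == "mbl":
        new_age = tip_date.copy()
        for i in tree.postorder():
            kids = tree.children(i)
            if kids:
                new_age[i] = max(max(new_age[c] for c in kids) + cfg.min_length, age[i])
        age = new_age
        root_stem = cfg.root_length
        root_age = age[0]
    else:  # add
        new_age = np.zeros_like(age)
        new_age[0] = age[0]
        for i in range(1, tree.n_nodes):
            basic_edge = age[tree.parent[i]] - age[i]
            new_age[i] = new_age[tree.parent[i]] - (basic_edge + cfg.increment)
        age = new_age
        root_stem = cfg.root_length
        root_age = age[0]

    out = tree.copy()
    for i in range(1, tree.n_nodes):
        d = age[tree.parent[i]] - age[i]
        if d < 0:
            raise PhylogenyError(f"negative duration on edge above node {i}")
        out.edge_length[i] = d
    out.root_age = float(root_age)
    out.root_length = float(max(root_stem, 0.0))
    if np.any(out.edge_length[1:] <= 0):
        bad = int(np.where(out.edge_length[1:] <= 0)[0][0]) + 1
        raise PhylogenyError(
            f"zero-duration edge above node {bad} after {cfg.method} scaling"
        )
    return out


def _share_equal(tree: Phylogeny, age: np.ndarray, root_length: float) -> np.ndarray:
    """Zero-edge removal by equal sharing from the nearest positive donor.

    The root stem (``root_length`` Ma above the basic root age) is the
    ultimate donor.  Edges are processed in preorder (root-to-tip,
    left-to-right); each zero edge pulls in the chain of consecutive zero
    edges up to the nearest ancestor edge with positive duration and the
    total span is split evenly across donor + chain by re-spacing the
    intermediate node ages.  Because the chain edges are consecutive
    zeros, re-spacing only raises intermediate nodes, so no other edge
    can go negative and tip dates never change.
    """
    age = age.copy()
    root_top = age[0] + root_length  # age of the top of the root stem

    def edge_dur(i: int) -> float:
        return age[tree.parent[i]] - age[i]

    preorder = [i for i in range(tree.n_nodes)]
    for i in preorder:
        if i == 0 or edge_dur(i) > 0:
            continue
        # climb to nearest ancestor edge with positive duration
        chain = [i]
        j = int(tree.parent[i])
        while j != 0 and edge_dur(j) <= 0:
            chain.append(j)
            j = int(tree.parent[j])
        if j == 0:
            top_age = root_top          # donor is the root stem
            path = chain + [0]
        else:
            top_age = age[int(tree.parent[j])]
            path = chain + [j]
        bottom_age = age[i]
        k = len(path)                   # donor + zero chain
        span = top_age - bottom_age
        if span <= 0:
            raise PhylogenyError(
                "equal sharing failed: no ancestral time available "
                f"above node {i} (increase the root stem length)"
            )
        step = span / k
        # path[0] is the focal node i, path[-1] the donor's child node
        for rank, node in enumerate(path):
            age[node] = bottom_age + rank * step
    return age
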