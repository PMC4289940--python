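"""Study-shaped synthetic data with known ground truth.

Generates the inputs every other module consumes — a non-ultrametric
time-scaled tree of fossil taxa spanning roughly 170-66 Ma, a taxon age
table, log10 limb-length traits, and nested clade labels (an inner
"Aves"-like clade inside an outer "Paraves"-like focal clade whose stem
branch is short, 0.31 Ma by default) — together with a truth record of
every generating parameter, so estimator recovery is checkable end to
end without any external download.

Three presets mirror the real data shapes: 125 taxa with one body-size
trait, 76 taxa with one forelimb trait, and 71 taxa with both.  Traits
can be simulated under Brownian motion with planted rate shifts, under a
two-optimum OU regime model, or as a group-wise allometric regression
with phylogenetic residuals at a chosen lambda.

Background trait scales are chosen so simulated log10 femur lengths span
roughly 1.3-3.0 (20 mm to 1 m), the realistic range for coelurosaurian
theropods, which keeps optimizer behaviour representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bm import build_scaling
from .ou import paint_regimes, simulate_ou
from .simulate import simulate_bm
from .timescale import TaxonAges
from .tree import Phylogeny

__all__ = ["SyntheticScenario", "make_scenario", "PRESETS"]

PRESETS = {
    # n_tips, trait columns
    "study71": (71, ("femur_mm", "forelimb_mm")),
    "study76": (76, ("forelimb_mm",)),
    "study125": (125, ("femur_mm",)),
}

ROOT_AGE = 170.0        # Ma; root of the coelurosaur-scale tree
YOUNGEST = 66.0         # Ma; end-Cretaceous floor for fossil tips
FOCAL_STEM = 0.31       # Ma; short stem of the focal (Paraves-like) clade
BG_SIGMA2 = 4e-4        # (log10 mm)^2/Ma; log10 femur sd ~0.2 over ~100 Ma
ROOT_LOG10_MM = 2.2     # ~160 mm femur at the root


@dataclass
class SyntheticScenario:
    """One generated dataset plus its complete ground truth."""

    preset: str
    seed: int
    trait_model: str
    tree: Phylogeny
    ages: TaxonAges
    traits: pd.DataFrame          # log10 mm, taxon-indexed
    clade_table: pd.DataFrame     # taxon, clade (innermost membership)
    groups: pd.Series             # taxon -> Aves | Paraves | other
    focal: int                    # node id of the outer (Paraves-like) clade
    inner: int                    # node id of the nested (Aves-like) clade
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        pd.DataFrame(
            {"taxon": list(self.ages.fad), "fad": list(self.ages.fad.values()),
             "lad": [self.ages.lad[t] for t in self.ages.fad]}
        ).to_csv(out / "ages.csv", index=False)
        mm = 10.0 ** self.traits
        mm.rename_axis("taxon").to_csv(out / "traits.csv")
        self.clade_table.to_csv(out / "clades.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _random_topology(n: int, rng: np.random.Generator) -> Phylogeny:
    """Random binary cladogram (no branch lengths) by sequential joins."""
    parent = {0: -1}
    children: dict[int, list[int]] = {0: []}
    next_id = 1
    leaves = [0]
    while len(leaves) < n:
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            parent[next_id] = leaf
            children.setdefault(leaf, []).append(next_id)
            children[next_id] = []
            leaves.append(next_id)
            next_id += 1
    order, stack = [], [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children.get(v, [])))
    remap = {old: new for new, old in enumerate(order)}
    n_nodes = len(order)
    p = np.empty(n_nodes, dtype=np.int64)
    labels = {}
    t = 0
    for old in order:
        p[remap[old]] = -1 if parent[old] == -1 else remap[parent[old]]
    for old in order:
        if not children.get(old):
            t += 1
            labels[remap[old]] = f"taxon_{t:03d}"
    return Phylogeny(p, np.full(n_nodes, np.nan), labels)


def _build_tree(n: int, rng: np.random.Generator) -> tuple[Phylogeny, TaxonAges]:
    """Random cladogram + fossil dates, scaled by the package's own
    oldest-descendant/equal-sharing method.

    First-appearance dates are drawn uniformly over the Late Jurassic to
    end-Cretaceous span and the cladogram is dated exactly the way the
    real composite trees were, so every internal node has a descendant
    tip anchored near its age and internal edges are short relative to
    terminal ones — the structure that controls how detectable a shift
    on a short internal stem is.
    """
    from .timescale import TimescaleConfig, timescale

    topo = _random_topology(n, rng)
    fad = {lab: float(rng.uniform(YOUNGEST, ROOT_AGE - 2.0))
           for lab in topo.tip_label_list}
    lad = {lab: max(f - float(rng.uniform(0.0, 5.0)), 0.8 * YOUNGEST)
           for lab, f in fad.items()}
    ages = TaxonAges(fad=fad, lad=lad)
    tree = timescale(topo, ages, TimescaleConfig(method="equal_oldest",
                                                 root_length=5.0))
    return tree, ages


def _pick_clades(tree: Phylogeny, rng: np.random.Generator,
                 focal_frac: float = 0.35) -> tuple[int, int]:
    """Focal clade ~focal_frac of tips, inner clade ~half the focal tips.

    The focal node is kept at least two edges from the root: a shift on a
    root-child edge is confounded with the free root state and would not
    be a meaningful stand-in for the study's focal stem branch.
    """
    n = tree.n_tips
    target = max(int(round(focal_frac * n)), 6)
    internal = [v for v in range(1, tree.n_nodes)
                if tree.children(v) and tree.depth_in_edges(v) >= 2]
    if not internal:
        internal = [v for v in range(1, tree.n_nodes) if tree.children(v)]
    focal = min(internal, key=lambda v: abs(len(tree.subtree_tips(v)) - target))
    f_tips = len(tree.subtree_tips(focal))
    inner_cands = [v for v in tree.subtree_nodes(focal)
                   if v != focal and tree.children(v)]
    inner = min(inner_cands,
                key=lambda v: abs(len(tree.subtree_tips(v)) - f_tips // 2))
    return int(focal), int(inner)


def make_scenario(
    preset: str = "study71",
    seed: int = 0,
    trait_model: str = "rate_shift",
    n_tips: int | None = None,
    focal_stem: float = FOCAL_STEM,
    shift_multiplier: float = 166.0,
    clade_multiplier: float = 8.5,
    ou_params: dict | None = None,
    allometry: dict | None = None,
) -> SyntheticScenario:
    """Generate a study-shaped dataset with recorded ground truth.

    ``trait_model`` selects how traits are simulated:

    * ``"rate_shift"`` — BM with a planted branch shift on the focal stem
      (``shift_multiplier``) and a clade shift (``clade_multiplier``) on a
      clade nested inside the focal clade;
    * ``"constant"`` — homogeneous BM (the null);
    * ``"ou"`` — two-regime OU with distinct optima for the focal clade
      (defaults emulate a miniaturization: background optimum 2.17,
      focal optimum 1.76 log10 mm);
    * ``"allometry"`` — group-wise linear allometry of the second trait
      on the first with BM residuals at a stated lambda (requires a
      two-trait preset).
    """
    if preset == "custom":
        if n_tips is None:
            raise ValueError("custom preset requires n_tips")
        cols = ("femur_mm", "forelimb_mm")
    else:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        n_preset, cols = PRESETS[preset]
        n_tips = n_tips or n_preset
    rng = np.random.default_rng(seed)
    tree, ages = _build_tree(n_tips, rng)
    focal, inner = _pick_clades(tree, rng)
    # shorten the focal stem by raising the focal node toward its parent,
    # compensating on its child edges so every tip date stays put
    spare = tree.edge_length[focal] - focal_stem
    kids = tree.children(focal)
    if spare > 0 or all(tree.edge_length[c] + spare > 0 for c in kids):
        tree.edge_length[focal] = focal_stem
        for c in kids:
            tree.edge_length[c] += spare
    else:
        tree = tree.set_edge_length(focal, focal_stem)
    tree.register_clade("Paraves", focal)
    tree.register_clade("Aves", inner)

    labels = tree.tip_label_list
    aves_taxa = {tree.tip_labels[i] for i in tree.subtree_tips(inner)}
    paraves_taxa = {tree.tip_labels[i] for i in tree.subtree_tips(focal)}
    groups = pd.Series(
        ["Aves" if t in aves_taxa else "Paraves" if t in paraves_taxa else "other"
         for t in labels],
        index=pd.Index(labels, name="taxon"),
    )

    m = len(cols)
    truth: dict = {
        "preset": preset, "seed": seed, "trait_model": trait_model,
        "n_tips": n_tips, "focal_node": focal, "inner_node": inner,
        "focal_stem_ma": focal_stem, "root_state_log10mm": ROOT_LOG10_MM,
        "background_sigma2": BG_SIGMA2,
    }

    if trait_model in {"rate_shift", "constant"}:
        R = BG_SIGMA2 * (np.full((m, m), 0.8) + 0.2 * np.eye(m))
        shifts = []
        if trait_model == "rate_shift":
            shifts = [(focal, "branch", shift_multiplier), (inner, "clade", clade_multiplier)]
        scaling = build_scaling(tree, shifts) if shifts else None
        Y = simulate_bm(tree, R, scaling, seed=int(rng.integers(2**31 - 1)),
                        root_state=np.full(m, ROOT_LOG10_MM))
        truth.update(
            {"rate_matrix": R.tolist(),
             "shifts": [{"node": int(nd), "type": k, "rate": float(r)}
                        for nd, k, r in shifts]}
        )
    elif trait_model == "ou":
        p = {"alpha": [0.002, 0.05], "sigma2": [BG_SIGMA2, BG_SIGMA2 / 4],
             "theta": [2.17, 1.76]}
        p.update(ou_params or {})
        painting = paint_regimes(tree, {"Paraves": focal}, stem_inclusive=False)
        y = simulate_ou(tree, painting, p["alpha"], p["sigma2"], p["theta"],
                        seed=int(rng.integers(2**31 - 1)))
        Y = np.column_stack([y] * m) if m > 1 else y[:, None]
        truth.update({"ou": p, "regimes": painting.labels})
    elif trait_model == "allometry":
        if m != 2:
            raise ValueError("allometry needs a two-trait preset")
        a = {"slopes": {"Aves": 1.1, "Paraves": 0.67, "other": 1.0},
             "intercepts": {"Aves": 0.4, "Paraves": 0.63, "other": -0.4},
             "lambda": 0.9, "resid_sigma2": BG_SIGMA2 / 8}
        a.update(allometry or {})
        x = simulate_bm(tree, BG_SIGMA2, seed=int(rng.integers(2**31 - 1)),
                        root_state=[ROOT_LOG10_MM])[:, 0]
        slopes = groups.map(a["slopes"]).to_numpy(float)
        inters = groups.map(a["intercepts"]).to_numpy(float)
        if a["resid_sigma2"] > 0:
            eps_phylo = simulate_bm(tree, a["resid_sigma2"],
                                    seed=int(rng.integers(2**31 - 1)))[:, 0]
            depth = tree.node_depths()[tree.tips]
            eps_ind = rng.normal(0.0, np.sqrt(a["resid_sigma2"] * depth *
                                              (1 - a["lambda"])))
            eps = np.sqrt(a["lambda"]) * eps_phylo + eps_ind
        else:
            eps = np.zeros_like(x)
        y = inters + slopes * x + eps
        Y = np.column_stack([x, y])
        truth.update({"allometry": a})
    else:
        raise ValueError(f"unknown trait_model {trait_model!r}")

    traits = pd.DataFrame(Y, index=pd.Index(labels, name="taxon"), columns=list(cols))
    clade_table = pd.DataFrame({"taxon": labels, "clade": groups.to_numpy()})
    return SyntheticScenario(
        preset=preset, seed=seed, trait_model=trait_model, tree=tree,
        ages=ages, traits=traits, clade_table=clade_table, groups=groups,
        focal=focal, inner=inner, truth=truth,
    )
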