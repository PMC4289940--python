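"""Whole-study orchestration from a single configuration mapping.

``run_all`` executes the stages in dependency order — inputs (files or a
synthetic scenario), time-scaling, threshold calibration, rate-shift
search, OU model comparison, trend test, PGLS ANCOVA, simulation studies
— writing one JSON report per stage plus a consolidated summary.  A
stage failure is recorded and its dependents are skipped; every numeric
in the summary is copied from a stage report, never recomputed.  All
randomness derives from the single ``seed`` entry.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bm, medusa, ou, pgls, simulate, synthetic
from .timescale import TimescaleConfig, read_ages_csv
from .timescale import timescale as _timescale
from .tree import PhylogenyError, read_newick
from .trend import fit_trend

log = logging.getLogger("paleorates")

__all__ = ["run_all", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "paleorates_out",
    "scenario": {"preset": "study71", "trait_model": "rate_shift"},
    "inputs": None,
    "timescale": {"enabled": False, "method": "equal_oldest", "root_length": 5.0},
    "calibrate": {"enabled": False, "n_sims": 500, "q": 0.95},
    "medusa": {"enabled": True, "max_shifts": 5, "min_clade": 5, "threshold": 9.22},
    "ou": {"enabled": True, "trait": None, "models": list(ou.MODELS),
           "clades": ["Paraves", "Aves"]},
    "trend": {"enabled": True, "trait": None, "clade": "Paraves"},
    "pgls": {"enabled": True, "variants": ["three_level", "paraves_only", "aves_only"]},
    "simulations": {
        "bias": {"enabled": False, "n": 200},
        "power": {"enabled": False, "n": 100, "multipliers": [10, 50, 100, 500, 1000]},
        "sweep": {"enabled": False},
    },
}


def _merge(base: dict, over: dict | None) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _load_inputs(cfg: dict, rng: np.random.Generator):
    """Returns (tree, traits frame (log10), groups Series, ages or None, truth)."""
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        tree = read_newick(Path(paths["tree"]).read_text())
        traits = bm.read_traits_csv(paths["traits"], log10=not paths.get("no_log", False))
        ages = read_ages_csv(paths["ages"]) if paths.get("ages") else None
        groups = None
        if paths.get("clades"):
            table = pd.read_csv(paths["clades"])
            groups = table.set_index("taxon")["clade"]
            for clade in [c for c in groups.unique() if c != "other"]:
                members = list(table.loc[table["clade"] == clade, "taxon"])
                inside = [t for t in members if t in set(tree.tip_label_list)]
                if len(inside) >= 2 and clade not in tree.clades:
                    tree.register_clade(clade, tree.mrca(inside))
        return tree, traits, groups, ages, {}
    sc_cfg = dict(cfg.get("scenario") or {"preset": "study71"})
    sc_cfg.setdefault("seed", int(rng.integers(2**31 - 1)))
    scenario = synthetic.make_scenario(**sc_cfg)
    return scenario.tree, scenario.traits, scenario.groups, scenario.ages, scenario.truth


def run_all(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run every enabled stage; returns the consolidated summary dict."""
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(int(cfg["seed"]))
    summary: dict = {"seed": int(cfg["seed"]), "stages": {}}
    failed: set[str] = set()

    def stage(name: str, needs: tuple[str, ...] = ()):
        def deco(fn):
            skipped = [d for d in needs if d in failed]
            t0 = time.perf_counter()
            if skipped:
                summary["stages"][name] = {"status": "skipped", "needs": skipped}
                failed.add(name)
                log.warning("stage %s skipped (needs %s)", name, skipped)
                return None
            try:
                out = fn()
            except Exception as exc:  # isolate stage failures
                summary["stages"][name] = {"status": "failed", "error": str(exc)}
                failed.add(name)
                log.error("stage %s failed: %s", name, exc)
                return None
            dt = time.perf_counter() - t0
            _dump(out, outdir / f"{name}.json")
            summary["stages"][name] = {"status": "ok", "seconds": round(dt, 3),
                                       "report": f"{name}.json"}
            log.info("stage %s done in %.2fs", name, dt)
            return out

        return deco

    state: dict = {}

    @stage("inputs")
    def _inputs():
        tree, traits, groups, ages, truth = _load_inputs(cfg, rng)
        state.update(tree=tree, traits=traits, groups=groups, ages=ages)
        return {"n_tips": tree.n_tips, "traits": list(traits.columns),
                "clades": {k: int(v) for k, v in tree.clades.items()},
                "truth": truth}

    @stage("timescale", needs=("inputs",))
    def _timescale():
        if not cfg["timescale"]["enabled"]:
            if not state["tree"].has_lengths:
                raise PhylogenyError("tree has no branch lengths and time-scaling is disabled")
            return {"skipped": True}
        tcfg = {k: v for k, v in cfg["timescale"].items() if k != "enabled"}
        tcfg.setdefault("seed", int(rng.integers(2**31 - 1)))
        scaled = _timescale(state["tree"], state["ages"], TimescaleConfig(**tcfg))
        state["tree"] = scaled
        (outdir / "scaled_tree.nwk").write_text(scaled.to_newick() + "\n")
        return {"method": tcfg["method"], "root_age": scaled.root_age,
                "min_edge": float(np.nanmin(scaled.edge_length[1:]))}

    @stage("calibrate", needs=("timescale",))
    def _calibrate():
        c = cfg["calibrate"]
        if not c["enabled"]:
            return {"skipped": True, "threshold": cfg["medusa"]["threshold"]}
        m = state["traits"].shape[1]
        thr = medusa.calibrate_threshold(
            state["tree"], n_sims=int(c["n_sims"]), q=float(c["q"]),
            seed=int(rng.integers(2**31 - 1)), m=m,
            min_clade=int(cfg["medusa"]["min_clade"]),
        )
        state["threshold"] = thr
        return {"threshold": thr, "n_sims": c["n_sims"], "q": c["q"]}

    @stage("medusa", needs=("calibrate",))
    def _medusa():
        if not cfg["medusa"]["enabled"]:
            return {"skipped": True}
        thr = state.get("threshold", cfg["medusa"]["threshold"])
        model = medusa.tm2_search(
            state["tree"], state["traits"],
            max_shifts=int(cfg["medusa"]["max_shifts"]),
            min_clade=int(cfg["medusa"]["min_clade"]),
            threshold=float(thr),
        )
        state["medusa"] = model
        return model.to_dict()

    @stage("ou", needs=("timescale",))
    def _ou():
        c = cfg["ou"]
        if not c["enabled"]:
            return {"skipped": True}
        tree = state["tree"]
        trait_col = c["trait"] or state["traits"].columns[0]
        y = state["traits"][[trait_col]]
        out = {}
        for clade in c["clades"]:
            if clade not in tree.clades:
                continue
            painting = ou.paint_regimes(tree, {clade: tree.clades[clade]})
            fits = [ou.fit_ou(tree, y, painting, mdl) for mdl in c["models"]]
            table = ou.compare_models(fits)
            out[clade] = {
                "trait": trait_col,
                "table": table.to_dict(orient="records"),
                "fits": [f.to_dict() for f in fits],
            }
        if not out:
            raise PhylogenyError("no configured clade found in the tree registry")
        return out

    @stage("trend", needs=("timescale",))
    def _trend():
        c = cfg["trend"]
        if not c["enabled"]:
            return {"skipped": True}
        tree = state["tree"]
        clade = c["clade"]
        if clade not in tree.clades:
            raise PhylogenyError(f"clade {clade!r} not registered on the tree")
        taxa = [tree.tip_labels[i] for i in tree.subtree_tips(tree.clades[clade])]
        sub = tree.prune_to_taxa(taxa)
        trait_col = c["trait"] or state["traits"].columns[0]
        fit = fit_trend(sub, state["traits"].loc[taxa, [trait_col]])
        return {"clade": clade, "trait": trait_col, **fit.to_dict()}

    @stage("pgls", needs=("timescale",))
    def _pgls():
        c = cfg["pgls"]
        if not c["enabled"]:
            return {"skipped": True}
        if state["groups"] is None:
            raise PhylogenyError("PGLS needs a clade membership table")
        if state["traits"].shape[1] < 2:
            raise PhylogenyError("PGLS ANCOVA needs two trait columns")
        xc, yc = state["traits"].columns[:2]
        out = {}
        for variant in c["variants"]:
            fit = pgls.pgls_ancova(state["tree"], state["traits"], state["groups"],
                                   variant=variant, x_col=xc, y_col=yc)
            out[variant] = fit.to_dict()
        return out

    @stage("simulations", needs=("calibrate",))
    def _sims():
        c = cfg["simulations"]
        tree = state["tree"]
        thr = state.get("threshold", cfg["medusa"]["threshold"])
        focal = tree.clades.get("Paraves")
        out = {}
        if c["bias"]["enabled"]:
            if focal is None:
                raise PhylogenyError("bias study needs a registered focal clade")
            rep = simulate.bias_study(tree, focal, float(thr), n=int(c["bias"]["n"]),
                                      seed=int(rng.integers(2**31 - 1)))
            out["bias"] = {"summary": rep.summary, "config": rep.config}
        if c["power"]["enabled"]:
            rep = simulate.power_study(
                tree, focal, float(thr), multipliers=c["power"]["multipliers"],
                n=int(c["power"]["n"]), seed=int(rng.integers(2**31 - 1)),
            )
            out["power"] = {"summary": rep.summary, "config": rep.config}
        if c["sweep"]["enabled"]:
            rep = simulate.branch_sweep(tree, state["traits"], focal, threshold=float(thr))
            out["sweep"] = {"summary": rep.summary}
        return out or {"skipped": True}

    _dump(summary, outdir / "summary.json")
    return summary
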