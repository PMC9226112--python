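"""End-to-end orchestration of the four analysis stages.

Stages communicate only through on-disk artifacts under a run directory:

    cohort/    expression.tsv groups.tsv methylation.tsv cna_calls.tsv
               cna_amp.txt cna_del.txt mutations.tsv clinical.tsv drg.tsv
               network.tsv truth.json
    drivers/   expression_stats.tsv methylation_stats.tsv
               drivers_<category>.tsv summary.json
    pairs/     pair_scores.tsv
    survival/  pair_prognosis.tsv summary.json
    manifest.json

Every artifact is a pure function of (config, seed), so re-running a stage
with the same configuration reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import drivers as drv
from . import io as omio
from . import network as net_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)

CATEGORIES = ("methylation", "cna", "mutation")


@dataclass
class RunConfig:
    """Single-source run configuration (YAML-serializable)."""

    workdir: str = "run"
    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    # thresholds (defaults follow the study's filters)
    deg_fdr: float = 0.05
    fc_thresh: float = 2.0
    dm_fdr: float = 0.05
    corr_p: float = 0.05
    screen_p: float = 0.1
    pair_fdr: float = 0.05
    top_k: int = 100
    min_mut_samples: int = 2  # recurrence condition; see docs/methods.md
    td_horizons: tuple[float, ...] = (365.0, 1095.0, 1825.0)
    # flags
    require_concordance: bool = False
    leave_one_out: bool = False
    pooled_top_k: bool = False

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("deg_fdr", "dm_fdr", "corr_p", "screen_p", "pair_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.fc_thresh < 1:
            raise ValueError("fc_thresh must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        cohort_doc = doc.pop("cohort", {})
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in doc.items()})
        cfg.cohort = cohort_mod.config_from_dict(cohort_doc)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        # workdir is a location, not a parameter: leaving it out keeps the
        # manifest and config hash identical wherever the run lands
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("cohort", "workdir")
        }
        d["cohort"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cohort_mod.config_to_dict(self.cohort).items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _paths(workdir) -> dict[str, Path]:
    root = Path(workdir)
    c, d, p, s = root / "cohort", root / "drivers", root / "pairs", root / "survival"
    return {
        "root": root, "cohort": c, "drivers": d, "pairs": p, "survival": s,
        "expression": c / "expression.tsv",
        "groups": c / "groups.tsv",
        "methylation": c / "methylation.tsv",
        "cna_calls": c / "cna_calls.tsv",
        "cna_amp": c / "cna_amp.txt",
        "cna_del": c / "cna_del.txt",
        "mutations": c / "mutations.tsv",
        "clinical": c / "clinical.tsv",
        "drg": c / "drg.tsv",
        "network": c / "network.tsv",
        "truth": c / "truth.json",
        "expr_stats": d / "expression_stats.tsv",
        "meth_stats": d / "methylation_stats.tsv",
        "driver_summary": d / "summary.json",
        "pair_scores": p / "pair_scores.tsv",
        "prognosis": s / "pair_prognosis.tsv",
        "surv_summary": s / "summary.json",
        "manifest": root / "manifest.json",
    }


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _write_json(doc: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict:
    t0 = _time.perf_counter()
    paths = _paths(cfg.workdir)
    paths["cohort"].mkdir(parents=True, exist_ok=True)
    cohort, truth = cohort_mod.generate_cohort(cfg.cohort)
    network = cohort_mod.generate_network(cfg.cohort, truth)
    omio.write_matrix(cohort.expression, paths["expression"], paths["groups"])
    omio.write_matrix(cohort.methylation, paths["methylation"], paths["groups"])
    omio.write_cna(cohort.cna, paths["cna_calls"], paths["cna_amp"], paths["cna_del"])
    omio.write_mutations(cohort.mutations, paths["mutations"])
    omio.write_clinical(cohort.clinical, paths["clinical"])
    omio.write_drg(cohort.drg, paths["drg"])
    omio.write_network(network, paths["network"])
    truth.to_json(paths["truth"])
    counts = {
        "n_genes": len(cohort.expression.genes),
        "n_tumor": len(cohort.expression.tumor_samples()),
        "n_normal": len(cohort.expression.normal_samples()),
        "n_network_edges": network.number_of_edges(),
        "n_mutation_records": len(cohort.mutations.records),
        "n_true_pairs": len(truth.true_pairs),
    }
    logger.info("simulate: %s (%.1fs)", counts, _time.perf_counter() - t0)
    return counts


def stage_drivers(cfg: RunConfig) -> dict:
    t0 = _time.perf_counter()
    paths = _paths(cfg.workdir)
    paths["drivers"].mkdir(parents=True, exist_ok=True)
    expr = omio.read_matrix(_require(paths["expression"], "simulate"), "expression",
                            paths["groups"])
    meth = omio.read_matrix(_require(paths["methylation"], "simulate"), "methylation",
                            paths["groups"])
    cna = omio.read_cna(_require(paths["cna_calls"], "simulate"),
                        paths["cna_amp"], paths["cna_del"])
    mut = omio.read_mutations(_require(paths["mutations"], "simulate"))

    stats = drv.moderated_t_test(expr)
    up, down = drv.select_degs(stats, cfg.fc_thresh, cfg.deg_fdr)
    dm = drv.diff_methylation(meth)
    sets = {
        "methylation": drv.methylation_driven(dm, expr, meth, cfg.dm_fdr, cfg.corr_p),
        "cna": drv.cna_driven(cna, up, down, cfg.require_concordance),
        "mutation": drv.mutation_driven(mut, up, down, cfg.min_mut_samples),
    }
    stats.to_csv(paths["expr_stats"], sep="\t", float_format="%.8g")
    dm.to_csv(paths["meth_stats"], sep="\t", float_format="%.8g")
    for cat, ds in sets.items():
        ds.evidence.to_csv(paths["drivers"] / f"drivers_{cat}.tsv", sep="\t",
                           index=False, float_format="%.8g")
    universe = len(expr.genes)
    overlaps = {}
    cats = list(sets)
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            k, p = drv.overlap_significance(sets[cats[i]].genes, sets[cats[j]].genes,
                                            universe)
            overlaps[f"{cats[i]}_x_{cats[j]}"] = {"overlap": k, "p": p}
    summary = {
        "n_deg_up": len(up),
        "n_deg_down": len(down),
        "n_drivers": {cat: len(ds.genes) for cat, ds in sets.items()},
        "universe_size": universe,
        "overlap_tests": overlaps,
    }
    _write_json(summary, paths["driver_summary"])
    logger.info("drivers: %s (%.1fs)", summary["n_drivers"], _time.perf_counter() - t0)
    return summary


def stage_score(cfg: RunConfig) -> dict:
    t0 = _time.perf_counter()
    paths = _paths(cfg.workdir)
    paths["pairs"].mkdir(parents=True, exist_ok=True)
    network = omio.read_network(_require(paths["network"], "simulate"))
    drg = omio.read_drg(_require(paths["drg"], "simulate"))
    _require(paths["driver_summary"], "drivers")
    driver_sets = {
        cat: _read_driver_genes(paths["drivers"] / f"drivers_{cat}.tsv")
        for cat in CATEGORIES
    }
    frames = []
    if cfg.pooled_top_k:
        pooled = sorted(set().union(*driver_sets.values()))
        scores = net_mod.top_pairs(network, pooled, drg.genes, "pooled",
                                   cfg.top_k, cfg.leave_one_out)
        frames.append(net_mod.pair_scores_frame(scores))
    else:
        for cat in CATEGORIES:
            scores = net_mod.top_pairs(network, driver_sets[cat], drg.genes, cat,
                                       cfg.top_k, cfg.leave_one_out)
            frames.append(net_mod.pair_scores_frame(scores))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table.to_csv(paths["pair_scores"], sep="\t", index=False, float_format="%.8g")
    counts = dict(table["category"].value_counts()) if len(table) else {}
    counts = {str(k): int(v) for k, v in counts.items()}
    logger.info("score: %s (%.1fs)", counts, _time.perf_counter() - t0)
    return {"n_pairs": counts}


def _read_driver_genes(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return sorted(set(df["gene"])) if len(df) else []


def stage_survival(cfg: RunConfig) -> dict:
    t0 = _time.perf_counter()
    paths = _paths(cfg.workdir)
    paths["survival"].mkdir(parents=True, exist_ok=True)
    expr = omio.read_matrix(_require(paths["expression"], "simulate"), "expression",
                            paths["groups"])
    clinical = omio.read_clinical(_require(paths["clinical"], "simulate"))
    pair_table = pd.read_csv(_require(paths["pair_scores"], "score"), sep="\t")
    candidates = [
        net_mod.PairScore(r.driver, r.drg, r.category, r.auc_driver, r.auc_drg, r.score)
        for r in pair_table.itertuples(index=False)
    ]
    results = surv_mod.evaluate_pairs(
        candidates, expr, clinical, fdr_thresh=cfg.pair_fdr,
        screen_p=cfg.screen_p, horizons=cfg.td_horizons,
    )
    frame = surv_mod.prognosis_frame(results)
    frame.to_csv(paths["prognosis"], sep="\t", index=False, float_format="%.8g")
    summary = {
        "n_candidates": len(results),
        "n_evaluated": int((~frame["dropped"]).sum()) if len(frame) else 0,
        "n_flagged": int(frame["flagged"].sum()) if len(frame) else 0,
    }
    _write_json(summary, paths["surv_summary"])
    logger.info("survival: %s (%.1fs)", summary, _time.perf_counter() - t0)
    return summary


def run_all(cfg: RunConfig) -> dict:
    """Run simulate → drivers → score → survival and write the manifest."""
    cfg.validate()
    counts = {
        "simulate": stage_simulate(cfg),
        "drivers": stage_drivers(cfg),
        "score": stage_score(cfg),
        "survival": stage_survival(cfg),
    }
    paths = _paths(cfg.workdir)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.cohort.seed,
        "versions": _versions(),
        "stage_counts": counts,
    }
    _write_json(manifest, paths["manifest"])
    return manifest


def _versions() -> dict:
    from importlib.metadata import version, PackageNotFoundError

    out = {"numpy": np.__version__, "pandas": pd.__version__,
           "networkx": nx.__version__}
    try:
        out["drivenet"] = version("drivenet")
    except PackageNotFoundError:
        out["drivenet"] = "unknown"
    return out
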