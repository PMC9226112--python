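"""Synthetic multi-omics cohort with planted, fully labeled signal.

The generator emulates the shape of a TCGA-style breast-cancer study: a log2
expression matrix with tumor/normal labels, promoter methylation betas, a
GISTIC-style integer call matrix with amplified/deleted gene lists, a somatic
mutation table, right-censored survival with binary clinical covariates, and a
positive-weighted functional-linkage network with planted modules that couple
designated driver genes to designated drug-response genes (DRGs).

Every planted effect is recorded in :class:`TruthLabels`, so downstream
recovery (driver discovery, mutual-predictability ranking, prognostic-pair
flagging) can be scored against known ground truth.

Randomness is organized as one master seed with a named independent substream
per modality, so adding or regenerating one modality never perturbs another's
draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CnaCalls,
    DrgAnnotation,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
)

# fixed substream codes: adding a modality appends a code, never renumbers
_STREAMS = {
    "layout": 0,
    "expression": 1,
    "methylation": 2,
    "cna": 3,
    "mutation": 4,
    "network": 5,
    "survival": 6,
    "clinical": 7,
}


class ConfigError(ValueError):
    """A CohortConfig field violates its invariant."""


@dataclass
class CohortConfig:
    """Generating parameters; defaults are the package's study conditions."""

    n_genes: int = 2000
    n_tumor: int = 100
    n_normal: int = 40

    # planted gene classes
    n_meth_driven: int = 20
    n_cna_driven: int = 20
    n_mut_driven: int = 20
    n_drg: int = 18
    n_drugs: int = 4
    n_de_extra: int = 100  # DE genes with no alteration behind them
    n_cna_passenger: int = 20  # genes inside altered regions, no dosage effect

    # expression
    logfc_de: float = 1.5  # log2 shift of planted DE genes in tumors
    expr_noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    # methylation and its expression coupling
    delta_beta: float = 0.3
    meth_noise_sd: float = 0.07
    meth_expr_slope: float = -7.0  # log2 expression units per unit beta

    # copy number
    cna_dosage: float = 1.0  # log2 expression shift per unit call
    cna_frac: float = 0.75  # fraction of tumors carrying the planted call
    cna_bg_rate: float = 0.02  # low-level +-1 background calls

    # mutation
    mut_rate_background: float = 2e-4
    mut_rate_driver: float = 0.12
    silent_fraction: float = 0.15

    # network
    module_count: int = 6
    module_filler: int = 8  # unlabeled genes added to each module
    within_module_edge_prob: float = 0.7
    background_edge_prob: float = 0.01
    within_weight_params: tuple[float, float] = (8.0, 2.0)  # Beta(a, b)
    background_weight_params: tuple[float, float] = (2.0, 8.0)

    # survival
    # strong enough that the *marginal* (univariate) effect of each gene
    # clears the p < 0.1 screen despite omitted-covariate attenuation
    surv_beta: tuple[float, float] = (1.0, -1.0)
    surv_baseline_hazard: float = 1.0 / 1500.0  # per day
    censor_rate: float = 1.0 / 4000.0

    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in (
            "n_meth_driven",
            "n_cna_driven",
            "n_mut_driven",
            "n_drg",
            "n_drugs",
            "n_de_extra",
            "n_cna_passenger",
            "module_count",
            "module_filler",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        planted = (
            self.n_meth_driven
            + self.n_cna_driven
            + self.n_mut_driven
            + self.n_drg
            + self.n_de_extra
            + self.n_cna_passenger
        )
        if planted > self.n_genes:
            raise ConfigError("planted gene classes exceed n_genes")
        for name in (
            "cna_frac",
            "cna_bg_rate",
            "mut_rate_background",
            "mut_rate_driver",
            "silent_fraction",
            "within_module_edge_prob",
            "background_edge_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not 0 <= self.delta_beta <= 0.5:
            raise ConfigError("delta_beta must be in [0, 0.5] to keep betas in (0,1)")
        for name in ("within_weight_params", "background_weight_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} must be positive Beta shape parameters")
        for name in ("expr_noise_sd", "meth_noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.surv_baseline_hazard <= 0 or self.censor_rate < 0:
            raise ConfigError("hazard rates must be positive")


@dataclass
class TruthLabels:
    """Ground truth of every planted effect."""

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    meth_driven: dict[str, int] = field(default_factory=dict)  # gene -> +1 hyper / -1 hypo
    cna_driven: dict[str, int] = field(default_factory=dict)  # gene -> call sign
    mut_driven: set[str] = field(default_factory=set)
    drg: dict[str, str] = field(default_factory=dict)  # gene -> drug
    module_assignment: dict[str, int] = field(default_factory=dict)
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    surv_pair: tuple[str, str] = ("", "")
    surv_beta_true: tuple[float, float] = (0.0, 0.0)

    def driver_truth(self, category: str):
        return {
            "methylation": set(self.meth_driven),
            "cna": set(self.cna_driven),
            "mutation": set(self.mut_driven),
        }[category]

    def true_pairs_for(self, category: str) -> set[tuple[str, str]]:
        drivers = self.driver_truth(category)
        return {p for p in self.true_pairs if p[0] in drivers}

    def to_json(self, path) -> None:
        doc = {
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "meth_driven": dict(sorted(self.meth_driven.items())),
            "cna_driven": dict(sorted(self.cna_driven.items())),
            "mut_driven": sorted(self.mut_driven),
            "drg": dict(sorted(self.drg.items())),
            "module_assignment": dict(sorted(self.module_assignment.items())),
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "surv_pair": list(self.surv_pair),
            "surv_beta_true": list(self.surv_beta_true),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLabels":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            de_genes_up=set(doc["de_genes_up"]),
            de_genes_down=set(doc["de_genes_down"]),
            meth_driven={k: int(v) for k, v in doc["meth_driven"].items()},
            cna_driven={k: int(v) for k, v in doc["cna_driven"].items()},
            mut_driven=set(doc["mut_driven"]),
            drg=dict(doc["drg"]),
            module_assignment={k: int(v) for k, v in doc["module_assignment"].items()},
            true_pairs={tuple(p) for p in doc["true_pairs"]},
            surv_pair=tuple(doc["surv_pair"]),
            surv_beta_true=tuple(doc["surv_beta_true"]),
        )


@dataclass
class OmicsCohort:
    """The bundled synthetic cohort sharing one gene/sample namespace."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    cna: CnaCalls
    mutations: MutationTable
    clinical: ClinicalTable
    drg: DrgAnnotation


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), _STREAMS[stream]])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _layout(config: CohortConfig) -> dict[str, list[str]]:
    """Deterministic partition of the gene universe into planted classes."""
    genes = _gene_ids(config.n_genes)
    i = 0

    def take(k: int) -> list[str]:
        nonlocal i
        out = genes[i : i + k]
        i += k
        return out

    return {
        "genes": genes,
        "meth": take(config.n_meth_driven),
        "cna": take(config.n_cna_driven),
        "mut": take(config.n_mut_driven),
        "drg": take(config.n_drg),
        "de_extra": take(config.n_de_extra),
        "cna_passenger": take(config.n_cna_passenger),
        "background": genes[i:],
    }


def _alternating_signs(genes: list[str]) -> dict[str, int]:
    return {g: (1 if k % 2 == 0 else -1) for k, g in enumerate(genes)}


def generate_cohort(config: CohortConfig) -> tuple[OmicsCohort, TruthLabels]:
    """Generate the labeled cohort.

    Planted structure: differentially expressed (DE) genes shift by
    ``±logfc_de`` in tumors; methylation-driven genes shift tumor beta by
    ``±delta_beta`` with expression generated as
    ``baseline + meth_expr_slope·beta + noise`` (negative slope → inverse
    coupling); CNA-driven genes carry ±2 calls in a fraction of tumors with a
    dosage expression shift; mutation-driven genes carry elevated non-silent
    mutation rates plus a tumor expression shift. Survival follows an
    exponential proportional-hazards model on the standardized expression of
    the planted pair, independently exponentially censored.
    """
    config.validate()
    lay = _layout(config)
    genes = lay["genes"]
    tumor = [f"T{i:04d}" for i in range(config.n_tumor)]
    normal = [f"N{i:04d}" for i in range(config.n_normal)]
    samples = tumor + normal
    n_g, n_t, n_n = config.n_genes, config.n_tumor, config.n_normal
    gidx = {g: k for k, g in enumerate(genes)}
    truth = TruthLabels()

    # --- methylation ------------------------------------------------------
    rng_m = _rng(config, "methylation")
    meth_sign = _alternating_signs(lay["meth"])
    base_beta = rng_m.uniform(0.2, 0.8, size=n_g)
    for g, s in meth_sign.items():
        # room for the planted shift on either side
        base_beta[gidx[g]] = rng_m.uniform(0.15, 0.35) if s > 0 else rng_m.uniform(0.55, 0.75)
    beta = base_beta[:, None] + rng_m.normal(0.0, config.meth_noise_sd, size=(n_g, n_t + n_n))
    for g, s in meth_sign.items():
        beta[gidx[g], :n_t] += s * config.delta_beta
    beta = np.clip(beta, 0.005, 0.995)
    truth.meth_driven = dict(meth_sign)

    # --- copy number ------------------------------------------------------
    rng_c = _rng(config, "cna")
    cna_sign = _alternating_signs(lay["cna"])
    call = np.zeros((n_g, n_t), dtype=int)
    bg = rng_c.random(size=(n_g, n_t)) < config.cna_bg_rate
    call[bg] = rng_c.choice([-1, 1], size=int(bg.sum()))
    for g, s in cna_sign.items():
        carrier = rng_c.random(n_t) < config.cna_frac
        call[gidx[g], carrier] = 2 * s
        call[gidx[g], ~carrier] = 0
    passenger_sign = _alternating_signs(lay["cna_passenger"])
    amp = {g for g, s in cna_sign.items() if s > 0}
    amp |= {g for g, s in passenger_sign.items() if s > 0}
    dele = {g for g, s in cna_sign.items() if s < 0}
    dele |= {g for g, s in passenger_sign.items() if s < 0}
    truth.cna_driven = dict(cna_sign)

    # --- mutations --------------------------------------------------------
    rng_u = _rng(config, "mutation")
    rate = np.full(n_g, config.mut_rate_background)
    for g in lay["mut"]:
        rate[gidx[g]] = config.mut_rate_driver
    mutated = rng_u.random(size=(n_g, n_t)) < rate[:, None]
    rows = []
    gi, si = np.nonzero(mutated)
    silent = rng_u.random(len(gi)) < config.silent_fraction
    for k in range(len(gi)):
        rows.append((genes[gi[k]], tumor[si[k]], "silent" if silent[k] else "nonsilent"))
    mut_table = MutationTable(
        records=pd.DataFrame(rows, columns=["gene", "sample", "variant_class"])
    )
    truth.mut_driven = set(lay["mut"])
    mut_sign = _alternating_signs(lay["mut"])

    # --- expression -------------------------------------------------------
    rng_e = _rng(config, "expression")
    baseline = rng_e.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    expr = baseline[:, None] + rng_e.normal(0.0, config.expr_noise_sd, size=(n_g, n_t + n_n))
    extra_sign = _alternating_signs(lay["de_extra"])
    for g, s in {**extra_sign, **mut_sign}.items():
        expr[gidx[g], :n_t] += s * config.logfc_de
    for g in lay["meth"]:
        expr[gidx[g]] += config.meth_expr_slope * beta[gidx[g]]
    for g in lay["cna"]:
        expr[gidx[g], :n_t] += config.cna_dosage * call[gidx[g]]

    def _shift(g: str) -> float:
        s = 0.0
        if g in extra_sign:
            s += extra_sign[g] * config.logfc_de
        if g in mut_sign:
            s += mut_sign[g] * config.logfc_de
        if g in meth_sign:
            s += config.meth_expr_slope * meth_sign[g] * config.delta_beta
        if g in cna_sign:
            s += config.cna_dosage * 2 * cna_sign[g] * config.cna_frac
        return s

    truth.de_genes_up = {g for g in genes if _shift(g) > 0}
    truth.de_genes_down = {g for g in genes if _shift(g) < 0}

    # --- DRG annotation ---------------------------------------------------
    rng_l = _rng(config, "layout")
    drugs = [f"drug_{i}" for i in range(max(config.n_drugs, 1))]
    truth.drg = {g: drugs[int(rng_l.integers(len(drugs)))] for g in lay["drg"]}
    drg_ann = DrgAnnotation(
        records=pd.DataFrame(
            sorted(truth.drg.items()), columns=["gene", "drug"]
        )
    )

    # --- modules and true pairs ------------------------------------------
    truth.module_assignment = _assign_modules(config, lay)
    by_module: dict[int, list[str]] = {}
    for g, m in truth.module_assignment.items():
        by_module.setdefault(m, []).append(g)
    drivers = set(lay["meth"]) | set(lay["cna"]) | set(lay["mut"])
    for members in by_module.values():
        mod_drivers = [g for g in members if g in drivers]
        mod_drgs = [g for g in members if g in truth.drg]
        truth.true_pairs |= {(d, r) for d in mod_drivers for r in mod_drgs}

    # --- survival ---------------------------------------------------------
    rng_s = _rng(config, "survival")
    pair_driver = lay["meth"][0] if lay["meth"] else genes[0]
    pair_drg = lay["drg"][0] if lay["drg"] else genes[-1]
    truth.surv_pair = (pair_driver, pair_drg)
    truth.surv_beta_true = tuple(config.surv_beta)
    x = expr[[gidx[pair_driver], gidx[pair_drg]], :n_t]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    eta = config.surv_beta[0] * x[0] + config.surv_beta[1] * x[1]
    hazard = config.surv_baseline_hazard * np.exp(eta)
    t_event = rng_s.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_cens = rng_s.exponential(1.0 / config.censor_rate, size=n_t)
    else:
        t_cens = np.full(n_t, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    # --- clinical covariates (independent of the planted pair) -----------
    rng_cl = _rng(config, "clinical")
    clin = pd.DataFrame(
        {
            "os_time": np.round(os_time, 2) + 0.01,
            "os_event": os_event,
            "age_group": np.where(rng_cl.random(n_t) < 0.5, "old", "young"),
            "er": np.where(rng_cl.random(n_t) < 0.7, "pos", "neg"),
            "pr": np.where(rng_cl.random(n_t) < 0.6, "pos", "neg"),
            "stage": np.where(rng_cl.random(n_t) < 0.3, "late", "early"),
        },
        index=pd.Index(tumor, name="sample"),
    )

    group = pd.Series(
        ["tumor"] * n_t + ["normal"] * n_n, index=pd.Index(samples, name="sample")
    )
    cohort = OmicsCohort(
        expression=ExpressionMatrix(
            values=pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples),
            group=group,
        ),
        methylation=MethylationMatrix(
            beta=pd.DataFrame(beta, index=pd.Index(genes, name="gene"), columns=samples),
            group=group,
        ),
        cna=CnaCalls(
            call=pd.DataFrame(call, index=pd.Index(genes, name="gene"), columns=tumor),
            amp_genes=amp,
            del_genes=dele,
        ),
        mutations=mut_table,
        clinical=ClinicalTable(table=clin),
        drg=drg_ann,
    )
    return cohort, truth


def _assign_modules(config: CohortConfig, lay: dict[str, list[str]]) -> dict[str, int]:
    """Functional-module layout.

    The first three modules each hold one driver category plus a share of the
    DRGs; remaining modules hold leftover DRGs and filler genes. Filler genes
    come deterministically from the background pool.
    """
    m = config.module_count
    if m == 0:
        return {}
    assignment: dict[str, int] = {}
    for mod, key in zip(range(3), ("meth", "cna", "mut")):
        if mod >= m:
            break
        for g in lay[key]:
            assignment[g] = mod
    # spread DRGs over the modules round-robin so each driver module gets some
    for k, g in enumerate(lay["drg"]):
        assignment[g] = k % m
    filler = iter(lay["background"])
    for mod in range(m):
        for _ in range(config.module_filler):
            try:
                assignment[next(filler)] = mod
            except StopIteration:
                break
    return assignment


def generate_network(config: CohortConfig, labels: TruthLabels) -> nx.Graph:
    """Sample the weighted functional-linkage network around the planted modules.

    Within-module gene pairs link at ``within_module_edge_prob`` with
    Beta(*within_weight_params*) weights; all other pairs link at
    ``background_edge_prob`` with Beta(*background_weight_params*) weights,
    stochastically smaller under the default shapes. Weights lie in (0, 1];
    the graph is simple and undirected, and includes every gene as a node.
    """
    config.validate()
    rng = _rng(config, "network")
    genes = _gene_ids(config.n_genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    wa, wb = config.within_weight_params
    ba, bb = config.background_weight_params

    by_module: dict[int, list[str]] = {}
    for gene, mod in labels.module_assignment.items():
        by_module.setdefault(mod, []).append(gene)
    module_of = labels.module_assignment

    for members in (sorted(v) for _, v in sorted(by_module.items())):
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < config.within_module_edge_prob:
                    w = float(np.clip(rng.beta(wa, wb), 1e-9, 1.0))
                    g.add_edge(members[i], members[j], weight=w)

    if config.background_edge_prob > 0:
        n = config.n_genes
        iu0, iu1 = np.triu_indices(n, k=1)
        total = len(iu0)
        k = rng.binomial(total, config.background_edge_prob)
        pick = rng.choice(total, size=k, replace=False)
        for a, b in zip(iu0[pick], iu1[pick]):
            ga, gb = genes[a], genes[b]
            ma, mb = module_of.get(ga), module_of.get(gb)
            if ma is not None and ma == mb:
                continue  # within-module pairs are sampled above
            if g.has_edge(ga, gb):
                continue
            w = float(np.clip(rng.beta(ba, bb), 1e-9, 1.0))
            g.add_edge(ga, gb, weight=w)

    # the planted prognostic pair shares a module by construction; pin its
    # edge so the pair is always network-adjacent (a module edge like any
    # other, just not left to the Bernoulli draw)
    d, r = labels.surv_pair
    if d in g and r in g and module_of.get(d) is not None \
            and module_of.get(d) == module_of.get(r) and not g.has_edge(d, r):
        g.add_edge(d, r, weight=float(np.clip(rng.beta(wa, wb), 1e-9, 1.0)))
    return g


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def config_from_dict(doc: dict) -> CohortConfig:
    cfg = CohortConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in doc.items()})
    cfg.validate()
    return cfg
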