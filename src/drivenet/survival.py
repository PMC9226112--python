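"""Prognostic evaluation of candidate gene pairs.

Each candidate driver×DRG pair is evaluated as a two-gene signature: genes are
screened by univariate Cox regression (p < 0.1), a two-covariate Cox model on
standardized expression yields coefficients (β1, β2), the per-patient risk
score β1·x1 + β2·x2 is dichotomized at its median, and the high/low groups are
compared by Kaplan–Meier/log-rank and by multivariable Cox adjusted for age,
ER, PR, and stage. Benjamini–Hochberg FDR across pairs flags prognostic
signatures; time-dependent (cumulative/dynamic, IPCW-weighted) ROC AUC
summarizes predictive capacity at fixed horizons.

The Cox fitter maximizes the Breslow-ties log partial likelihood by
Newton–Raphson with step-halving (tolerance 1e-8 on the score norm); standard
errors come from the inverse observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drivers import benjamini_hochberg
from .io import ClinicalTable, ExpressionMatrix
from .network import PairScore

logger = logging.getLogger(__name__)


class SingularInformationError(np.linalg.LinAlgError):
    """The observed information matrix is singular (collinear design)."""


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    hr_low: np.ndarray
    hr_high: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "hr": self.hr,
                "hr_low": self.hr_low,
                "hr_high": self.hr_high,
            },
            index=self.names,
        )


@dataclass
class KmCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float, inclusive: bool = True) -> float:
        """S(t); with inclusive=False, the left limit S(t−)."""
        if inclusive:
            mask = self.times <= t
        else:
            mask = self.times < t
        if not mask.any():
            return 1.0
        return float(self.survival[mask][-1])


@dataclass
class PairPrognosis:
    driver: str
    drg: str
    category: str = ""
    screen_p: dict[str, float] = field(default_factory=dict)
    beta: tuple[float, float] = (np.nan, np.nan)
    risk_scores: pd.Series | None = None
    risk_group: pd.Series | None = None
    logrank_chi2: float = np.nan
    logrank_p: float = np.nan
    adjusted_hr: float = np.nan
    adjusted_ci: tuple[float, float] = (np.nan, np.nan)
    adjusted_p: float = np.nan
    fdr: float = np.nan
    td_auc: dict[float, float] = field(default_factory=dict)
    dropped: bool = False
    drop_reason: str = ""
    flagged: bool = False  # fdr < threshold, set by evaluate_pairs


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)


class _CoxData:
    """Time-sorted design with tie-group bookkeeping, shared across Newton steps."""

    def __init__(self, x: np.ndarray, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.x = x[order]
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.event_times = np.unique(self.time[self.event])
        # risk set of an event time = suffix starting at its first index
        self.first = np.searchsorted(self.time, self.event_times, side="left")
        self.d = np.array(
            [int((self.event & (self.time == t)).sum()) for t in self.event_times]
        )
        self.x_event_sum = self.x[self.event].sum(axis=0)

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.x @ beta
        m = eta.max()
        w = np.exp(eta - m)
        s0 = np.cumsum(w[::-1])[::-1][self.first]
        return float(eta[self.event].sum() - (self.d * (np.log(s0) + m)).sum())

    def score_info(self, beta: np.ndarray):
        eta = self.x @ beta
        w = np.exp(eta - eta.max())
        s0 = np.cumsum(w[::-1])[::-1][self.first]  # (k,)
        s1 = np.cumsum((w[:, None] * self.x)[::-1], axis=0)[::-1][self.first]  # (k,p)
        outer = self.x[:, :, None] * self.x[:, None, :]
        s2 = np.cumsum((w[:, None, None] * outer)[::-1], axis=0)[::-1][self.first]
        xbar = s1 / s0[:, None]
        score = self.x_event_sum - (self.d[:, None] * xbar).sum(axis=0)
        info = (
            self.d[:, None, None]
            * (s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0)
        return score, info


def cox_partial_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow-ties log partial likelihood at the given coefficients."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    data = _CoxData(x, np.asarray(time, dtype=float), np.asarray(event).astype(bool))
    return data.loglik(beta)


def fit_cox(design, time, event, names: list[str] | None = None,
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Newton–Raphson).

    ``design`` is an (n × p) covariate matrix or DataFrame. Raises
    :class:`SingularInformationError` on collinear designs; monotone
    likelihoods (separation) yield ``converged=False``.
    """
    if isinstance(design, pd.DataFrame):
        names = names or list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(design, dtype=float))
        if x.shape[0] == 1 and len(np.asarray(time)) != 1:
            x = x.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    if event.sum() == 0:
        raise ValueError("no events")
    if not np.isfinite(x).all():
        raise ValueError("non-finite covariates")
    const = np.all(x == x[0, :], axis=0)
    if const.any():
        raise ValueError(f"constant covariate(s): {[names[i] for i in np.flatnonzero(const)]}")

    data = _CoxData(x, time, event)
    beta = np.zeros(x.shape[1])
    ll = data.loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info = data.score_info(beta)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(str(exc)) from exc
        if np.linalg.cond(info) > 1e12:
            raise SingularInformationError("ill-conditioned information matrix")
        # step-halving: never accept a decrease in the partial likelihood
        factor = 1.0
        for _ in range(30):
            ll_new = data.loglik(beta + factor * step)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        ll = data.loglik(beta)
        if np.max(np.abs(beta)) > 30:
            break
    # monotone likelihood: the score also vanishes as |beta| -> inf, so a
    # small score at an extreme coefficient is separation, not convergence
    if converged and np.max(np.abs(beta)) > 15:
        logger.warning("extreme coefficient %.1f suggests separation; flagged "
                       "non-converged", float(np.max(np.abs(beta))))
        converged = False
    _, info = data.score_info(beta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(str(exc)) from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        return CoxFit(
        names=names,
        beta=beta,
        se=se,
        z=z,
        p=p,
        hr=np.exp(beta),
        hr_low=np.exp(beta - 1.959963984540054 * se),
        hr_high=np.exp(beta + 1.959963984540054 * se),
        loglik=float(ll),
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


def km_estimate(time, event) -> KmCurve:
    """Product-limit survival estimate.

    At tied times, events are processed before censorings: subjects censored
    at t remain in the risk set for the events at t.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise ValueError("empty input")
    event_times = np.unique(time[event])
    at_risk = np.array([(time >= t).sum() for t in event_times], dtype=int)
    d = np.array([(event & (time == t)).sum() for t in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(times=event_times, at_risk=at_risk, events=d, survival=surv)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    in_a = group == levels[0]
    if in_a.all() or (~in_a).all():
        raise ValueError("one group is empty")
    if event.sum() == 0:
        raise ValueError("no events")
    first_event = time[event].min()
    for g_mask, name in ((in_a, levels[0]), (~in_a, levels[1])):
        if (time[g_mask] >= first_event).sum() == 0:
            raise ValueError(f"group {name!r} has no subjects at risk at the first event")
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(time[event]):
        risk = time >= tau
        n = int(risk.sum())
        n_a = int((risk & in_a).sum())
        d = int((event & (time == tau)).sum())
        d_a = int((event & (time == tau) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative cases / dynamic controls, IPCW)


def td_auc(scores, time, event, horizon: float) -> float | None:
    """Cumulative/dynamic AUC at the horizon with IPCW weights.

    Cases are subjects with an event by the horizon (weight 1/G(T−)); controls
    survive past it (weight 1/G(horizon)), where G is the Kaplan–Meier
    estimate of the censoring distribution. Tie-corrected weighted
    Mann–Whitney on the risk scores. Returns None when either class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    cases = event & (time <= horizon)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        return None
    g_curve = km_estimate(time, ~event)
    w_case = np.array([1.0 / max(g_curve.at(t, inclusive=False), 1e-12)
                       for t in time[cases]])
    g_h = max(g_curve.at(horizon), 1e-12)
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_h)
    sc_case = scores[cases]
    sc_ctrl = scores[controls]
    gt = (sc_case[:, None] > sc_ctrl[None, :]).astype(float)
    eq = (sc_case[:, None] == sc_ctrl[None, :]).astype(float)
    wmat = np.outer(w_case, w_ctrl)
    return float((wmat * (gt + 0.5 * eq)).sum() / wmat.sum())


# ---------------------------------------------------------------------------
# pair evaluation


def _standardized_expression(expr: ExpressionMatrix, genes, samples) -> pd.DataFrame:
    sub = expr.values.loc[list(genes), list(samples)].T  # samples × genes
    return (sub - sub.mean()) / sub.std(ddof=1)


def univariate_screen(expr: ExpressionMatrix, clinical: ClinicalTable,
                      genes, p_thresh: float = 0.1) -> set[str]:
    """Genes whose standardized expression has univariate Cox p < p_thresh."""
    table = univariate_screen_table(expr, clinical, genes)
    return set(table.index[table["p"] < p_thresh])

def univariate_screen_table(expr: ExpressionMatrix, clinical: ClinicalTable,
                            genes) -> pd.DataFrame:
    samples = [s for s in clinical.samples if s in set(expr.samples)]
    genes = [g for g in genes if g in set(expr.genes)]
    x = _standardized_expression(expr, genes, samples)
    t = clinical.table.loc[samples, "os_time"].to_numpy()
    e = clinical.table.loc[samples, "os_event"].to_numpy()
    rows = []
    for g in genes:
        try:
            fit = fit_cox(x[[g]], t, e, names=[g])
        except (ValueError, SingularInformationError) as exc:
            logger.warning("univariate Cox failed for %s: %s", g, exc)
            continue
        if not fit.converged:
            logger.warning("univariate Cox did not converge for %s; excluded", g)
            continue
        rows.append((g, fit.beta[0], fit.hr[0], fit.hr_low[0], fit.hr_high[0], fit.p[0]))
    return pd.DataFrame(
        rows, columns=["gene", "beta", "hr", "hr_low", "hr_high", "p"]
    ).set_index("gene")


def pair_risk_score(expr: ExpressionMatrix, clinical: ClinicalTable,
                    pair: tuple[str, str]) -> PairPrognosis:
    """Two-gene Cox risk score, dichotomized at the median.

    risk_i = β1·x1i + β2·x2i on standardized expression; samples at or below
    the median risk form the low group (median-tied samples go low, for
    determinism).
    """
    g1, g2 = pair
    out = PairPrognosis(driver=g1, drg=g2)
    samples = [s for s in clinical.samples if s in set(expr.samples)]
    x = _standardized_expression(expr, (g1, g2), samples)
    t = clinical.table.loc[samples, "os_time"].to_numpy()
    e = clinical.table.loc[samples, "os_event"].to_numpy()
    try:
        fit = fit_cox(x, t, e, names=[g1, g2])
    except (ValueError, SingularInformationError) as exc:
        out.dropped = True
        out.drop_reason = f"pair Cox failed: {exc}"
        return out
    if not fit.converged:
        out.dropped = True
        out.drop_reason = "pair Cox did not converge"
        return out
    out.beta = (float(fit.beta[0]), float(fit.beta[1]))
    risk = x[g1].to_numpy() * fit.beta[0] + x[g2].to_numpy() * fit.beta[1]
    out.risk_scores = pd.Series(risk, index=pd.Index(samples, name="sample"))
    med = float(np.median(risk))
    grp = np.where(risk > med, "high", "low")
    out.risk_group = pd.Series(grp, index=out.risk_scores.index)
    if (grp == "high").sum() == 0 or (grp == "low").sum() == 0:
        out.dropped = True
        out.drop_reason = "degenerate risk split (all scores tied)"
    return out


_COVARIATE_MAP = {
    "age_group": ("age_old", {"old": 1, "young": 0}),
    "er": ("er_pos", {"pos": 1, "neg": 0}),
    "pr": ("pr_pos", {"pos": 1, "neg": 0}),
    "stage": ("stage_late", {"late": 1, "early": 0}),
}


def clinical_design(clinical: ClinicalTable, samples) -> pd.DataFrame:
    """Binary covariate design; unknown-valued samples are complete-case excluded."""
    t = clinical.table.loc[list(samples)]
    cols = {}
    for raw, (name, mapping) in _COVARIATE_MAP.items():
        vals = t[raw]
        if (vals == "unknown").all():
            logger.warning("covariate %s entirely unknown; dropped from design", raw)
            continue
        cols[name] = vals.map(mapping)  # unknown -> NaN
    design = pd.DataFrame(cols, index=t.index)
    return design.dropna().astype(float)


def adjusted_cox(prog: PairPrognosis, clinical: ClinicalTable) -> CoxFit:
    """Multivariable Cox of risk group adjusted for age, ER, PR, and stage."""
    if prog.risk_group is None:
        raise ValueError("risk group undefined")
    design = clinical_design(clinical, prog.risk_group.index)
    design.insert(0, "risk_high", (prog.risk_group.loc[design.index] == "high").astype(float))
    # a covariate constant in the complete-case subset carries no information
    const = [c for c in design.columns[1:] if design[c].nunique() == 1]
    if const:
        logger.warning("dropping constant covariate(s) %s", const)
        design = design.drop(columns=const)
    t = clinical.table.loc[design.index, "os_time"].to_numpy()
    e = clinical.table.loc[design.index, "os_event"].to_numpy()
    return fit_cox(design, t, e)


def evaluate_pairs(candidates: list[PairScore], expr: ExpressionMatrix,
                   clinical: ClinicalTable, fdr_thresh: float = 0.05,
                   screen_p: float = 0.1, apply_screen: bool = True,
                   horizons: tuple[float, ...] = (365.0, 1095.0, 1825.0),
                   ) -> list[PairPrognosis]:
    """Run the full prognostic chain over candidate pairs.

    screen → pair risk score → log-rank → covariate-adjusted Cox → BH FDR over
    the adjusted p-values of all evaluated pairs → time-dependent AUC.
    Per-pair failures drop that pair with a recorded reason; the batch never
    aborts.
    """
    genes = sorted({g for c in candidates for g in (c.driver, c.drg)})
    screen_table = univariate_screen_table(expr, clinical, genes)
    passed = set(screen_table.index[screen_table["p"] < screen_p])
    samples = [s for s in clinical.samples if s in set(expr.samples)]
    t_all = clinical.table.loc[samples, "os_time"].to_numpy()
    e_all = clinical.table.loc[samples, "os_event"].to_numpy()

    results: list[PairPrognosis] = []
    for cand in candidates:
        prog = PairPrognosis(driver=cand.driver, drg=cand.drg, category=cand.category)
        prog.screen_p = {
            g: float(screen_table.loc[g, "p"]) if g in screen_table.index else np.nan
            for g in (cand.driver, cand.drg)
        }
        if apply_screen and not {cand.driver, cand.drg} <= passed:
            prog.dropped = True
            prog.drop_reason = "failed univariate screen"
            results.append(prog)
            continue
        scored = pair_risk_score(expr, clinical, (cand.driver, cand.drg))
        scored.category = cand.category
        scored.screen_p = prog.screen_p
        prog = scored
        if prog.dropped:
            results.append(prog)
            continue
        try:
            chi2, p_lr = logrank_test(t_all, e_all, prog.risk_group.to_numpy())
            prog.logrank_chi2, prog.logrank_p = chi2, p_lr
        except ValueError as exc:
            prog.dropped = True
            prog.drop_reason = f"log-rank failed: {exc}"
            results.append(prog)
            continue
        try:
            adj = adjusted_cox(prog, clinical)
        except (ValueError, SingularInformationError) as exc:
            prog.dropped = True
            prog.drop_reason = f"adjusted Cox failed: {exc}"
            results.append(prog)
            continue
        i = adj.names.index("risk_high")
        prog.adjusted_hr = float(adj.hr[i])
        prog.adjusted_ci = (float(adj.hr_low[i]), float(adj.hr_high[i]))
        prog.adjusted_p = float(adj.p[i])
        for h in horizons:
            auc = td_auc(prog.risk_scores.to_numpy(), t_all, e_all, h)
            if auc is not None:
                prog.td_auc[h] = auc
        results.append(prog)

    evaluated = [r for r in results if not r.dropped]
    if evaluated:
        fdr = benjamini_hochberg([r.adjusted_p for r in evaluated])
        for r, q in zip(evaluated, fdr):
            r.fdr = float(q)
            r.flagged = bool(q < fdr_thresh)
    return results


def prognosis_frame(results: list[PairPrognosis]) -> pd.DataFrame:
    """Tabular mirror of the per-pair prognosis (one row per candidate)."""
    rows = []
    for r in results:
        row = {
            "driver": r.driver,
            "drg": r.drg,
            "category": r.category,
            "screen_p_driver": r.screen_p.get(r.driver, np.nan),
            "screen_p_drg": r.screen_p.get(r.drg, np.nan),
            "beta1": r.beta[0],
            "beta2": r.beta[1],
            "logrank_chi2": r.logrank_chi2,
            "logrank_p": r.logrank_p,
            "adjusted_hr": r.adjusted_hr,
            "adjusted_hr_low": r.adjusted_ci[0],
            "adjusted_hr_high": r.adjusted_ci[1],
            "adjusted_p": r.adjusted_p,
            "fdr": r.fdr,
            "flagged": r.flagged,
            "dropped": r.dropped,
            "drop_reason": r.drop_reason,
        }
        for h, a in r.td_auc.items():
            row[f"td_auc_{int(h)}"] = a
        rows.append(row)
    return pd.DataFrame(rows)
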