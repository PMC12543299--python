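"""Evaluation statistics: ROC/AUC edge recovery, group-to-individual
prediction with confidence bands, inclusion Bayes factors, heterogeneity,
discordance rates, and the simulation-experiment driver.

Edge recovery is scored with ROC curves on posterior inclusion
probabilities; the AUC equals the tie-corrected Mann-Whitney statistic.
The inclusion Bayes factor BF_e is the ratio of posterior to prior
inclusion odds; BF_e >= 3 counts as evidence for inclusion, <= 1/3 for
exclusion, anything between as insufficient.  The median probability
model keeps exactly the edges with posterior inclusion probability above
1/2 — with a prior probability of 1/2 that threshold is the BF_e = 1
point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .ggm import prepare_data
from .simulate import SimulationTruth, simulate_study

__all__ = [
    "RocCurve",
    "BandedRoc",
    "UndefinedAucError",
    "roc_auc",
    "individual_edge_auc",
    "group_edge_auc",
    "group_to_individual_roc",
    "inclusion_bf",
    "bf_category",
    "heterogeneity_variance",
    "discordance_rates",
    "recovery_experiment",
]

BF_INCLUDE = 3.0
BF_EXCLUDE = 1.0 / 3.0


class UndefinedAucError(ValueError):
    """Raised when labels contain a single class (no ROC curve exists)."""


@dataclass
class RocCurve:
    """One receiver operating characteristic: (fpr, tpr) path and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class BandedRoc:
    """Per-participant ROC curves vertically averaged on a common FPR grid.

    ``lower``/``upper`` are the pointwise 2.5%/97.5% quantiles of the
    per-participant TPRs; ``multimodal`` flags two separated bundles of
    curves (largest adjacent gap in the sorted AUCs exceeding five times
    the median adjacent gap).
    """

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    per_participant_auc: np.ndarray  # sorted ascending
    mean_auc: float
    multimodal: bool
    excluded: list[int]  # participants with single-class labels, 0-based


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve by threshold sweep; AUC by trapezoid.

    Tied scores collapse into a single threshold step, so the trapezoidal
    area equals the Mann-Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise UndefinedAucError("labels contain a single class; AUC undefined")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def individual_edge_auc(fit, truth: SimulationTruth, mode: str = "pooled") -> float:
    """AUC for recovering the individual-level edges.

    ``pooled`` throws all (participant, edge) pairs into one score/label
    set; ``averaged`` computes one AUC per participant and averages
    (participants whose true graph is single-class are skipped).  For the
    aggregate method the rows of ``individual_probs`` are copies of its
    single network.
    """
    probs = np.asarray(fit.individual_probs, dtype=float)
    y = np.asarray(truth.individual_graphs)
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {y.shape}")
    if mode == "pooled":
        return roc_auc(probs.ravel(), y.ravel()).auc
    if mode == "averaged":
        aucs = []
        for n in range(y.shape[0]):
            if y[n].min() != y[n].max():
                aucs.append(roc_auc(probs[n], y[n]).auc)
        if not aucs:
            raise UndefinedAucError("no participant has both edge classes")
        return float(np.mean(aucs))
    raise ValueError(f"unknown mode {mode!r}")


def group_edge_auc(fit, truth: SimulationTruth) -> float:
    """AUC for recovering the group-level graph from the group probabilities."""
    return roc_auc(np.asarray(fit.group_probs), truth.group_graph).auc


def _step_interp(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """TPR at each grid FPR: the largest TPR attained at fpr <= grid value."""
    idx = np.searchsorted(fpr, grid, side="right") - 1
    return tpr[np.clip(idx, 0, fpr.size - 1)]


def group_to_individual_roc(fit, threshold: float = 0.5) -> BandedRoc:
    """How well the group probabilities predict each thresholded individual net.

    Per participant, labels are the median-probability-model edges
    (individual inclusion probability > threshold) and scores are the
    group-level probabilities; the band is the pointwise 95% envelope of
    per-participant TPR on a 101-point FPR grid.  Distinct bundles of
    curves — the signature of an ignored subgroup structure — raise the
    ``multimodal`` flag.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(fit.group_probs, dtype=float)
    probs = np.asarray(fit.individual_probs, dtype=float)
    grid = np.linspace(0.0, 1.0, 101)
    tprs, aucs, excluded = [], [], []
    for n in range(probs.shape[0]):
        labels = (probs[n] > threshold).astype(int)
        if labels.min() == labels.max():
            excluded.append(n)
            continue
        curve = roc_auc(scores, labels)
        tprs.append(_step_interp(curve.fpr, curve.tpr, grid))
        aucs.append(curve.auc)
    if not tprs:
        raise UndefinedAucError("every participant had single-class labels")
    tprs = np.vstack(tprs)
    aucs = np.sort(np.asarray(aucs))
    gaps = np.diff(aucs)
    multimodal = bool(gaps.size and gaps.max() > 5.0 * np.median(gaps))
    return BandedRoc(
        fpr_grid=grid,
        mean_tpr=tprs.mean(axis=0),
        lower=np.quantile(tprs, 0.025, axis=0),
        upper=np.quantile(tprs, 0.975, axis=0),
        per_participant_auc=aucs,
        mean_auc=float(aucs.mean()),
        multimodal=multimodal,
        excluded=excluded,
    )


def inclusion_bf(posterior_prob: float, prior_prob: float) -> float:
    """Inclusion Bayes factor: posterior inclusion odds over prior odds."""
    if not (0.0 < prior_prob < 1.0):
        raise ValueError(f"prior probability must be in (0, 1), got {prior_prob}")
    if not (0.0 <= posterior_prob <= 1.0):
        raise ValueError(f"posterior probability must be in [0, 1]")
    prior_odds = prior_prob / (1.0 - prior_prob)
    if posterior_prob in (0.0, 1.0):
        warnings.warn(
            "posterior probability of exactly 0 or 1 reflects a finite number "
            "of MCMC draws; the Bayes factor is reported as 0 or inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0 if posterior_prob == 0.0 else np.inf
    return float(posterior_prob / (1.0 - posterior_prob) / prior_odds)


def bf_category(bf: float) -> str:
    """'include' (BF >= 3), 'exclude' (BF <= 1/3), else 'insufficient'."""
    if bf >= BF_INCLUDE:
        return "include"
    if bf <= BF_EXCLUDE:
        return "exclude"
    return "insufficient"


def heterogeneity_variance(individual_probs, group_probs) -> np.ndarray:
    """Per-edge variance of individual inclusion probabilities around the
    group probability (not the sample mean):
    var_e = mean_n (p_ne - g_e)^2, which exceeds the centered variance by
    (mean_n p_ne - g_e)^2."""
    p = np.asarray(individual_probs, dtype=float)
    g = np.asarray(group_probs, dtype=float)
    if p.ndim != 2 or p.shape[1] != g.shape[0]:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return ((p - g) ** 2).mean(axis=0)


def discordance_rates(individual_graphs, group_graph) -> tuple[float, float]:
    """Average rates of individual deviation from the group graph.

    extra_rate: mean over participants of the fraction of group-absent
    edges present in the individual graph; miss_rate: mean fraction of
    group-present edges absent individually.
    """
    G = np.atleast_2d(np.asarray(individual_graphs))
    g = np.asarray(group_graph)
    present = g == 1
    absent = ~present
    if not (present.any() and absent.any()):
        raise ValueError("group graph must have at least one present and one absent edge")
    extra = G[:, absent].mean(axis=1).mean()
    miss = (1 - G[:, present]).mean(axis=1).mean()
    return float(extra), float(miss)


def recovery_experiment(
    sim_configs,
    fit_config,
    methods=("multilevel", "individual", "aggregate"),
    reps: int = 1,
    out: str | None = None,
) -> pd.DataFrame:
    """Simulate -> fit -> score over a grid of study designs.

    ``sim_configs`` is an iterable of :class:`SimulationConfig` (one per
    grid cell); ``fit_config`` a base :class:`~mlggm.sampler.FitConfig`
    whose seed and method are replaced per (cell, rep, method).  Returns
    one tidy row per (cell, rep, method) with both AUCs; a failed cell is
    recorded with ``error`` set and the run continues.  Written as TSV
    when ``out`` is given.
    """
    from dataclasses import replace as _replace

    from .sampler import fit as run_fit  # local import avoids a cycle

    rows = []
    for cfg in sim_configs:
        for rep in range(reps):
            seed = int(
                np.random.SeedSequence(cfg.seed, spawn_key=(rep,)).generate_state(1)[0]
                % (2**31)
            )
            try:
                truth = simulate_study(_replace(cfg, seed=seed))
                data = [prepare_data(x) for x in truth.timeseries]
                for method in methods:
                    result = run_fit(
                        data, _replace(fit_config, method=method, seed=seed)
                    )
                    rows.append(
                        {
                            "T": cfg.T,
                            "N": cfg.N,
                            "rho": cfg.rho,
                            "rep": rep,
                            "method": method,
                            "auc_individual": individual_edge_auc(result, truth),
                            "auc_group": group_edge_auc(result, truth),
                            "seed": seed,
                            "error": "",
                        }
                    )
            except Exception as err:  # noqa: BLE001 - cell failures are logged
                rows.append(
                    {
                        "T": cfg.T,
                        "N": cfg.N,
                        "rho": cfg.rho,
                        "rep": rep,
                        "method": "",
                        "auc_individual": np.nan,
                        "auc_group": np.nan,
                        "seed": seed,
                        "error": f"{type(err).__name__}: {err}",
                    }
                )
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    return table
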