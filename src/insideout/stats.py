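"""Lag selection, permutation inference, ANOVA contracts and normality tests.

Three ways of fixing the lagged-correlation lag tau are provided: the area
under the r(tau) curve ("total" irreversibility, no single tau), the
orthogonal contrast (tau maximizing the grand-mean irreversibility across
all datasets), and counter-balanced cross-validation (tau maximizing the
drug-vs-control difference on training folds, scored on held-out folds).
Permutation p-values always use the (1 + exceedances) / (n_perm + 1)
convention and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import DatasetKey, ResultTable, StudyDesign
from .irreversibility import IrrevCurve

__all__ = [
    "TauSelection",
    "ClusterResult",
    "select_tau_orthogonal",
    "select_tau_crossval",
    "paired_permutation",
    "cluster_perm_over_tau",
    "rm_anova",
    "tukey_posthoc",
    "fdr_adjust",
    "normality_battery",
]


@dataclass
class TauSelection:
    approach: str
    tau_optimal: int
    fold_assignments: dict[str, int] = field(default_factory=dict)
    fold_taus: list[int] = field(default_factory=list)
    fold_stats: list[float] = field(default_factory=list)
    p_value: float | None = None


@dataclass
class ClusterResult:
    """Contiguous supra-threshold tau clusters with permutation p-values."""

    clusters: list[tuple[int, int]]  # inclusive tau-index ranges, ordered
    masses: list[float]
    p_values: list[float]
    taus: np.ndarray
    t_threshold: float


def _common_grid(curves: dict[DatasetKey, IrrevCurve]) -> np.ndarray:
    grids = [tuple(c.taus.tolist()) for c in curves.values()]
    if len(set(grids)) != 1:
        raise ValueError("curves are not on a common tau grid")
    return next(iter(curves.values())).taus


def select_tau_orthogonal(curves: dict[DatasetKey, IrrevCurve]) -> TauSelection:
    """Tau maximizing the grand mean of r(tau) across all datasets.

    Ties break to the smallest tau (np.argmax returns the first maximum on
    a strictly increasing grid).
    """
    taus = _common_grid(curves)
    grand = np.mean([c.values for c in curves.values()], axis=0)
    return TauSelection("orthogonal", int(taus[int(np.argmax(grand))]))


def _participant_fold_map(
    design: StudyDesign, n_folds: int, seed: int
) -> dict[str, int]:
    pids = list(design.participant_ids)
    if len(pids) % n_folds != 0:
        raise ValueError(
            f"{len(pids)} participants not divisible into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    per = len(pids) // n_folds
    return {pids[order[i]]: i // per for i in range(len(pids))}


def select_tau_crossval(
    curves: dict[DatasetKey, IrrevCurve],
    design: StudyDesign,
    n_folds: int = 8,
    n_perm: int = 1000,
    seed: int = 0,
    final_rule: str = "fold_winner",
) -> TauSelection:
    """Cross-validated tau maximizing the drug-vs-control difference.

    Folds group whole participants (all of a participant's drug x condition
    datasets stay together), so every fold is automatically drug- and
    condition-counter-balanced.  Per loop, the training folds give
    argmax_tau |mean_drug - mean_control|; the held-out fold's difference at
    that tau is recorded.  The final tau is the winning tau of the fold with
    the largest held-out difference (``final_rule='fold_winner'``) or the
    argmax of the mean held-out difference curve (``'pooled'``).
    Significance is a paired sign-flip permutation of per-participant
    drug-minus-control means at the selected tau.
    """
    taus = _common_grid(curves)
    fold_of = _participant_fold_map(design, n_folds, seed)
    control, drug = design.drug_levels
    per_fold_taus: list[int] = []
    per_fold_stats: list[float] = []
    arr = {k: c.values for k, c in curves.items()}

    def mean_curve(fold_pred, level):
        vals = [
            v
            for (pid, d, _), v in arr.items()
            if d == level and fold_pred(fold_of[pid])
        ]
        if not vals:
            raise ValueError("fold constraint unsatisfiable: empty drug cell")
        return np.mean(vals, axis=0)

    test_diffs = np.empty((n_folds, taus.size))
    for f in range(n_folds):
        train_diff = np.abs(
            mean_curve(lambda g: g != f, control) - mean_curve(lambda g: g != f, drug)
        )
        tau_f = int(taus[int(np.argmax(train_diff))])
        test_curve = np.abs(
            mean_curve(lambda g: g == f, control) - mean_curve(lambda g: g == f, drug)
        )
        test_diffs[f] = test_curve
        per_fold_taus.append(tau_f)
        per_fold_stats.append(float(test_curve[int(np.argmax(train_diff))]))
    if final_rule == "fold_winner":
        tau_optimal = per_fold_taus[int(np.argmax(per_fold_stats))]
    elif final_rule == "pooled":
        tau_optimal = int(taus[int(np.argmax(test_diffs.mean(axis=0)))])
    else:
        raise ValueError("final_rule must be 'fold_winner' or 'pooled'")
    # permutation significance at the selected tau
    ti = int(np.flatnonzero(taus == tau_optimal)[0])
    per_pid: dict[str, dict[str, list[float]]] = {}
    for (pid, d, _), v in arr.items():
        per_pid.setdefault(pid, {}).setdefault(d, []).append(float(v[ti]))
    a = np.array([np.mean(per_pid[p][control]) for p in design.participant_ids])
    b = np.array([np.mean(per_pid[p][drug]) for p in design.participant_ids])
    p = paired_permutation(a, b, n_perm=n_perm, seed=seed + 1)
    return TauSelection(
        "crossval",
        tau_optimal,
        fold_assignments=fold_of,
        fold_taus=per_fold_taus,
        fold_stats=per_fold_stats,
        p_value=p,
    )


def paired_permutation(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Sign-flip permutation test on paired differences.

    The statistic is |mean(a - b)| (or signed mean for one-sided
    alternatives); the null flips the sign of each pair's difference
    independently.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("a and b must be equal-length 1-D arrays with n >= 3")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} < 100: coarse p-value resolution")
    d = a - b
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null_means = (signs * d).mean(axis=1)
    if alternative == "two-sided":
        obs = abs(d.mean())
        null = np.abs(null_means)
    elif alternative == "greater":
        obs = d.mean()
        null = null_means
    elif alternative == "less":
        obs = -d.mean()
        null = -null_means
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return float((1 + np.sum(null >= obs)) / (n_perm + 1))


def cluster_perm_over_tau(
    a: np.ndarray,
    b: np.ndarray,
    taus: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test over the tau axis (paired design).

    ``a`` and ``b`` are n_subjects x n_taus curve stacks (e.g. control and
    drug within one condition).  Pointwise paired t statistics exceeding the
    two-sided alpha threshold form contiguous clusters whose mass is the sum
    of |t|; the null distribution is the maximum cluster mass under random
    within-subject sign flips of the difference curves.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be n_subjects x n_taus arrays")
    n, n_tau = a.shape
    taus = np.asarray(taus)
    if taus.size != n_tau:
        raise ValueError("taus length mismatch")
    if n_tau < 1:
        raise ValueError("tau grid too short")
    t_crit = float(scipy.stats.t.ppf(1 - alpha_cluster / 2, df=n - 1))
    d = a - b

    def tstats(diff: np.ndarray) -> np.ndarray:
        mean = diff.mean(axis=0)
        sd = diff.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return mean / (sd / np.sqrt(n))

    def clusters_of(t: np.ndarray) -> list[tuple[int, int, float]]:
        supra = np.abs(t) > t_crit
        out = []
        i = 0
        while i < n_tau:
            if supra[i]:
                j = i
                while j + 1 < n_tau and supra[j + 1]:
                    j += 1
                out.append((i, j, float(np.abs(t[i : j + 1]).sum())))
                i = j + 1
            else:
                i += 1
        return out

    obs = clusters_of(tstats(d))
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n, 1))
        perm_clusters = clusters_of(tstats(d * flips))
        null_max[p] = max((m for _, _, m in perm_clusters), default=0.0)
    clusters = [(i, j) for i, j, _ in obs]
    masses = [m for _, _, m in obs]
    pvals = [
        float((1 + np.sum(null_max >= m)) / (n_perm + 1)) for m in masses
    ]
    return ClusterResult(clusters, masses, pvals, taus, t_crit)


def _check_balanced(df: pd.DataFrame, factors: list[str]) -> None:
    counts = df.groupby(["participant"] + factors, observed=True).size()
    n_cells = 1
    for f in factors:
        n_cells *= df[f].nunique()
    by_subj = counts.groupby("participant", observed=True).size()
    if (counts != 1).any() or (by_subj != n_cells).any():
        raise ValueError(
            "unbalanced within-subject design: every participant needs "
            f"exactly one observation per {' x '.join(factors)} cell"
        )


def rm_anova(
    table: ResultTable | pd.DataFrame,
    metric_name: str | None = None,
    factors: tuple[str, ...] = ("drug", "condition"),
) -> pd.DataFrame:
    """Repeated-measures ANOVA with the given within-subject factors.

    Delegates the F computation to a standard within-subject ANOVA routine;
    this wrapper owns the balance checking and tidy output (columns factor,
    F, df1, df2, p).  Region may be included as a third factor when the
    table carries a ``region`` column.
    """
    df = table.df if isinstance(table, ResultTable) else table.copy()
    if metric_name is not None:
        df = df[df["metric_name"] == metric_name]
    if df.empty:
        raise ValueError("no rows to analyse")
    factors = list(factors)
    _check_balanced(df, factors)
    res = AnovaRM(
        data=df, depvar="value", subject="participant", within=factors
    ).fit()
    out = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    out.index.name = "factor"
    return out.reset_index()


def tukey_posthoc(
    table: ResultTable | pd.DataFrame,
    factor: str,
    metric_name: str | None = None,
) -> pd.DataFrame:
    """Tukey honest-significant-difference contrasts on one factor."""
    df = table.df if isinstance(table, ResultTable) else table.copy()
    if metric_name is not None:
        df = df[df["metric_name"] == metric_name]
    res = pairwise_tukeyhsd(df["value"].to_numpy(), df[factor].to_numpy())
    return pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def normality_battery(values, alpha: float = 0.05) -> pd.DataFrame:
    """Panel of normality tests with per-test verdicts and a majority row.

    Runs Shapiro-Wilk, D'Agostino K^2, Anderson-Darling and Jarque-Bera at
    the given alpha.  Anderson-Darling is judged against its tabulated
    critical value; the others against their p-values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("need at least 8 samples")
    if np.std(values) == 0:
        raise ValueError("degenerate (zero-variance) input")
    rows = []
    sw = scipy.stats.shapiro(values)
    rows.append(("shapiro_wilk", sw.statistic, sw.pvalue, sw.pvalue > alpha))
    k2 = scipy.stats.normaltest(values)
    rows.append(("dagostino_k2", k2.statistic, k2.pvalue, k2.pvalue > alpha))
    ad = scipy.stats.anderson(values, dist="norm", method="interpolate")
    rows.append(
        ("anderson_darling", ad.statistic, ad.pvalue, ad.pvalue > alpha)
    )
    jb = scipy.stats.jarque_bera(values)
    rows.append(("jarque_bera", jb.statistic, jb.pvalue, jb.pvalue > alpha))
    df = pd.DataFrame(rows, columns=["test", "statistic", "p", "normal"])
    majority = bool(df["normal"].sum() >= (len(df) + 1) // 2)
    df.attrs["majority_normal"] = majority
    return df
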