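"""Random-forest comparison of metric families for drug-vs-control decoding.

One observation per (participant, drug) session; the default feature vector
is the per-condition scalar metric (4 features in the study design), with a
regional mode (condition x region features) available.  Splits keep a
participant's two sessions on the same side of the train/test divide, so no
within-participant information leaks across the split; the non-safe
observation-level split is retained as an option for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .containers import DatasetKey, EnvelopeEpochs, ResultTable, StudyDesign
from .irreversibility import corr_matrices
from .stats import fdr_adjust

__all__ = [
    "FeatureTable",
    "undirected_fc",
    "mean_forward_xcorr",
    "build_features",
    "rf_evaluate",
    "rf_nested_tau",
    "compare_feature_sets",
]


@dataclass
class FeatureTable:
    """Observation x feature matrix with session labels."""

    X: np.ndarray
    y: np.ndarray  # 0 = control, 1 = drug
    participants: np.ndarray  # participant label per observation
    feature_names: list[str]
    feature_set: str

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.participants)):
            raise ValueError("X, y and participants must align")
        if np.any(self.X.std(axis=0) == 0):
            import warnings

            warnings.warn("zero-variance feature column(s) present")


def undirected_fc(env: EnvelopeEpochs) -> float:
    """Mean pairwise zero-lag Pearson correlation of the envelopes.

    Computed per epoch on demeaned envelopes and averaged across epochs;
    invariant to the direction of coupling by construction.
    """
    X = env.demeaned()
    vals = []
    for e in range(env.n_epochs):
        C = np.corrcoef(X[e])
        iu = np.triu_indices(env.n_regions, k=1)
        vals.append(C[iu].mean())
    return float(np.mean(vals))


def mean_forward_xcorr(env: EnvelopeEpochs, tau: int) -> float:
    """Mean forward lagged correlation across all region pairs."""
    X = env.demeaned()
    vals = []
    for e in range(env.n_epochs):
        Cf = corr_matrices(X[e], tau, labels=env.region_labels).Cf
        mask = ~np.eye(env.n_regions, dtype=bool)
        vals.append(Cf[mask].mean())
    return float(np.mean(vals))


def build_features(
    results: ResultTable,
    feature_set: str,
    design: StudyDesign,
    mode: str = "scalar",
) -> FeatureTable:
    """Pivot a long result table into an observation x feature matrix.

    Scalar mode yields one feature per condition; regional mode one per
    (condition, region) and requires a ``region`` column in the table.
    """
    df = results.df[results.df["metric_name"] == feature_set]
    if df.empty:
        raise ValueError(f"no rows for metric {feature_set!r}")
    if mode == "scalar":
        wide = df.pivot_table(
            index=["participant", "drug"], columns="condition", values="value"
        )
    elif mode == "regional":
        if "region" not in df.columns:
            raise ValueError("regional mode needs a 'region' column")
        wide = df.pivot_table(
            index=["participant", "drug"], columns=["condition", "region"],
            values="value",
        )
    else:
        raise ValueError("mode must be 'scalar' or 'regional'")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing grid cells for observations {missing[:5]}")
    control, drug = design.drug_levels
    participants = wide.index.get_level_values("participant").to_numpy()
    y = np.asarray(wide.index.get_level_values("drug") == drug, dtype=int)
    names = [
        "_".join(map(str, c)) if isinstance(c, tuple) else str(c)
        for c in wide.columns
    ]
    return FeatureTable(
        X=wide.to_numpy(float), y=y, participants=participants,
        feature_names=names, feature_set=feature_set,
    )


def _participant_split(pids: np.ndarray, train_frac: float, rng) -> np.ndarray:
    """Boolean train mask keeping each participant's sessions together."""
    unique = np.unique(pids)
    n_train = max(1, min(unique.size - 1, round(train_frac * unique.size)))
    train_pids = rng.permutation(unique)[:n_train]
    return np.isin(pids, train_pids)


def rf_evaluate(
    features: FeatureTable,
    n_runs: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    n_trees: int = 100,
    leakage_safe: bool = True,
) -> np.ndarray:
    """Held-out AUROC distribution over repeated 80/20 splits.

    Splits depend only on (seed, run), never on the feature values, so runs
    are paired across feature sets evaluated with the same seed.
    """
    if len(features.y) < 8:
        raise ValueError("too few observations to split")
    aurocs = np.empty(n_runs)
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, run)))
        if leakage_safe:
            train = _participant_split(features.participants, train_frac, rng)
        else:
            train = np.zeros(len(features.y), dtype=bool)
            train[rng.permutation(len(features.y))[: round(train_frac * len(features.y))]] = True
        y_test = features.y[~train]
        if len(np.unique(y_test)) < 2 or len(np.unique(features.y[train])) < 2:
            aurocs[run] = np.nan  # degenerate split (possible for shuffled labels)
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31))
        )
        clf.fit(features.X[train], features.y[train])
        prob = clf.predict_proba(features.X[~train])[:, list(clf.classes_).index(1)]
        aurocs[run] = roc_auc_score(y_test, prob)
    return aurocs


def rf_nested_tau(
    metric_curves: dict[DatasetKey, np.ndarray],
    tau_grid: np.ndarray,
    design: StudyDesign,
    n_runs: int = 100,
    train_frac: float = 0.8,
    inner_folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Nested cross-validation: the inner loop selects the lag tau.

    ``metric_curves`` maps each dataset to its metric evaluated on the full
    ``tau_grid``.  Per outer run the training participants undergo
    ``inner_folds``-fold CV at every tau; the tau maximizing mean inner
    AUROC (ties: smallest tau) is used for the outer holdout model.
    Returns (AUROC per run, chosen tau per run).
    """
    tau_grid = np.asarray(tau_grid)
    if tau_grid.size == 0:
        raise ValueError("empty tau grid")
    control, drug = design.drug_levels
    pids = np.array(
        [p for p in design.participant_ids for _ in range(2)]
    )
    y = np.tile([0, 1], len(design.participant_ids))
    # features[t] : observations x conditions at tau_grid[t]
    feats = np.empty((tau_grid.size, len(y), len(design.condition_levels)))
    for i, pid in enumerate(design.participant_ids):
        for d_idx, level in enumerate((control, drug)):
            for c_idx, cond in enumerate(design.condition_levels):
                feats[:, 2 * i + d_idx, c_idx] = metric_curves[(pid, level, cond)]
    aurocs = np.empty(n_runs)
    chosen = np.empty(n_runs, dtype=int)
    unique_pids = np.array(design.participant_ids)
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, run)))
        train = _participant_split(pids, train_frac, rng)
        train_pids = np.unique(pids[train])
        fold_of = {
            p: k % inner_folds
            for k, p in enumerate(rng.permutation(train_pids))
        }
        inner_scores = np.zeros(tau_grid.size)
        for t in range(tau_grid.size):
            scores = []
            for fold in range(inner_folds):
                val_mask = train & np.isin(
                    pids, [p for p, f in fold_of.items() if f == fold]
                )
                fit_mask = train & ~val_mask
                if val_mask.sum() == 0 or len(np.unique(y[val_mask])) < 2:
                    continue
                clf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=int(rng.integers(2**31))
                )
                clf.fit(feats[t][fit_mask], y[fit_mask])
                prob = clf.predict_proba(feats[t][val_mask])[
                    :, list(clf.classes_).index(1)
                ]
                scores.append(roc_auc_score(y[val_mask], prob))
            inner_scores[t] = np.mean(scores) if scores else -np.inf
        best = int(np.argmax(inner_scores))
        chosen[run] = int(tau_grid[best])
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31))
        )
        clf.fit(feats[best][train], y[train])
        prob = clf.predict_proba(feats[best][~train])[:, list(clf.classes_).index(1)]
        aurocs[run] = roc_auc_score(y[~train], prob)
    return aurocs, chosen


def compare_feature_sets(reports: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests on paired AUROC vectors, with FDR.

    Runs must be paired (same split seeds across feature sets).  The output
    median difference column is antisymmetric under swapping the pair.
    """
    names = list(reports)
    lengths = {len(v) for v in reports.values()}
    if len(lengths) != 1:
        raise ValueError("unpaired runs: AUROC vectors differ in length")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = reports[a] - reports[b]
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = scipy.stats.wilcoxon(reports[a], reports[b])
            rows.append(
                dict(
                    set_a=a, set_b=b, median_diff=float(np.median(diff)),
                    statistic=float(stat), p=float(p),
                )
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = fdr_adjust(df["p"].to_numpy())
    return df
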