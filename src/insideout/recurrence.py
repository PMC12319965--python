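"""Sliding-window metric dynamics, time-delay embedding, recurrence networks.

The static hierarchy metrics are re-estimated in short overlapping windows
to obtain a 1-D metric timeseries per dataset.  The timeseries is embedded
in a delay space whose delay is the first minimum of the delayed mutual
information and whose dimension minimizes the false-nearest-neighbour
count.  A recurrence network connects embedded timepoints closer than the
smallest distance threshold at which the network becomes connected
(Eroglu's criterion); its edge density is the recurrence rate.  Coherent
phase-randomization surrogates destroy the temporal evolution of the
metric while preserving the envelope cross-spectra, giving a "static null"
for recurrence-rate comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph
import scipy.spatial.distance

from .containers import DatasetKey, EnvelopeEpochs, StudyDesign
from .hierarchy import profile_from_matrices
from .irreversibility import corr_matrices, irrev_matrix, thresholded_mean

__all__ = [
    "MetricTimeseries",
    "Embedding",
    "RecurrenceNet",
    "sliding_metric",
    "mi_delay",
    "fnn_dimension",
    "build_embedding",
    "recurrence_network",
    "coherent_phase_surrogate",
    "dataset_recurrence_rate",
    "dynamics_compare",
]

METRICS = ("irreversibility", "coherence", "inhomogeneity")


@dataclass
class MetricTimeseries:
    values: np.ndarray
    times: np.ndarray  # window start times, seconds from recording onset
    epoch_index: np.ndarray  # source epoch per window
    metric: str
    window_s: float
    overlap: float


@dataclass
class Embedding:
    """Delay embedding: rows are [x(t), x(t+tau), ..., x(t+(m-1) tau)]."""

    tau: int  # delay in windows
    m: int  # dimension
    points: np.ndarray

    def __post_init__(self) -> None:
        if not (1 <= self.m <= 10):
            raise ValueError("embedding dimension must be in [1, 10]")


@dataclass
class RecurrenceNet:
    epsilon: float
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    recurrence_rate: float


def _window_metric(win: np.ndarray, metric: str, tau: int, percentile: float) -> float:
    win = win - win.mean(axis=1, keepdims=True)
    m = corr_matrices(win, tau)
    if metric == "irreversibility":
        R = irrev_matrix(m)
        iu = np.triu_indices(R.shape[0], k=1)
        return thresholded_mean(R[iu], percentile)
    prof = profile_from_matrices(m, percentile, mode="absolute")
    if metric == "coherence":
        return prof.coherence
    if metric == "inhomogeneity":
        return prof.inhomogeneity
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def sliding_metric(
    env: EnvelopeEpochs,
    metric: str,
    tau: int,
    percentile: float = 95.0,
    window_s: float = 1.0,
    overlap: float = 0.8,
) -> MetricTimeseries:
    """Metric evaluated in overlapping windows that never straddle epochs.

    Step = window_s * (1 - overlap).  Epochs are temporally discontinuous
    (artifact rejection removes segments), so windows are confined to
    single epochs and the per-epoch window blocks are concatenated in
    recording order.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    win = round(env.fs * window_s)
    if win > env.n_samples:
        raise ValueError(f"window ({win} samples) longer than epoch ({env.n_samples})")
    if tau >= win:
        raise ValueError(f"tau={tau} must be < window length {win}")
    step = max(1, round(win * (1.0 - overlap)))
    starts = np.arange(0, env.n_samples - win + 1, step)
    values, times, epoch_idx = [], [], []
    for e in range(env.n_epochs):
        for s in starts:
            values.append(
                _window_metric(env.values[e, :, s : s + win], metric, tau, percentile)
            )
            times.append(e * env.epoch_length_s + s / env.fs)
            epoch_idx.append(e)
    return MetricTimeseries(
        np.asarray(values), np.asarray(times), np.asarray(epoch_idx),
        metric, window_s, overlap,
    )


def _hist_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    pxy, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = pxy / pxy.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    return float(
        np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz]))
    )


def mi_delay(
    ts: np.ndarray | MetricTimeseries, max_delay: int | None = None, bins: int = 10
) -> int:
    """First local minimum of the delayed mutual information.

    MI is estimated with equal-width histograms between x(t) and
    x(t + tau) for tau = 1 .. max_delay (default: half the series length).
    The self-information at tau = 0 serves as the left neighbour of the
    first lag.  If no local minimum exists, the global argmin is returned
    with a warning.
    """
    x = ts.values if isinstance(ts, MetricTimeseries) else np.asarray(ts, float)
    if np.std(x) == 0:
        raise ValueError("constant series: mutual information undefined")
    n = x.size
    if max_delay is None:
        max_delay = n // 2
    max_delay = int(min(max_delay, n - 2))
    if max_delay < 1:
        raise ValueError("series too short for delay scan")
    mi = np.empty(max_delay + 1)
    mi[0] = _hist_mi(x, x, bins)
    for tau in range(1, max_delay + 1):
        mi[tau] = _hist_mi(x[:-tau], x[tau:], bins)
    for tau in range(1, max_delay):
        if mi[tau] < mi[tau - 1] and mi[tau] < mi[tau + 1]:
            return tau
    warnings.warn("no local minimum of mutual information; using global argmin")
    return int(np.argmin(mi[1:]) + 1)


def build_embedding(ts: np.ndarray | MetricTimeseries, tau: int, m: int) -> Embedding:
    x = ts.values if isinstance(ts, MetricTimeseries) else np.asarray(ts, float)
    n_points = x.size - (m - 1) * tau
    if n_points < 2:
        raise ValueError("series too short for this embedding")
    points = np.column_stack([x[i * tau : i * tau + n_points] for i in range(m)])
    return Embedding(tau=tau, m=m, points=points)


def fnn_dimension(
    ts: np.ndarray | MetricTimeseries,
    tau: int,
    m_max: int = 10,
    ratio: float = 2.0,
    tol: float | None = None,
) -> int:
    """Embedding dimension minimizing the false-nearest-neighbour count.

    For each m, every point's nearest neighbour in dimension m is found;
    the pair is a false neighbour if their distance in dimension m + 1
    exceeds ``ratio`` times their distance in dimension m.  The default
    selection is the argmin of the false-neighbour count (ties break to the
    smallest m).  Because the count typically keeps creeping downward with
    m on chaotic data, ``tol`` offers the common plateau rule instead: the
    smallest m whose false-neighbour *fraction* is at most ``tol``.
    """
    x = ts.values if isinstance(ts, MetricTimeseries) else np.asarray(ts, float)
    counts, fractions = fnn_counts(x, tau, m_max, ratio)
    if tol is not None:
        below = [m + 1 for m, f in enumerate(fractions) if f <= tol]
        if below:
            return below[0]
    return int(np.argmin(counts) + 1)


def fnn_counts(
    x: np.ndarray, tau: int, m_max: int = 10, ratio: float = 2.0
) -> tuple[list[int], list[float]]:
    """False-nearest-neighbour counts and fractions for m = 1 .. m_max - 1."""
    x = np.asarray(x, dtype=float)
    counts: list[int] = []
    fractions: list[float] = []
    for m in range(1, m_max):
        n_pts = x.size - m * tau  # points that exist in both m and m+1
        if n_pts < 3:
            if not counts:
                raise ValueError("series too short for FNN scan")
            break
        emb_lo = build_embedding(x, tau, m).points[:n_pts]
        emb_hi = build_embedding(x, tau, m + 1).points[:n_pts]
        D = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(emb_lo)
        )
        np.fill_diagonal(D, np.inf)
        nn = np.argmin(D, axis=1)
        d_lo = D[np.arange(n_pts), nn]
        d_hi = np.linalg.norm(emb_hi - emb_hi[nn], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            false = np.where(d_lo > 0, d_hi > ratio * d_lo, d_hi > 0)
        counts.append(int(false.sum()))
        fractions.append(false.sum() / n_pts)
    return counts, fractions


def recurrence_network(points: np.ndarray | Embedding) -> RecurrenceNet:
    """Recurrence network at the smallest threshold giving a connected graph.

    Candidate thresholds are the sorted unique pairwise Euclidean
    distances; epsilon* is the smallest candidate at which the graph with
    edges {distance <= epsilon*, i != j} is one connected component.  The
    recurrence rate is the edge density 2E / (T (T - 1)).
    """
    pts = points.points if isinstance(points, Embedding) else np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    T = pts.shape[0]
    if T < 2:
        raise ValueError("need at least two points")
    D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(pts))
    cands = np.unique(D[np.triu_indices(T, k=1)])

    def connected(eps: float) -> bool:
        adj = (D <= eps) & ~np.eye(T, dtype=bool)
        n_comp, _ = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(adj), directed=False
        )
        return n_comp == 1

    lo, hi = 0, cands.size - 1
    if not connected(cands[hi]):  # pragma: no cover - complete graph is connected
        raise RuntimeError("graph not connected at the largest distance")
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(cands[mid]):
            hi = mid
        else:
            lo = mid + 1
    eps = float(cands[lo])
    adj = ((D <= eps) & ~np.eye(T, dtype=bool)).astype(int)
    rr = float(adj.sum() / (T * (T - 1)))
    return RecurrenceNet(epsilon=eps, adjacency=adj, recurrence_rate=rr)


def coherent_phase_surrogate(
    env: EnvelopeEpochs,
    method: str = "common_phase",
    seed: int = 0,
    ridge: float = 1e-12,
) -> EnvelopeEpochs:
    """Phase-randomized surrogate envelopes, coherent across channels.

    ``common_phase`` multiplies one random phase per frequency into every
    channel's spectrum, preserving all sample cross-spectra (and hence the
    circular cross-correlation function) exactly.  ``cholesky_csd`` draws
    new realizations from randomly-phased Cholesky factors of the epoch-
    averaged cross-spectral density, preserving cross-spectra in
    expectation; a singular CSD is ridge-regularized with a logged delta.
    """
    if env.n_samples < 8:
        raise ValueError("epochs too short for phase randomization")
    rng = np.random.default_rng(seed)
    n = env.n_samples
    n_freq = n // 2 + 1
    out = np.empty_like(env.values)
    if method == "common_phase":
        for e in range(env.n_epochs):
            F = np.fft.rfft(env.values[e], axis=1)
            rot = np.ones(n_freq, dtype=complex)
            hi = n_freq - 1 if n % 2 == 0 else n_freq
            rot[1:hi] = np.exp(2j * np.pi * rng.random(hi - 1))
            if n % 2 == 0:
                rot[-1] = rng.choice([-1.0, 1.0])
            out[e] = np.fft.irfft(F * rot, n=n, axis=1)
    elif method == "cholesky_csd":
        F_all = np.fft.rfft(env.values, axis=2)  # epochs x regions x freq
        for e in range(env.n_epochs):
            F = F_all[e]
            sur = np.empty((env.n_regions, n_freq), dtype=complex)
            sur[:, 0] = F[:, 0].real  # keep the mean level
            for f in range(1, n_freq):
                # epoch-averaged CSD stabilizes the factorization
                S = np.einsum(
                    "ei,ej->ij", F_all[:, :, f], np.conj(F_all[:, :, f])
                ) / env.n_epochs
                S = 0.5 * (S + S.conj().T)
                base = max(np.trace(S).real / env.n_regions, np.finfo(float).tiny)
                Lc = None
                for delta in (ridge * base, 1e-8 * base, 1e-6 * base,
                              1e-4 * base, 1e-2 * base):
                    try:
                        Lc = np.linalg.cholesky(S + delta * np.eye(env.n_regions))
                        break
                    except np.linalg.LinAlgError:
                        continue
                if Lc is None:
                    raise np.linalg.LinAlgError(f"CSD not factorizable at bin {f}")
                if delta > ridge * base:
                    warnings.warn(
                        f"singular CSD at bin {f}: ridge delta={delta:.3g}"
                    )
                z = np.exp(2j * np.pi * rng.random(env.n_regions))
                if n % 2 == 0 and f == n_freq - 1:
                    z = rng.choice([-1.0, 1.0], size=env.n_regions).astype(complex)
                sur[:, f] = Lc @ z
            out[e] = np.fft.irfft(sur, n=n, axis=1)
    else:
        raise ValueError("method must be 'common_phase' or 'cholesky_csd'")
    return EnvelopeEpochs(out, env.fs, env.region_labels, env.epoch_length_s)


def dataset_recurrence_rate(
    env: EnvelopeEpochs,
    metric: str,
    tau: int,
    percentile: float = 95.0,
    window_s: float = 1.0,
    overlap: float = 0.8,
    max_delay: int | None = None,
    m_max: int = 6,
) -> float:
    """Full dynamics path for one dataset: windows -> embedding -> RR."""
    ts = sliding_metric(env, metric, tau, percentile, window_s, overlap)
    tau_rn = mi_delay(ts, max_delay=max_delay)
    m = fnn_dimension(ts, tau_rn, m_max=m_max)
    emb = build_embedding(ts, tau_rn, m)
    return recurrence_network(emb).recurrence_rate


def dynamics_compare(
    datasets: dict[DatasetKey, EnvelopeEpochs],
    design: StudyDesign,
    metric: str = "irreversibility",
    tau: int = 5,
    percentile: float = 95.0,
    surrogate_method: str = "common_phase",
    n_surrogates: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    **rr_kwargs,
):
    """Recurrence rates for true and surrogate series, with paired tests.

    Returns a tidy DataFrame of per-dataset recurrence rates (columns
    participant, drug, condition, rr_true, rr_surrogate) and a dict of
    per-condition paired-permutation p-values for both series, enabling the
    true-vs-static-null significance comparison.
    """
    import pandas as pd

    from .stats import paired_permutation

    ss = np.random.SeedSequence(seed)
    rows = []
    for k_idx, (key, env) in enumerate(sorted(datasets.items())):
        pid, drug, cond = key
        rr_true = dataset_recurrence_rate(env, metric, tau, percentile, **rr_kwargs)
        sur_seeds = np.random.SeedSequence((seed, k_idx)).generate_state(n_surrogates)
        rr_sur = float(
            np.mean(
                [
                    dataset_recurrence_rate(
                        coherent_phase_surrogate(env, surrogate_method, int(s)),
                        metric, tau, percentile, **rr_kwargs,
                    )
                    for s in sur_seeds
                ]
            )
        )
        rows.append(
            dict(participant=pid, drug=drug, condition=cond,
                 rr_true=rr_true, rr_surrogate=rr_sur)
        )
    df = pd.DataFrame(rows)
    control, drug = design.drug_levels
    pvals = {}
    for cond in design.condition_levels:
        sub = df[df["condition"] == cond].pivot(
            index="participant", columns="drug", values=["rr_true", "rr_surrogate"]
        )
        for which in ("rr_true", "rr_surrogate"):
            a = sub[(which, control)].to_numpy()
            b = sub[(which, drug)].to_numpy()
            pvals[(cond, which)] = paired_permutation(
                a, b, n_perm=n_perm, seed=int(ss.generate_state(1)[0]) % (2**31)
            )
    return df, pvals
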