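"""Time-reversal irreversibility of lagged correlations.

The central quantity is the squared difference between the lagged
correlation matrix of the forward timeseries and that of the time-reversed
timeseries,

    R(tau) = (Cf(tau) - Cr(tau))^{\\circ 2},

evaluated per epoch on demeaned amplitude envelopes and averaged across
epochs.  Because reversing both series and lagging one of them is the same
as lagging the other series forward, ``Cr`` equals ``Cf`` transposed; the
explicit-reversal estimator is retained as a debug path and tested against
the transpose identity rather than assumed.

A stationary, time-reversible process (e.g. any process whose lagged
cross-correlations are symmetric under exchange of the two series) has
R = 0 in expectation; directed coupling makes R positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeEpochs

__all__ = [
    "LaggedCorrMatrices",
    "IrrevResult",
    "IrrevCurve",
    "lagged_corr",
    "corr_matrices",
    "reversed_corr_matrices",
    "irrev_matrix",
    "regional_irrev",
    "thresholded_mean",
    "dataset_irrev",
    "partial_corr_matrices",
    "irrev_curve",
]


@dataclass
class LaggedCorrMatrices:
    """Forward and time-reversed lagged correlation matrices at one lag.

    ``Cf[i, j]`` is the normalized lagged correlation with region *i*
    leading region *j* by ``tau_samples`` samples; ``Cr`` is the
    time-reversed counterpart (equal to ``Cf.T``).
    """

    Cf: np.ndarray
    Cr: np.ndarray
    tau_samples: int

    def __post_init__(self) -> None:
        self.Cf = np.asarray(self.Cf, dtype=float)
        self.Cr = np.asarray(self.Cr, dtype=float)
        if self.Cf.shape != self.Cr.shape or self.Cf.ndim != 2:
            raise ValueError("Cf and Cr must be square matrices of equal shape")
        if self.tau_samples < 0:
            raise ValueError("tau_samples must be >= 0")


@dataclass
class IrrevResult:
    """Dataset-level irreversibility summary at one lag."""

    R: np.ndarray  # epoch-averaged N x N irreversibility matrix
    r: float  # thresholded mean over the off-diagonal upper triangle
    r_region: np.ndarray  # per-region thresholded means
    tau_samples: int
    percentile: float


@dataclass
class IrrevCurve:
    """Irreversibility r(tau) over a lag grid, with its integral."""

    taus: np.ndarray  # lags in samples, strictly increasing
    values: np.ndarray  # r(tau)
    fs: float
    total: float  # trapezoidal area over tau expressed in seconds

    def argmax_tau(self) -> int:
        """Lag (samples) maximizing r(tau); ties broken to the smallest lag."""
        return int(self.taus[int(np.argmax(self.values))])


def _check_variance(sumsq: np.ndarray, labels=None) -> None:
    zero = np.flatnonzero(sumsq <= 0)
    if zero.size:
        names = (
            [labels[i] for i in zero] if labels is not None else zero.tolist()
        )
        raise ValueError(f"zero-variance region(s): {names}")


def lagged_corr(x: np.ndarray, y: np.ndarray, tau: int) -> float:
    """Normalized lagged correlation of demeaned series at lag ``tau``.

    Computes ``sum_t x(t) y(t+tau) / sqrt(sum x^2 * sum y^2)`` with the
    overlap sum truncated at the series end and a fixed denominator, so the
    zero-lag autocorrelation of any series is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if not (0 <= tau <= n - 1):
        raise ValueError(f"tau={tau} outside [0, {n - 1}]")
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    if denom == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.dot(x[: n - tau], y[tau:]) / denom)


def corr_matrices(
    epoch: np.ndarray,
    tau: int,
    labels=None,
    circular: bool = False,
) -> LaggedCorrMatrices:
    """Lagged correlation matrices of a demeaned epoch (regions x samples).

    ``Cr`` is computed as the transpose of ``Cf`` (exact under this
    estimator); :func:`reversed_corr_matrices` provides the independent
    explicit-reversal path for verification.

    With ``circular=True`` the overlap sum wraps around (periodic lag), the
    form preserved exactly by phase-randomization surrogates.
    """
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be (n_regions, n_samples)")
    n_regions, n = X.shape
    if not (1 <= tau <= n - 1):
        raise ValueError(f"tau={tau} outside [1, {n - 1}]")
    sumsq = np.sum(X**2, axis=1)
    _check_variance(sumsq, labels)
    denom = np.sqrt(np.outer(sumsq, sumsq))
    if circular:
        F = np.fft.rfft(X, axis=1)
        # cross-covariance c_ij(tau) = IFFT(conj(F_i) * F_j)[tau]
        cross = np.fft.irfft(np.conj(F[:, None, :]) * F[None, :, :], n=n, axis=2)
        Cf = cross[:, :, tau] / denom
    else:
        Cf = (X[:, : n - tau] @ X[:, tau:].T) / denom
    return LaggedCorrMatrices(Cf=Cf, Cr=Cf.T.copy(), tau_samples=tau)


def reversed_corr_matrices(epoch: np.ndarray, tau: int, labels=None) -> np.ndarray:
    """Time-reversed lagged correlation matrix by explicitly reversing.

    Debug/verification path: reverses every region's series in time and
    applies the forward estimator.  Agrees with ``corr_matrices(...).Cr``
    (the transpose) to floating-point tolerance.
    """
    X = np.asarray(epoch, dtype=float)[:, ::-1]
    n = X.shape[1]
    sumsq = np.sum(X**2, axis=1)
    _check_variance(sumsq, labels)
    denom = np.sqrt(np.outer(sumsq, sumsq))
    return (X[:, : n - tau] @ X[:, tau:].T) / denom


def irrev_matrix(m: LaggedCorrMatrices) -> np.ndarray:
    """Elementwise squared difference (Cf - Cr)^2; symmetric, zero diagonal."""
    R = (m.Cf - m.Cr) ** 2
    np.fill_diagonal(R, 0.0)
    return R


def regional_irrev(m: LaggedCorrMatrices, region: int) -> np.ndarray:
    """Squared forward-vs-reversed row difference for one region.

    Returns the off-diagonal entries of the region's row of R, i.e. the
    irreversibility of every connection involving the region.
    """
    n = m.Cf.shape[0]
    if not (0 <= region < n):
        raise IndexError(f"region {region} out of range [0, {n})")
    diff = (m.Cf[region] - m.Cr[region]) ** 2
    return np.delete(diff, region)


def thresholded_mean(values: np.ndarray, percentile: float) -> float:
    """Mean of entries strictly above the array's own empirical percentile.

    Linear-interpolation percentile; ties at the threshold are dropped.  If
    no entry survives (e.g. a constant array), falls back to the plain mean.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    thr = np.percentile(values, percentile)
    survivors = values[values > thr]
    if survivors.size == 0:
        return float(values.mean())
    return float(survivors.mean())


def _epoch_summaries(
    R: np.ndarray, percentile: float, threshold_mode: str
) -> tuple[float, np.ndarray]:
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = R[iu]
    mask = ~np.eye(n, dtype=bool)
    if threshold_mode == "none":
        r = float(upper.mean())
        r_region = np.array([R[i][mask[i]].mean() for i in range(n)])
    else:
        r = thresholded_mean(upper, percentile)
        r_region = np.array(
            [thresholded_mean(R[i][mask[i]], percentile) for i in range(n)]
        )
    return r, r_region


def dataset_irrev(
    env: EnvelopeEpochs,
    tau: int,
    percentile: float = 95.0,
    threshold_mode: str = "survivors",
    partial: bool = False,
) -> IrrevResult:
    """Dataset irreversibility: per-epoch R, thresholded means, epoch average.

    Whole-brain ``r`` uses the upper triangle only (R is symmetric);
    regional values use each region's full off-diagonal row.
    """
    if env.n_epochs < 1:
        raise ValueError("need at least one epoch")
    if tau >= env.n_samples:
        raise ValueError(f"tau={tau} >= n_samples={env.n_samples}")
    X = env.demeaned()
    rs, regs, Rs = [], [], []
    for e in range(env.n_epochs):
        if partial:
            m = partial_corr_matrices(X[e], tau, labels=env.region_labels)
        else:
            m = corr_matrices(X[e], tau, labels=env.region_labels)
        R = irrev_matrix(m)
        r_e, reg_e = _epoch_summaries(R, percentile, threshold_mode)
        rs.append(r_e)
        regs.append(reg_e)
        Rs.append(R)
    return IrrevResult(
        R=np.mean(Rs, axis=0),
        r=float(np.mean(rs)),
        r_region=np.mean(regs, axis=0),
        tau_samples=tau,
        percentile=percentile,
    )


def partial_corr_matrices(
    epoch: np.ndarray, tau: int, labels=None, cond_max: float = 1e10
) -> LaggedCorrMatrices:
    """Lagged *partial* correlation matrices: confounds regressed out.

    For each ordered pair (i, j), region i at time t and region j at time
    t + tau are each regressed on the contemporaneous values of all other
    regions over the overlap window; the residuals are then correlated.
    With only two regions there are no confounds and the result equals
    :func:`corr_matrices`.
    """
    X = np.asarray(epoch, dtype=float)
    n_regions, n = X.shape
    if n - tau <= n_regions:
        raise ValueError(
            f"overlap window n-tau={n - tau} too short for {n_regions} regions"
        )
    sumsq = np.sum(X**2, axis=1)
    _check_variance(sumsq, labels)
    if n_regions == 2:
        return corr_matrices(X, tau, labels=labels)
    Cf = np.zeros((n_regions, n_regions))
    head = X[:, : n - tau]  # region values at t
    tail = X[:, tau:]  # region values at t + tau
    for i in range(n_regions):
        for j in range(n_regions):
            if i == j:
                Cf[i, j] = lagged_corr(X[i], X[j], tau)
                continue
            others = [k for k in range(n_regions) if k not in (i, j)]
            Zi = head[others].T
            Zj = tail[others].T
            for Z in (Zi, Zj):
                if np.linalg.cond(Z) > cond_max:
                    raise np.linalg.LinAlgError(
                        "ill-conditioned confound regressors "
                        f"(cond > {cond_max:g}) for pair ({i}, {j})"
                    )
            xi = head[i]
            yj = tail[j]
            ri = xi - Zi @ np.linalg.lstsq(Zi, xi, rcond=None)[0]
            rj = yj - Zj @ np.linalg.lstsq(Zj, yj, rcond=None)[0]
            denom = np.sqrt(np.sum(ri**2) * np.sum(rj**2))
            if denom == 0:
                raise ValueError(f"zero residual variance for pair ({i}, {j})")
            Cf[i, j] = float(np.dot(ri, rj) / denom)
    return LaggedCorrMatrices(Cf=Cf, Cr=Cf.T.copy(), tau_samples=tau)


def irrev_curve(
    env: EnvelopeEpochs,
    percentile: float = 95.0,
    taus: np.ndarray | None = None,
    threshold_mode: str = "survivors",
) -> IrrevCurve:
    """r(tau) over a lag grid plus the trapezoidal 'total irreversibility'.

    By default the grid is every positive lag 1 .. n_samples - 1; a 2-s
    epoch at 200 Hz therefore admits 399 lags.  The area is taken over tau
    expressed in seconds.
    """
    if taus is None:
        taus = np.arange(1, env.n_samples)
    taus = np.asarray(taus, dtype=int)
    if taus.size < 2:
        raise ValueError("need at least two lags for a curve")
    if np.any(np.diff(taus) <= 0):
        raise ValueError("tau grid must be strictly increasing")
    X = env.demeaned()
    n = env.n_samples
    sumsq = np.sum(X**2, axis=2)
    _check_variance(sumsq.min(axis=0), env.region_labels)
    denoms = np.sqrt(sumsq[:, :, None] * sumsq[:, None, :])
    values = np.empty(taus.size)
    for k, tau in enumerate(taus):
        rs = []
        for e in range(env.n_epochs):
            Cf = (X[e, :, : n - tau] @ X[e, :, tau:].T) / denoms[e]
            R = (Cf - Cf.T) ** 2
            np.fill_diagonal(R, 0.0)
            r_e, _ = _epoch_summaries(R, percentile, threshold_mode)
            rs.append(r_e)
        values[k] = np.mean(rs)
    total = float(np.trapezoid(values, taus / env.fs))
    return IrrevCurve(taus=taus, values=values, fs=env.fs, total=total)
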