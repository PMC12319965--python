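"""Synthetic envelope cohorts with controllable directional asymmetry.

The generative model is a linear vector autoregression

    x(t) = A x(t-1) + W x(t - L) + eta(t),      eta ~ N(0, noise_sd^2 I)

whose directed-coupling matrix ``W`` carries the controllable asymmetry
(``A`` is a diagonal persistence term giving the channels envelope-like
temporal continuity, ``L`` is the coupling delay in samples).  The channel
magnitudes of the analytic signal are taken as the amplitude envelope, and
the envelope is split into fixed-length epochs.  A symmetric ``W``
(asymmetry kappa = 0) yields a time-reversible stationary Gaussian process,
so downstream irreversibility vanishes in expectation; increasing kappa
increases the forward/reversed lagged-correlation asymmetry.

Cohorts are organized on a participant x drug x condition grid with a
multiplicative "drug" effect that shrinks each subject's asymmetry, so the
directed-hierarchy pipeline can be exercised end-to-end with known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .containers import DatasetKey, EnvelopeEpochs, StudyDesign

__all__ = [
    "CouplingGraph",
    "CohortSpec",
    "ToyNetwork",
    "random_coupling",
    "simulate_network_timeseries",
    "make_cohort",
    "toy_networks",
    "make_synthetic_map",
    "random_centroids",
]


class StabilityError(ValueError):
    """The linear recurrence defined by the coupling graph is not stationary."""


@dataclass
class CouplingGraph:
    """Directed coupling for the linear recurrence.

    ``weights[i, j]`` is the influence of channel j on channel i.
    ``kappa`` records the asymmetry level used to construct the matrix
    (0 means ``weights`` is symmetric).  ``coupling_lag`` is the delay L
    (samples) at which the coupling acts; ``persistence`` is the diagonal
    AR(1) coefficient.
    """

    weights: np.ndarray
    kappa: float = 0.0
    coupling_lag: int = 1
    persistence: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not (0 <= self.kappa <= 1):
            raise ValueError("kappa must be in [0, 1]")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1")
        if self.spectral_radius() >= 1.0:
            raise StabilityError(
                f"companion spectral radius {self.spectral_radius():.3f} >= 1"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def spectral_radius(self) -> float:
        """Spectral radius of the companion form of the full recurrence."""
        n, L = self.n_nodes, self.coupling_lag
        order = max(L, 1)
        comp = np.zeros((n * order, n * order))
        comp[:n, :n] = self.persistence * np.eye(n)
        comp[:n, n * (L - 1) : n * L] += self.weights
        if order > 1:
            comp[n:, :-n] = np.eye(n * (order - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def random_coupling(
    n_nodes: int,
    kappa: float,
    seed: int,
    density: float = 0.5,
    radius: float = 0.65,
    coupling_lag: int = 1,
    persistence: float = 0.0,
    normalize: str = "symmetric_base",
) -> CouplingGraph:
    """Random coupling with asymmetry interpolated by ``kappa``.

    A symmetric non-negative base coupling ``S`` is drawn, and for every
    connected pair a random preferred direction receives the fraction
    ``(1 + kappa)`` of the pair's weight while the opposite direction keeps
    ``(1 - kappa)``.  kappa = 0 gives an exactly symmetric
    (time-reversible) coupling, kappa = 1 fully directed pairs, and
    |W - W.T| = 2 kappa S grows linearly in kappa.

    Normalization: with ``"symmetric_base"`` (default) the coupling scale
    is fixed by requiring the *symmetric* base (kappa = 0) to hit the
    target companion spectral radius, and the same scale is used for every
    kappa drawn from this structure — so varying kappa redistributes each
    pair's weight between directions without changing the total coupling,
    and the manipulation is invisible to zero-lag correlations by
    construction.  ``"self"`` rescales each matrix itself to the target
    radius instead (matched stability margin, but total coupling then
    varies with kappa).
    """
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.uniform(0.2, 1.0, size=(n_nodes, n_nodes)), k=1)
    upper *= np.triu(rng.random((n_nodes, n_nodes)), k=1) < density
    S = upper + upper.T
    direction = np.triu(rng.choice([-1.0, 1.0], size=(n_nodes, n_nodes)), k=1)
    direction = direction - direction.T
    W = S * (1.0 + kappa * direction)
    if np.any(W):
        if normalize == "symmetric_base":
            W = W * _solve_scale(S, coupling_lag, persistence, radius)
        elif normalize == "self":
            W = W * _solve_scale(W, coupling_lag, persistence, radius)
        else:
            raise ValueError("normalize must be 'symmetric_base' or 'self'")
    return CouplingGraph(
        W, kappa, coupling_lag=coupling_lag, persistence=persistence
    )


def _solve_scale(
    W: np.ndarray, L: int, persistence: float, radius: float
) -> float:
    """Scale s such that the companion radius of s*W (with persistence) = radius."""

    def rho_of(s: float) -> float:
        g = CouplingGraph.__new__(CouplingGraph)
        g.weights = W * s
        g.kappa = 0.0
        g.coupling_lag = L
        g.persistence = persistence
        return g.spectral_radius()

    lo, hi = 0.0, 1.0
    while rho_of(hi) < radius:
        hi *= 2.0
        if hi > 1e6:
            raise StabilityError("cannot scale coupling to target radius")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rho_of(mid) < radius:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_network_timeseries(
    graph: CouplingGraph,
    T: int,
    fs: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    epoch_length_s: float = 2.0,
    burn_in: int = 200,
    region_labels=None,
) -> EnvelopeEpochs:
    """Simulate the recurrence, take Hilbert envelopes, split into epochs.

    ``T`` is the number of retained samples (>= 2 epochs).  Later stages
    demean per epoch; the envelope itself is left non-negative.
    """
    n_per_epoch = round(fs * epoch_length_s)
    if T < 2 * n_per_epoch:
        raise ValueError(f"T={T} shorter than two epochs ({2 * n_per_epoch})")
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    L = graph.coupling_lag
    total = T + burn_in
    X = np.zeros((total, n))
    eta = rng.normal(0.0, noise_sd, size=(total, n))
    W, a = graph.weights, graph.persistence
    for t in range(total):
        x = eta[t].copy()
        if t >= 1 and a != 0.0:
            x += a * X[t - 1]
        if t >= L:
            x += W @ X[t - L]
        X[t] = x
    X = X[burn_in:]
    env = np.abs(hilbert(X, axis=0)).T  # regions x samples
    n_epochs = T // n_per_epoch
    values = env[:, : n_epochs * n_per_epoch].reshape(n, n_epochs, n_per_epoch)
    values = np.transpose(values, (1, 0, 2))
    return EnvelopeEpochs(values, fs, region_labels, epoch_length_s)


@dataclass
class CohortSpec:
    """Parameters of a synthetic participant x drug x condition cohort.

    ``drug_effect`` (delta) multiplies each subject's asymmetry by
    ``1 - delta`` under the drug level; control datasets use the subject's
    own kappa.  Defaults mirror the study geometry (fs = 200 Hz, 2-s epochs,
    16 subjects) at a region/epoch count small enough for routine runs.
    """

    n_subjects: int = 16
    drug_effect: float = 0.8
    kappa_mean: float = 0.5
    kappa_sd: float = 0.1
    n_regions: int = 10
    epochs_per_dataset: int = 60
    fs: float = 200.0
    epoch_length_s: float = 2.0
    coupling_lag: int = 1
    persistence: float = 0.3
    noise_sd: float = 1.0
    coupling_density: float = 0.5
    spectral_radius: float = 0.65
    seed: int = 0
    condition_modulation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.drug_effect <= 1):
            raise ValueError("drug_effect must be in [0, 1]")
        for name, val in (
            ("n_subjects", self.n_subjects),
            ("n_regions", self.n_regions),
            ("epochs_per_dataset", self.epochs_per_dataset),
        ):
            if val < 1:
                raise ValueError(f"{name} must be positive")


def make_cohort(
    spec: CohortSpec, design: StudyDesign | None = None
) -> tuple[dict[DatasetKey, EnvelopeEpochs], StudyDesign]:
    """Generate one envelope dataset per (participant, drug, condition) cell.

    Per subject s a base random coupling structure and an asymmetry level
    kappa_s ~ N(kappa_mean, kappa_sd) (clipped to [0, 1]) are drawn; control
    datasets are simulated at kappa_s and drug datasets at
    kappa_s * (1 - drug_effect), all else matched.  Optional
    ``condition_modulation`` scales kappa per condition.
    """
    if design is None:
        design = StudyDesign(
            participant_ids=tuple(f"sub{i + 1:02d}" for i in range(spec.n_subjects))
        )
    if len(design.participant_ids) != spec.n_subjects:
        raise ValueError("design participant count does not match spec.n_subjects")
    ss = np.random.SeedSequence(spec.seed)
    subj_seeds = ss.spawn(spec.n_subjects)
    T = spec.epochs_per_dataset * round(spec.fs * spec.epoch_length_s)
    control, drug = design.drug_levels
    datasets: dict[DatasetKey, EnvelopeEpochs] = {}
    for s_idx, pid in enumerate(design.participant_ids):
        sub_ss = subj_seeds[s_idx]
        struct_seed, kappa_seed, *noise_seeds = sub_ss.generate_state(
            2 + 2 * len(design.condition_levels)
        )
        kappa_s = float(
            np.clip(
                np.random.default_rng(kappa_seed).normal(
                    spec.kappa_mean, spec.kappa_sd
                ),
                0.0,
                1.0,
            )
        )
        for c_idx, cond in enumerate(design.condition_levels):
            mod = spec.condition_modulation.get(cond, 1.0)
            for d_idx, (level, kappa) in enumerate(
                [(control, kappa_s), (drug, kappa_s * (1.0 - spec.drug_effect))]
            ):
                key = (pid, level, cond)
                if key in design.missing:
                    continue
                graph = random_coupling(
                    spec.n_regions,
                    float(np.clip(kappa * mod, 0.0, 1.0)),
                    seed=struct_seed,
                    density=spec.coupling_density,
                    radius=spec.spectral_radius,
                    coupling_lag=spec.coupling_lag,
                    persistence=spec.persistence,
                )
                datasets[key] = simulate_network_timeseries(
                    graph,
                    T=T,
                    fs=spec.fs,
                    noise_sd=spec.noise_sd,
                    seed=noise_seeds[2 * c_idx + d_idx],
                    epoch_length_s=spec.epoch_length_s,
                )
    return datasets, design


@dataclass
class ToyNetwork:
    """Small weighted directed network (node labels + positive edges)."""

    name: str
    labels: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if any(w <= 0 for _, _, w in self.edges):
            raise ValueError("edge weights must be positive")

    def weight_matrix(self) -> np.ndarray:
        """W[i, j] = weight of edge j -> i (influence convention)."""
        idx = {lbl: k for k, lbl in enumerate(self.labels)}
        W = np.zeros((len(self.labels), len(self.labels)))
        for u, v, w in self.edges:
            W[idx[v], idx[u]] = w
        return W

    def in_strengths(self) -> np.ndarray:
        return self.weight_matrix().sum(axis=1)

    def out_strengths(self) -> np.ndarray:
        return self.weight_matrix().sum(axis=0)


def toy_networks() -> tuple[ToyNetwork, ToyNetwork, ToyNetwork, ToyNetwork]:
    """The four 4-node illustration networks for the hierarchy metrics.

    (1) a ring of reciprocal unit edges, so every node receives exactly as
    much as it sends (non-hierarchical); (2) one reciprocal pair collapsed
    to a single direction, imbalancing exactly two nodes; (3)/(4) the same
    flipped edge scaled up (x2) / down (x0.5).
    """
    labels = ("A", "B", "C", "D")
    ring = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    recip = []
    for u, v in ring:
        recip.append((u, v, 1.0))
        recip.append((v, u, 1.0))
    net1 = ToyNetwork("net1", labels, tuple(recip))

    def drop_and_scale(scale: float, name: str) -> ToyNetwork:
        edges = [
            (u, v, (scale if (u, v) == ("A", "B") else w))
            for (u, v, w) in recip
            if (u, v) != ("B", "A")
        ]
        return ToyNetwork(name, labels, tuple(edges))

    return (
        net1,
        drop_and_scale(1.0, "net2"),
        drop_and_scale(2.0, "net3"),
        drop_and_scale(0.5, "net4"),
    )


def random_centroids(n: int, seed: int, box_mm: float = 140.0) -> np.ndarray:
    """Uniform random 3-D centroids inside a cube (mm), for map fixtures."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-box_mm / 2, box_mm / 2, size=(n, 3))


def make_synthetic_map(
    centroids: np.ndarray, correlation_length: float, seed: int, labels=None
):
    """Gaussian random field over centroids with exponential covariance.

    cov(i, j) = exp(-d_ij / correlation_length); the limit
    correlation_length -> 0 is iid noise (flat variogram).
    """
    from .spatial import BrainMap

    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    if n < 10:
        raise ValueError("need at least 10 regions")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    D = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    C = np.exp(-D / correlation_length)
    Lchol = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    rng = np.random.default_rng(seed)
    values = Lchol @ rng.standard_normal(n)
    if labels is None:
        labels = tuple(f"R{i:03d}" for i in range(n))
    return BrainMap(labels=tuple(labels), values=values, centroids=centroids)
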