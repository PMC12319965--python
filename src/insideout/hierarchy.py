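"""Incoming-outgoing asymmetry per region and its cohort summaries.

For each region the squared forward-row lagged correlations (region leading
its partners: OUTGOING components) and the squared reversed-row entries
(partners leading the region: INCOMING components) are concatenated,
thresholded at the concatenation's own percentile, surviving outgoing
entries negated, and averaged — a signed per-region asymmetry A_region.
The mean of A_region across regions is the hierarchical coherence and the
standard deviation is the hierarchical inhomogeneity.

A perfectly balanced network (every region sends as much as it receives,
with symmetric lagged correlations) has A_region = 0 everywhere and hence
zero coherence and inhomogeneity, even if individual connections are
strongly directed.  The default summary uses |A_region| (absolute mode):
signed asymmetries of a sender and its matched receiver cancel in the mean,
hiding exactly the imbalance the summaries are meant to expose; the signed
variant is retained as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeEpochs
from .irreversibility import LaggedCorrMatrices, corr_matrices

__all__ = ["AsymmetryProfile", "region_asymmetry", "profile_from_matrices", "profile"]


@dataclass
class AsymmetryProfile:
    """Per-region incoming-outgoing asymmetry plus scalar summaries."""

    A_region: np.ndarray  # signed, epoch-averaged
    coherence: float  # H_c: mean over regions of f(A_region)
    inhomogeneity: float  # H_i: sd over regions of f(A_region)
    tau_samples: int
    percentile: float
    mode: str


def region_asymmetry(
    m: LaggedCorrMatrices, region: int, percentile: float = 95.0
) -> float:
    """Signed incoming-minus-outgoing thresholded mean for one region.

    Builds the concatenation [forward row squared (outgoing), reversed row
    squared (incoming)] over off-diagonal partners, thresholds it at its own
    percentile (entries strictly above; ties dropped), negates surviving
    outgoing entries, and returns the mean of the surviving signed entries
    (0 if none survive).
    """
    n = m.Cf.shape[0]
    if not (0 <= region < n):
        raise IndexError(f"region {region} out of range [0, {n})")
    keep = np.arange(n) != region
    outgoing = m.Cf[region, keep] ** 2
    incoming = m.Cr[region, keep] ** 2
    concat = np.concatenate([outgoing, incoming])
    thr = np.percentile(concat, percentile)
    signs = np.concatenate([-np.ones_like(outgoing), np.ones_like(incoming)])
    survive = concat > thr
    if not survive.any():
        return 0.0
    return float(np.mean(signs[survive] * concat[survive]))


def profile_from_matrices(
    m: LaggedCorrMatrices, percentile: float = 95.0, mode: str = "absolute"
) -> AsymmetryProfile:
    """Asymmetry profile of a single lagged-correlation matrix pair."""
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    n = m.Cf.shape[0]
    A = np.array([region_asymmetry(m, i, percentile) for i in range(n)])
    f = np.abs(A) if mode == "absolute" else A
    return AsymmetryProfile(
        A_region=A,
        coherence=float(f.mean()),
        inhomogeneity=float(f.std()),
        tau_samples=m.tau_samples,
        percentile=percentile,
        mode=mode,
    )


def profile(
    env: EnvelopeEpochs,
    tau: int,
    percentile: float = 95.0,
    mode: str = "absolute",
) -> AsymmetryProfile:
    """Dataset asymmetry profile: per-epoch A_region, epoch-averaged.

    The percentile threshold is taken per region per epoch over the
    2(N-1)-length concatenation; H_c and H_i summarize the epoch-averaged
    regional values across regions.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    if env.n_epochs < 1:
        raise ValueError("need at least one epoch")
    X = env.demeaned()
    n = env.n_regions
    per_epoch = np.empty((env.n_epochs, n))
    for e in range(env.n_epochs):
        m = corr_matrices(X[e], tau, labels=env.region_labels)
        per_epoch[e] = [region_asymmetry(m, i, percentile) for i in range(n)]
    A = per_epoch.mean(axis=0)
    f = np.abs(A) if mode == "absolute" else A
    return AsymmetryProfile(
        A_region=A,
        coherence=float(f.mean()),
        inhomogeneity=float(f.std()),
        tau_samples=tau,
        percentile=percentile,
        mode=mode,
    )
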