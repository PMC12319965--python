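"""Envelope construction on source-localized regional timeseries.

Front-end stages: zero-phase band-pass filtering into canonical bands,
symmetric (multivariate) orthogonalization removing zero-lag correlations,
Hilbert amplitude envelopes, and epoching with per-epoch demeaning.  The
broadband path is a passthrough: no filter and, by default, no
orthogonalization.  The delta band is excluded by construction — no band
below 4 Hz is defined, because a 2-s epoch holds barely one delta cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .containers import EnvelopeEpochs

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "bandpass",
    "symmetric_orthogonalize",
    "hilbert_envelope",
    "epoch_and_demean",
    "prepare_envelopes",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low < high")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band {self.name}: high edge {self.high_hz} Hz at or above "
                f"Nyquist ({fs / 2} Hz)"
            )


CANONICAL_BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 48.0),
}


def bandpass(ts: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, regions x samples."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    band.validate(fs)
    sos = scipy.signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return scipy.signal.sosfiltfilt(sos, ts, axis=1)


def symmetric_orthogonalize(ts: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Closest-orthogonal-matrix correction of zero-lag correlations.

    Finds the set of mutually orthogonal timeseries (symmetric scheme: no
    channel is privileged) closest in least-squares to the input, via the
    orthogonal polar factor: with rows as channels, ``ts.T = U P`` and the
    corrected channels are ``U.T`` rescaled to the original channel norms.
    Output pairwise zero-lag correlations are ~0 after demeaning upstream
    of the correlation estimator; channels already orthogonal are returned
    unchanged up to scale.
    """
    ts = np.asarray(ts, dtype=float)
    n_regions, n_samples = ts.shape
    if n_samples <= n_regions:
        raise ValueError("need more samples than regions")
    # demeaned channels stay exactly zero-mean under the polar factor,
    # making the output's zero-lag correlations vanish identically
    ts = ts - ts.mean(axis=1, keepdims=True)
    A = ts.T  # samples x regions
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[-1] < tol * s[0]:
        gram = np.corrcoef(ts)
        i, j = np.unravel_index(
            np.argmax(np.abs(gram - np.eye(n_regions))), gram.shape
        )
        raise np.linalg.LinAlgError(
            f"rank-deficient input: channels {i} and {j} are collinear "
            f"(|corr| = {abs(gram[i, j]):.4f})"
        )
    ortho = (U @ Vt).T  # orthonormal columns -> orthogonal channels
    norms = np.linalg.norm(ts, axis=1)
    ortho *= (norms / np.linalg.norm(ortho, axis=1))[:, None]
    return ortho


def hilbert_envelope(ts: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal per channel (non-negative)."""
    ts = np.asarray(ts, dtype=float)
    if not np.all(np.isfinite(ts)):
        raise ValueError("input must be finite")
    return np.abs(scipy.signal.hilbert(ts, axis=-1))


def epoch_and_demean(
    ts: np.ndarray, fs: float, epoch_length_s: float = 2.0, region_labels=None
) -> EnvelopeEpochs:
    """Split into non-overlapping epochs and subtract per-epoch channel means.

    The trailing partial epoch is dropped.  The returned container holds the
    demeaned values (so zero-mean epochs are an invariant of this stage).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n_regions, n_samples = ts.shape
    n_per = round(fs * epoch_length_s)
    n_epochs = n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"input of {n_samples} samples shorter than one epoch ({n_per})"
        )
    trimmed = ts[:, : n_epochs * n_per].reshape(n_regions, n_epochs, n_per)
    epochs = np.transpose(trimmed, (1, 0, 2))
    epochs = epochs - epochs.mean(axis=2, keepdims=True)
    return EnvelopeEpochs(epochs, fs, region_labels, epoch_length_s)


def prepare_envelopes(
    ts: np.ndarray,
    fs: float,
    band: str | BandSpec | None = None,
    orthogonalize: bool | None = None,
    epoch_length_s: float = 2.0,
    region_labels=None,
) -> EnvelopeEpochs:
    """Full front-end: (band-pass ->) (orthogonalize ->) envelope -> epochs.

    ``band=None`` (broadband) skips the filter and, unless explicitly
    requested, the orthogonalization; for named bands orthogonalization
    defaults to on.
    """
    if isinstance(band, str):
        if band in ("broadband", "none"):
            band = None
        else:
            band = CANONICAL_BANDS[band]
    if orthogonalize is None:
        orthogonalize = band is not None
    out = np.atleast_2d(np.asarray(ts, dtype=float))
    if band is not None:
        out = bandpass(out, band, fs)
    if orthogonalize:
        out = symmetric_orthogonalize(out)
    env = hilbert_envelope(out)
    return epoch_and_demean(env, fs, epoch_length_s, region_labels)
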