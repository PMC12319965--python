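"""Core data containers for the envelope-hierarchy pipeline.

The pipeline operates on regional amplitude-envelope timeseries that have
been segmented into fixed-length epochs.  :class:`EnvelopeEpochs` is the
canonical in-memory container; :class:`StudyDesign` describes the
participant x drug x condition grid of a cohort; :class:`AnalysisConfig`
collects the tunable parameters of every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "EnvelopeEpochs",
    "AnalysisConfig",
    "ResultTable",
    "DatasetKey",
]

#: A cell of the cohort grid: (participant, drug, condition).
DatasetKey = tuple[str, str, str]


@dataclass(frozen=True)
class StudyDesign:
    """The participant x drug x condition grid of a cohort.

    Parameters
    ----------
    participant_ids
        Unique participant labels.
    drug_levels
        Exactly two labels; by convention ``(control, drug)``.
    condition_levels
        One or more condition labels.  The study default is
        ``("Open", "Closed", "Music", "Video")``.
    missing
        Explicitly declared missing grid cells.
    """

    participant_ids: tuple[str, ...]
    drug_levels: tuple[str, str] = ("control", "drug")
    condition_levels: tuple[str, ...] = ("Open", "Closed", "Music", "Video")
    missing: frozenset[DatasetKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pids = tuple(str(p) for p in self.participant_ids)
        object.__setattr__(self, "participant_ids", pids)
        object.__setattr__(self, "drug_levels", tuple(self.drug_levels))
        object.__setattr__(self, "condition_levels", tuple(self.condition_levels))
        object.__setattr__(self, "missing", frozenset(self.missing))
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("participant_ids must be unique")
        if len(self.drug_levels) != 2:
            raise ValueError("exactly two drug levels are required")
        if len(self.condition_levels) < 1:
            raise ValueError("at least one condition is required")
        for cell in self.missing:
            if cell not in set(self._full_grid()):
                raise ValueError(f"missing cell {cell} is not in the design grid")

    def _full_grid(self) -> Iterator[DatasetKey]:
        for p in self.participant_ids:
            for d in self.drug_levels:
                for c in self.condition_levels:
                    yield (p, d, c)

    def grid(self, include_missing: bool = False) -> list[DatasetKey]:
        """All (participant, drug, condition) cells, in a fixed order."""
        cells = list(self._full_grid())
        if include_missing:
            return cells
        return [c for c in cells if c not in self.missing]

    @property
    def n_datasets(self) -> int:
        return len(self.grid())


class EnvelopeEpochs:
    """Epoched regional amplitude envelopes.

    Attributes
    ----------
    values : ndarray, shape (n_epochs, n_regions, n_samples)
        Non-negative envelope amplitudes (arbitrary units).  Finiteness is
        enforced; non-negativity is a property of envelope construction and
        is not enforced so that demeaned intermediates can reuse the type.
    fs : float
        Sampling rate in Hz.
    region_labels : tuple of str
    epoch_length_s : float
        Epoch duration in seconds; ``n_samples == round(fs * epoch_length_s)``.
    """

    def __init__(
        self,
        values: np.ndarray,
        fs: float,
        region_labels: Sequence[str] | None = None,
        epoch_length_s: float | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError(
                f"values must be (n_epochs, n_regions, n_samples), got ndim={values.ndim}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("envelope values must be finite")
        if fs is None or not np.isfinite(fs) or fs <= 0:
            raise ValueError("sampling rate fs must be a positive number")
        n_epochs, n_regions, n_samples = values.shape
        if region_labels is None:
            region_labels = [f"R{i:03d}" for i in range(n_regions)]
        region_labels = tuple(str(r) for r in region_labels)
        if len(region_labels) != n_regions:
            raise ValueError(
                f"{len(region_labels)} region labels for {n_regions} regions"
            )
        if epoch_length_s is None:
            epoch_length_s = n_samples / fs
        if round(fs * epoch_length_s) != n_samples:
            raise ValueError(
                f"n_samples={n_samples} inconsistent with fs={fs}, "
                f"epoch_length_s={epoch_length_s}"
            )
        self.values = values
        self.fs = float(fs)
        self.region_labels = region_labels
        self.epoch_length_s = float(epoch_length_s)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def demeaned(self) -> np.ndarray:
        """Per-epoch, per-region demeaned copy of ``values``."""
        return self.values - self.values.mean(axis=2, keepdims=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvelopeEpochs):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.fs == other.fs
            and self.region_labels == other.region_labels
            and self.epoch_length_s == other.epoch_length_s
        )

    def __repr__(self) -> str:
        return (
            f"EnvelopeEpochs(n_epochs={self.n_epochs}, n_regions={self.n_regions}, "
            f"n_samples={self.n_samples}, fs={self.fs})"
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters shared by the pipeline stages.

    ``tau_samples`` is the lag of the lagged-correlation estimator, in
    samples (seconds appear only at the interface and are converted via
    ``fs``).  ``threshold_percentile`` is the percentile above which matrix
    entries contribute to thresholded means.  Seeds are mandatory for every
    stochastic stage: a missing seed raises rather than silently defaulting,
    so that permutation and classifier results are replayable.
    """

    tau_samples: int = 45
    threshold_percentile: float = 95.0
    window_length_s: float = 1.0
    window_overlap: float = 0.8
    n_permutations: int = 1000
    n_folds: int = 8
    seeds: dict[str, int] = field(default_factory=dict)
    threshold_mode: str = "survivors"  # or "none": plain mean, no thresholding
    asymmetry_mode: str = "absolute"  # or "signed"

    def __post_init__(self) -> None:
        if self.tau_samples < 1:
            raise ValueError("tau_samples must be >= 1")
        if not (0 < self.threshold_percentile < 100):
            raise ValueError("threshold_percentile must be in (0, 100)")
        if not (0 <= self.window_overlap < 1):
            raise ValueError("window_overlap must be in [0, 1)")
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if self.threshold_mode not in ("survivors", "none"):
            raise ValueError("threshold_mode must be 'survivors' or 'none'")
        if self.asymmetry_mode not in ("absolute", "signed"):
            raise ValueError("asymmetry_mode must be 'absolute' or 'signed'")

    def seed_for(self, stage: str) -> int:
        """Return the seed for a stochastic stage; absence is an error."""
        try:
            return int(self.seeds[stage])
        except KeyError:
            raise KeyError(
                f"no seed configured for stochastic stage {stage!r}; "
                "seeds are mandatory for replayability"
            ) from None

    def validate_for(self, env: EnvelopeEpochs) -> None:
        if self.tau_samples >= env.n_samples:
            raise ValueError(
                f"tau_samples={self.tau_samples} must be < n_samples={env.n_samples}"
            )


class ResultTable:
    """Long-format results: one row per (participant, drug, condition, metric).

    Thin wrapper over a :class:`pandas.DataFrame` that enforces the column
    contract and finiteness of values (explicitly missing rows carry NaN and
    ``missing=True``).
    """

    REQUIRED = ("participant", "drug", "condition", "metric_name", "value")

    def __init__(self, df: pd.DataFrame | None = None) -> None:
        if df is None:
            df = pd.DataFrame(columns=list(self.REQUIRED))
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"ResultTable missing required column {col!r}")
        if "missing" not in df.columns:
            df["missing"] = False
        bad = ~np.isfinite(df["value"].to_numpy(dtype=float)) & ~df["missing"]
        if bad.any():
            raise ValueError(
                "non-finite values present without missing flag at rows "
                f"{list(df.index[bad])[:5]}"
            )
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[dict]) -> "ResultTable":
        if not records:
            return cls()
        return cls(pd.DataFrame.from_records(records))

    def append(self, **row) -> None:
        for col in self.REQUIRED:
            if col not in row:
                raise ValueError(f"row missing required key {col!r}")
        row.setdefault("missing", False)
        if not row["missing"] and not np.isfinite(row["value"]):
            raise ValueError("non-finite value without missing flag")
        new = pd.DataFrame.from_records([row])
        if self.df.empty:
            self.df = new
        else:
            self.df = pd.concat([self.df, new], ignore_index=True)

    def pivot(self, metric_name: str) -> pd.DataFrame:
        """Wide table (participant x drug x condition) for one metric."""
        sub = self.df[self.df["metric_name"] == metric_name]
        return sub.pivot_table(
            index="participant", columns=["drug", "condition"], values="value"
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        a = self.df[list(self.REQUIRED)].reset_index(drop=True)
        b = other.df[list(self.REQUIRED)].reset_index(drop=True)
        if len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True
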