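"""Per-participant diary time series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiarySeries", "missing_runs"]


def missing_runs(observed: np.ndarray) -> list[tuple[int, int]]:
    """Runs of consecutive missing occasions as (start, length) pairs.

    Includes edge runs (leading and trailing non-response), since a long
    dropout tail is as much a gap in observations as an interior block.
    """
    runs: list[tuple[int, int]] = []
    start = None
    for i, obs in enumerate(observed):
        if not obs and start is None:
            start = i
        elif obs and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(observed) - start))
    return runs


@dataclass
class DiarySeries:
    """Cleaned daily habit-strength series for one participant.

    Occasions are integers ``0 .. n_days-1`` (one unit = one day of the
    decay phase). ``values[t]`` is the SRBAI score in [0, 4] or NaN when
    missing; ``imputed[t]`` marks occasions filled by singleton-gap
    imputation (an imputed occasion counts as usable for model fitting
    but not toward retention). The Day-7 measurement, taken before the
    decay phase begins, is kept aside as ``baseline``.
    """

    participant_id: str
    group: str
    values: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.values.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.imputed.shape != self.values.shape:
            raise ValueError("imputed mask shape must match values")
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(self.values, nan=2.0)
        if ((bad < 0) | (bad > 4)).any():
            raise ValueError("SRBAI values must lie in [0, 4]")
        if (self.imputed & ~np.isfinite(self.values)).any():
            raise ValueError("imputed occasions must carry a value")

    @property
    def n_days(self) -> int:
        return len(self.values)

    @property
    def present(self) -> np.ndarray:
        """Mask of usable occasions (observed or imputed)."""
        return np.isfinite(self.values)

    @property
    def observed(self) -> np.ndarray:
        """Mask of genuinely observed (non-imputed) occasions."""
        return self.present & ~self.imputed

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def t_first(self) -> int:
        """First usable occasion."""
        idx = np.flatnonzero(self.present)
        if idx.size == 0:
            raise ValueError("series has no usable occasions")
        return int(idx[0])

    @property
    def t_last(self) -> int:
        """Last usable occasion."""
        idx = np.flatnonzero(self.present)
        if idx.size == 0:
            raise ValueError("series has no usable occasions")
        return int(idx[-1])

    @property
    def last_observed(self) -> int | None:
        idx = np.flatnonzero(self.observed)
        return int(idx[-1]) if idx.size else None

    def gap_lengths(self) -> list[int]:
        """Lengths of missing runs (post-imputation), including edges."""
        return [length for _, length in missing_runs(self.present)]

    @property
    def longest_gap(self) -> int:
        gaps = self.gap_lengths()
        return max(gaps) if gaps else 0

    def fit_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, y) arrays of usable occasions, for model fitting."""
        mask = self.present
        return np.flatnonzero(mask).astype(float), self.values[mask]

    def drop_occasion(self, t: int) -> "DiarySeries":
        """Copy with occasion ``t`` made missing (for leave-one-out)."""
        values = self.values.copy()
        imputed = self.imputed.copy()
        values[t] = np.nan
        imputed[t] = False
        return DiarySeries(
            self.participant_id, self.group, values, imputed, self.baseline
        )
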