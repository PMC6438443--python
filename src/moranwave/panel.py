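"""Spatiotemporal panels: N location time series on a common annual axis.

The basic data container of the package. A panel holds one variable
``x_n(t)`` measured at locations ``n = 1..N`` and years ``t_1..t_T`` on an
equally spaced annual grid. All downstream machinery (wavelet transforms,
mean fields, coherence, wavelet regression) consumes these panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatioTemporalSeries"]


@dataclass(frozen=True)
class SpatioTemporalSeries:
    """An ``N x T`` real panel of annual time series.

    Parameters
    ----------
    values
        Real matrix of shape ``(N, T)``; rows are locations, columns years.
        All entries must be finite: missing data are rejected at
        construction rather than silently propagated.
    location_ids
        ``N`` distinct labels for the rows.
    years
        Strictly increasing integer axis of length ``T`` with step 1.
    """

    values: np.ndarray
    location_ids: tuple[str, ...]
    years: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (N, T); got shape {values.shape}")
        n, t = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 locations; got {n}")
        if t < 4:
            raise ValueError(f"need at least 4 time steps; got {t}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            cells = ", ".join(f"(row {i}, col {j})" for i, j in bad[:5])
            raise ValueError(f"non-finite entries at {cells}" + ("..." if len(bad) > 5 else ""))
        ids = tuple(str(x) for x in self.location_ids)
        if len(ids) != n:
            raise ValueError(f"{len(ids)} location ids for {n} rows")
        if len(set(ids)) != n:
            raise ValueError("duplicate location ids")
        years = self.years
        if years is None:
            years = np.arange(t)
        years = np.asarray(years)
        if not np.issubdtype(years.dtype, np.integer):
            if not np.allclose(years, np.round(years)):
                raise ValueError("years must be integers")
            years = np.round(years).astype(int)
        if years.shape != (t,):
            raise ValueError(f"years has length {years.shape}, expected ({t},)")
        if not np.all(np.diff(years) == 1):
            raise ValueError("years must be strictly increasing with step 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "location_ids", ids)
        object.__setattr__(self, "years", years)

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SpatioTemporalSeries":
        """A copy of this panel carrying new values on the same axes."""
        return SpatioTemporalSeries(np.asarray(values, dtype=float), self.location_ids, self.years)

    def subset_locations(self, index: np.ndarray) -> "SpatioTemporalSeries":
        index = np.asarray(index)
        return SpatioTemporalSeries(
            self.values[index], tuple(np.asarray(self.location_ids, dtype=object)[index]), self.years
        )
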