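"""CSV/JSON input and output.

Panels travel as CSV matrices: first column the location id, header row
the integer years. Surfaces are written as CSV with timescales as rows
and years as columns. Transform sets serialize to a directory of
per-timescale CSV pairs (real and imaginary parts) plus a JSON sidecar
describing the grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .meanfields import MeanFieldSurface
from .moran import SynchronyPartition
from .panel import SpatioTemporalSeries
from .preprocess import CleanReport
from .wavelets import WaveletTransformSet

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "write_surface_csv",
    "read_surface_csv",
    "write_clean_report_csv",
    "write_partition_csv",
    "write_transforms",
    "read_transforms",
]


def read_panel_csv(path: str | Path) -> SpatioTemporalSeries:
    """Read and validate a panel CSV (rows locations, columns years)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate location labels in {path.name}: {dups}")
    try:
        years = np.array([int(c) for c in frame.columns])
    except ValueError as err:
        raise ValueError(f"header of {path.name} must be integer years: {err}") from None
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [
            (str(frame.index[i]), str(frame.columns[j]))
            for i, j in zip(*np.where(frame.map(lambda v: isinstance(v, str)).to_numpy()))
        ]
        raise ValueError(f"non-numeric cells in {path.name}: {bad[:5]}")
    values = values.astype(float)
    if np.isnan(values).any():
        cells = [
            f"(location {frame.index[i]!r}, year {frame.columns[j]})"
            for i, j in zip(*np.where(np.isnan(values)))
        ]
        raise ValueError(f"missing values in {path.name}: {', '.join(cells[:5])}")
    return SpatioTemporalSeries(values, tuple(str(i) for i in frame.index), years)


def write_panel_csv(series: SpatioTemporalSeries, path: str | Path) -> None:
    frame = pd.DataFrame(series.values, index=list(series.location_ids), columns=series.years)
    frame.index.name = "location"
    frame.to_csv(path, float_format="%.17g")


def write_surface_csv(surface: MeanFieldSurface, path: str | Path, squared: bool = False) -> None:
    """Write a mean-field magnitude surface (rows timescales, columns years)."""
    mag = surface.magnitude
    if squared:
        mag = mag**2
    cols = surface.years if surface.years is not None else np.arange(mag.shape[0])
    frame = pd.DataFrame(mag.T, index=[f"{s:.6f}" for s in surface.timescales], columns=cols)
    frame.index.name = "timescale"
    frame.to_csv(path, float_format="%.17g")


def read_surface_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a surface CSV; returns (timescales, years, magnitude (T, S))."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    timescales = frame.index.to_numpy(dtype=float)
    years = np.array([int(c) for c in frame.columns])
    return timescales, years, frame.to_numpy().T


def write_clean_report_csv(report: CleanReport, path: str | Path) -> None:
    pd.DataFrame(
        {
            "location": list(report.location_ids),
            "lambda": report.lambdas,
            "shift": report.shifts,
            "trend_slope": report.trend_slopes,
            "trend_intercept": report.trend_intercepts,
        }
    ).to_csv(path, index=False)


def write_partition_csv(partition: SynchronyPartition, path: str | Path) -> None:
    rows = [
        {"band_low": partition.band[0], "band_high": partition.band[1],
         "component": name, "fraction": frac}
        for name, frac in partition.fraction_per_predictor.items()
    ]
    rows.append(
        {"band_low": partition.band[0], "band_high": partition.band[1],
         "component": "interactions", "fraction": partition.fraction_interactions}
    )
    rows.append(
        {"band_low": partition.band[0], "band_high": partition.band[1],
         "component": "total", "fraction": partition.fraction_total}
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_transforms(transforms: WaveletTransformSet, out_dir: str | Path) -> None:
    """Write a transform set as per-timescale real/imaginary CSV pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = list(transforms.location_ids)
    years = transforms.years if transforms.years is not None else np.arange(
        transforms.coefficients.shape[1]
    )
    for j, sigma in enumerate(transforms.timescales):
        for part, arr in (("real", transforms.coefficients[:, :, j].real),
                          ("imag", transforms.coefficients[:, :, j].imag)):
            frame = pd.DataFrame(arr, index=ids, columns=years)
            frame.index.name = "location"
            frame.to_csv(out_dir / f"scale_{j:03d}_{part}.csv")
    sidecar = {
        "timescales": [float(s) for s in transforms.timescales],
        "central_frequency": transforms.central_frequency,
        "years": [int(y) for y in years],
        "location_ids": ids,
    }
    (out_dir / "transforms.json").write_text(json.dumps(sidecar, indent=1))


def read_transforms(out_dir: str | Path) -> WaveletTransformSet:
    """Read a transform set written by :func:`write_transforms`."""
    from .wavelets import _kernels  # COI depends only on grid geometry

    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / "transforms.json").read_text())
    timescales = np.array(sidecar["timescales"])
    years = np.array(sidecar["years"])
    n_times = len(years)
    coeffs = []
    for j in range(len(timescales)):
        real = pd.read_csv(out_dir / f"scale_{j:03d}_real.csv", index_col=0).to_numpy()
        imag = pd.read_csv(out_dir / f"scale_{j:03d}_imag.csv", index_col=0).to_numpy()
        coeffs.append(real + 1j * imag)
    coefficients = np.stack(coeffs, axis=2)
    _, coi_ts = _kernels(n_times, timescales, sidecar["central_frequency"])
    coi = np.broadcast_to(coi_ts, (coefficients.shape[0],) + coi_ts.shape)
    return WaveletTransformSet(
        coefficients=coefficients,
        timescales=timescales,
        central_frequency=sidecar["central_frequency"],
        coi_mask=coi,
        location_ids=tuple(sidecar["location_ids"]),
        years=years,
    )
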