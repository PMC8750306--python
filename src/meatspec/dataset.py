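"""Core data model and I/O for replicate-structured meat spectra.

A :class:`SpectralDataset` couples a scan-by-wavelength intensity matrix with
per-scan metadata (sample id, species, intact/ground form, replicate index)
and the wavelength grid the columns live on.  Every stage of the pipeline —
preprocessing, splitting, one-class screening, discriminant modelling —
consumes and produces this structure.

Two handheld sensors are supported:

``visnir``
    400–1000 nm; each scan yields two derived 600-channel spectra which are
    concatenated into a single 1200-channel row (two source blocks).
``nir``
    900–1700 nm, 252 channels (one block).

Spectra tables are stored as plain CSV, one scan per row, with metadata
columns ``sample_id, species, form, replicate`` followed by wavelength
columns named ``<sensor>_b<block>_<nm>``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, ValidationError

SPECIES: tuple[str, ...] = ("lamb", "beef", "chicken", "pork")
FORMS: tuple[str, ...] = ("intact", "ground")
SENSORS: tuple[str, ...] = ("visnir", "nir")

#: Channel layout each sensor must have: (total channels, block sizes).
_SENSOR_LAYOUT: dict[str, tuple[int, tuple[int, ...]]] = {
    "visnir": (1200, (600, 600)),
    "nir": (252, (252,)),
}

META_COLUMNS: tuple[str, ...] = ("sample_id", "species", "form", "replicate")

_COLUMN_RE = re.compile(r"^(?P<sensor>[a-z]+)_b(?P<block>\d+)_(?P<nm>[0-9.]+)$")


@dataclass(frozen=True)
class WavelengthGrid:
    """Wavelength axis of one sensor, possibly built from several source blocks."""

    sensor: str
    wavelengths_nm: np.ndarray
    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor {self.sensor!r}; expected one of {SENSORS}")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        expected_n, expected_blocks = _SENSOR_LAYOUT[self.sensor]
        if tuple(self.block_sizes) != expected_blocks:
            raise ValidationError(
                f"sensor {self.sensor!r} requires block sizes {expected_blocks}, "
                f"got {tuple(self.block_sizes)}"
            )
        if wl.ndim != 1 or wl.size != expected_n:
            raise ValidationError(
                f"sensor {self.sensor!r} requires {expected_n} channels, got {wl.size}"
            )
        for lo, hi in self._block_bounds():
            block = wl[lo:hi]
            if not np.all(np.diff(block) > 0):
                raise ValidationError(
                    f"wavelengths must be strictly increasing within block [{lo}:{hi}]"
                )

    def _block_bounds(self) -> list[tuple[int, int]]:
        edges = np.concatenate([[0], np.cumsum(self.block_sizes)])
        return [(int(edges[i]), int(edges[i + 1])) for i in range(len(self.block_sizes))]

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths_nm.size)

    def column_names(self) -> list[str]:
        names = []
        for b, (lo, hi) in enumerate(self._block_bounds(), start=1):
            names.extend(
                f"{self.sensor}_b{b}_{nm:.2f}" for nm in self.wavelengths_nm[lo:hi]
            )
        return names

    def __eq__(self, other: object) -> bool:  # ndarray field needs explicit handling
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.sensor == other.sensor
            and tuple(self.block_sizes) == tuple(other.block_sizes)
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm)
        )


def visnir_grid() -> WavelengthGrid:
    """Default Vis-NIR grid: two 600-point blocks spanning 400–1000 nm."""
    block = np.linspace(400.0, 1000.0, 600)
    return WavelengthGrid("visnir", np.concatenate([block, block]), (600, 600))


def nir_grid() -> WavelengthGrid:
    """Default NIR grid: 252 channels spanning 900–1700 nm."""
    return WavelengthGrid("nir", np.linspace(900.0, 1700.0, 252), (252,))


@dataclass(frozen=True)
class ScanMeta:
    """Metadata of one scan (one spectral acquisition point on one sample)."""

    sample_id: str
    species: str
    form: str
    replicate: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if self.form not in FORMS:
            raise ValidationError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if not (1 <= int(self.replicate) <= 6):
            raise ValidationError(
                f"replicate must be in 1..6, got {self.replicate} (sample {self.sample_id})"
            )


@dataclass
class SpectralDataset:
    """Scan × wavelength matrix with aligned per-scan metadata."""

    X: np.ndarray
    grid: WavelengthGrid
    meta: list[ScanMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {self.X.shape}")
        if self.X.shape[1] != self.grid.n_channels:
            raise DimensionError(
                f"X has {self.X.shape[1]} columns but grid has {self.grid.n_channels} channels"
            )
        if self.X.shape[0] != len(self.meta):
            raise DimensionError(
                f"X has {self.X.shape[0]} rows but meta has {len(self.meta)} entries"
            )
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValidationError("intensity matrix contains non-finite values")
        _check_sample_consistency(self.meta)

    @property
    def n_scans(self) -> int:
        return int(self.X.shape[0])

    @property
    def sample_ids(self) -> np.ndarray:
        return np.array([m.sample_id for m in self.meta], dtype=object)

    @property
    def species(self) -> np.ndarray:
        return np.array([m.species for m in self.meta], dtype=object)

    @property
    def form(self) -> np.ndarray:
        return np.array([m.form for m in self.meta], dtype=object)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "species": self.species,
                "form": self.form,
                "replicate": [m.replicate for m in self.meta],
            }
        )

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectralDataset":
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(self.X[rows], self.grid, [self.meta[i] for i in rows])

    def sample_species(self) -> dict[str, str]:
        """Species of each sample (constant across its replicates)."""
        out: dict[str, str] = {}
        for m in self.meta:
            out.setdefault(m.sample_id, m.species)
        return out


def _check_sample_consistency(meta: Sequence[ScanMeta]) -> None:
    seen: dict[str, tuple[str, str]] = {}
    counts: dict[str, int] = {}
    for m in meta:
        key = (m.species, m.form)
        if m.sample_id in seen and seen[m.sample_id] != key:
            raise ValidationError(
                f"sample {m.sample_id!r} has inconsistent species/form metadata: "
                f"{seen[m.sample_id]} vs {key}"
            )
        seen[m.sample_id] = key
        counts[m.sample_id] = counts.get(m.sample_id, 0) + 1
    for sid, n in counts.items():
        if n > 6:
            raise ValidationError(f"sample {sid!r} has {n} replicates; at most 6 allowed")


def _grid_from_columns(columns: Sequence[str]) -> WavelengthGrid:
    sensors: list[str] = []
    blocks: list[int] = []
    nm: list[float] = []
    for col in columns:
        match = _COLUMN_RE.match(col)
        if match is None:
            raise FormatError(f"column {col!r} is not a recognised wavelength column")
        sensors.append(match["sensor"])
        blocks.append(int(match["block"]))
        nm.append(float(match["nm"]))
    sensor_set = set(sensors)
    if len(sensor_set) != 1:
        raise FormatError(f"mixed sensors in one table: {sorted(sensor_set)}")
    blocks_arr = np.asarray(blocks)
    block_sizes = tuple(
        int(np.sum(blocks_arr == b)) for b in sorted(set(blocks))
    )
    return WavelengthGrid(sensors[0], np.asarray(nm), block_sizes)


def read_spectra_table(path: str | Path) -> SpectralDataset:
    """Read a CSV spectra table (one scan per row) into a :class:`SpectralDataset`.

    The header must contain the metadata columns ``sample_id, species, form,
    replicate`` and wavelength columns named ``<sensor>_b<block>_<nm>``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise FormatError(f"{path}: no wavelength columns found")
    grid = _grid_from_columns(wl_cols)

    raw = df[wl_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric intensity at data row {row}, column {wl_cols[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing intensity at data row {row}, column {wl_cols[col]!r}"
        )

    meta = [
        ScanMeta(str(r.sample_id), str(r.species), str(r.form), int(r.replicate))
        for r in df[list(META_COLUMNS)].itertuples(index=False)
    ]
    return SpectralDataset(numeric.to_numpy(dtype=float), grid, meta)


def write_spectra_table(
    ds: SpectralDataset, path: str | Path, sidecar: bool = False
) -> Path:
    """Write a dataset as CSV, re-readable by :func:`read_spectra_table`.

    With ``sidecar=True`` a JSON file alongside the CSV records the sensor and
    block layout explicitly (redundant with the header, convenient for audit).
    """
    path = Path(path)
    df = ds.meta_frame()
    spec = pd.DataFrame(ds.X, columns=ds.grid.column_names())
    out = pd.concat([df.reset_index(drop=True), spec.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
    if sidecar:
        info = {
            "sensor": ds.grid.sensor,
            "block_sizes": list(ds.grid.block_sizes),
            "n_channels": ds.grid.n_channels,
            "n_scans": ds.n_scans,
        }
        path.with_suffix(".json").write_text(json.dumps(info, indent=2))
    return path


def concatenate_dual_scans(
    block_a: np.ndarray,
    block_b: np.ndarray,
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    meta: Sequence[ScanMeta] | None = None,
) -> SpectralDataset:
    """Join the two 600-channel derived spectra of each Vis-NIR scan row-wise.

    ``grid_a``/``grid_b`` are the per-block wavelength axes (600 values each).
    Row ``i`` of the result is row ``i`` of ``block_a`` followed by row ``i``
    of ``block_b``.  When no metadata is supplied, placeholder single-replicate
    pork/intact entries are attached (useful for matrix-level work).
    """
    block_a = np.atleast_2d(np.asarray(block_a, dtype=float))
    block_b = np.atleast_2d(np.asarray(block_b, dtype=float))
    if block_a.shape[0] != block_b.shape[0]:
        raise DimensionError(
            f"row counts differ: {block_a.shape[0]} vs {block_b.shape[0]}"
        )
    if block_a.shape[1] != 600 or block_b.shape[1] != 600:
        raise DimensionError(
            f"each block must have 600 channels, got {block_a.shape[1]} and {block_b.shape[1]}"
        )
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.size != 600 or grid_b.size != 600:
        raise DimensionError("each block grid must have 600 wavelengths")
    grid = WavelengthGrid("visnir", np.concatenate([grid_a, grid_b]), (600, 600))
    X = np.hstack([block_a, block_b])
    if meta is None:
        meta = [
            ScanMeta(f"scan{i:04d}", "pork", "intact", 1) for i in range(X.shape[0])
        ]
    return SpectralDataset(X, grid, list(meta))


def group_by_sample(ds: SpectralDataset) -> dict[str, np.ndarray]:
    """Row indices of each sample, keyed by sample id in first-appearance order.

    The groups partition all row indices; replicates of one sample always share
    species and form (enforced at dataset construction).
    """
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(ds.meta):
        groups.setdefault(m.sample_id, []).append(i)
    return {sid: np.asarray(rows, dtype=int) for sid, rows in groups.items()}


def group_table(groups: Mapping[str, np.ndarray], ds: SpectralDataset) -> pd.DataFrame:
    """One row per sample: id, species, form, replicate count."""
    records = []
    for sid, rows in groups.items():
        m = ds.meta[rows[0]]
        records.append(
            {"sample_id": sid, "species": m.species, "form": m.form, "n_replicates": len(rows)}
        )
    return pd.DataFrame(records)
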