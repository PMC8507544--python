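"""Domain types and I/O for Raman spectra.

A :class:`SpectrumSet` is the container every pre-processing and
classification stage transforms: an ``(n_spectra, n_channels)`` intensity
matrix over one shared, strictly-increasing wavenumber axis, with optional
per-spectrum class labels and free-form metadata records.

On disk, spectra live in plain CSV/TSV.  The canonical "wide" layout has a
header row, ``wavenumber_cm1`` as the first column and one column per
spectrum; a "long" layout (``wavenumber,intensity,spectrum_id``) is also
accepted.  Dataset-level labels/metadata travel in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectrumSet",
    "SpectraParseError",
    "AxisMismatchError",
    "read_spectra",
    "write_spectra",
    "crop_fingerprint",
    "pearson",
]

FINGERPRINT_LO = 600.0  #: default fingerprint-region lower bound, cm^-1
FINGERPRINT_HI = 1800.0  #: default fingerprint-region upper bound, cm^-1


class SpectraParseError(ValueError):
    """A spectra table could not be parsed (non-numeric cell, bad layout)."""


class AxisMismatchError(ValueError):
    """Spectra in one dataset do not share a common wavenumber axis."""


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing axis of Raman shifts in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber axis must be 1-D with length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavenumber axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: intensities (detector counts or corrected units) on an axis."""

    axis: WavenumberAxis
    intensities: np.ndarray
    id: str = "spectrum"

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intens)
        if intens.shape != (len(self.axis),):
            raise ValueError(
                f"intensities shape {intens.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(intens)):
            raise ValueError("spectrum intensities must be finite")


@dataclass
class SpectrumSet:
    """A stack of spectra on one shared axis.

    Parameters
    ----------
    axis:
        Shared wavenumber axis.
    matrix:
        ``(n_spectra, n_channels)`` intensities.
    ids:
        Per-spectrum opaque identifiers.
    labels:
        Optional class label per spectrum.
    meta:
        Per-spectrum key-value records (acquisition time, stage position,
        quality flags, ...).
    """

    axis: WavenumberAxis
    matrix: np.ndarray
    ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    meta: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, p = self.matrix.shape
        if p != len(self.axis):
            raise AxisMismatchError(
                f"matrix has {p} channels but axis has {len(self.axis)}"
            )
        if not self.ids:
            self.ids = [f"s{i:04d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length does not match number of spectra")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of spectra")
        if not self.meta:
            self.meta = [{} for _ in range(n)]
        if len(self.meta) != n:
            raise ValueError("meta length does not match number of spectra")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.matrix.shape[1])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.matrix[i], self.ids[i])

    def with_matrix(self, matrix: np.ndarray, axis: WavenumberAxis | None = None) -> "SpectrumSet":
        """Copy of this set with a replaced matrix (and optionally axis)."""
        return SpectrumSet(
            axis=axis if axis is not None else self.axis,
            matrix=np.asarray(matrix, dtype=float),
            ids=list(self.ids),
            labels=None if self.labels is None else list(self.labels),
            meta=[dict(m) for m in self.meta],
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectrumSet":
        idx = np.asarray(idx, dtype=int)
        return SpectrumSet(
            axis=self.axis,
            matrix=self.matrix[idx],
            ids=[self.ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            meta=[dict(self.meta[i]) for i in idx],
        )

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], labels: list[str] | None = None) -> "SpectrumSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis != axis:
                raise AxisMismatchError(f"spectrum {s.id!r} is on a different axis")
        return cls(
            axis=axis,
            matrix=np.vstack([s.intensities for s in spectra]),
            ids=[s.id for s in spectra],
            labels=labels,
        )


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_spectra(path: str | Path, dialect: str = "wide") -> SpectrumSet:
    """Read a spectra table from CSV/TSV.

    ``dialect="wide"``: first column is the wavenumber, every other column one
    spectrum.  ``dialect="long"``: columns ``wavenumber,intensity,spectrum_id``.
    A descending source axis is reordered ascending.  Labels and per-spectrum
    metadata are restored from the ``<path>.meta.json`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraParseError(f"could not parse {path}: {exc}") from exc

    if dialect == "long":
        required = {"wavenumber", "intensity", "spectrum_id"}
        if not required.issubset(df.columns):
            raise SpectraParseError(
                f"long-format table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        _check_numeric(df, ["wavenumber", "intensity"], path)
        ids = list(dict.fromkeys(df["spectrum_id"].astype(str)))
        axis_ref: np.ndarray | None = None
        rows = []
        for sid in ids:
            sub = df[df["spectrum_id"].astype(str) == sid]
            order = np.argsort(sub["wavenumber"].to_numpy())
            wn = sub["wavenumber"].to_numpy(dtype=float)[order]
            if axis_ref is None:
                axis_ref = wn
            elif not np.array_equal(axis_ref, wn):
                raise AxisMismatchError(
                    f"spectrum {sid!r} in {path} is on a different wavenumber axis"
                )
            rows.append(sub["intensity"].to_numpy(dtype=float)[order])
        axis_vals = axis_ref
        matrix = np.vstack(rows)
    elif dialect == "wide":
        if df.shape[1] < 2:
            raise SpectraParseError(f"{path}: need a wavenumber column plus >= 1 spectrum")
        _check_numeric(df, list(df.columns), path)
        axis_vals = df.iloc[:, 0].to_numpy(dtype=float)
        order = np.argsort(axis_vals)
        axis_vals = axis_vals[order]
        matrix = df.iloc[:, 1:].to_numpy(dtype=float).T[:, order]
        ids = [str(c) for c in df.columns[1:]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    ss = SpectrumSet(axis=WavenumberAxis(axis_vals), matrix=matrix, ids=ids)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        labels = side.get("labels")
        if labels is not None:
            by_id = dict(zip(side.get("ids", ss.ids), labels))
            ss.labels = [by_id.get(i) for i in ss.ids]
        meta = side.get("meta")
        if meta is not None:
            by_id = dict(zip(side.get("ids", ss.ids), meta))
            ss.meta = [dict(by_id.get(i, {})) for i in ss.ids]
    return ss


def _check_numeric(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SpectraParseError(f"{path}: missing value at row {row}, column {col!r}")


def write_spectra(ss: SpectrumSet, path: str | Path, dialect: str = "wide") -> Path:
    """Write a :class:`SpectrumSet` to CSV/TSV (plus a JSON metadata sidecar)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if dialect == "wide":
        df = pd.DataFrame({"wavenumber_cm1": ss.axis.values})
        for i, sid in enumerate(ss.ids):
            df[sid] = ss.matrix[i]
    elif dialect == "long":
        frames = []
        for i, sid in enumerate(ss.ids):
            frames.append(
                pd.DataFrame(
                    {
                        "wavenumber": ss.axis.values,
                        "intensity": ss.matrix[i],
                        "spectrum_id": sid,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    side = {"ids": ss.ids, "labels": ss.labels, "meta": ss.meta}
    _sidecar_path(path).write_text(json.dumps(side, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Fingerprint extraction and the Pearson primitive


def crop_fingerprint(
    ss: SpectrumSet, lo: float = FINGERPRINT_LO, hi: float = FINGERPRINT_HI
) -> SpectrumSet:
    """Retain exactly the channels with ``lo <= wavenumber <= hi`` (closed interval).

    The 600-1800 cm^-1 fingerprint window carries most biomolecular Raman
    bands; everything downstream of acquisition operates on it.
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    mask = (ss.axis.values >= lo) & (ss.axis.values <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"fingerprint window [{lo}, {hi}] overlaps fewer than 2 axis channels"
        )
    return ss.with_matrix(ss.matrix[:, mask], axis=WavenumberAxis(ss.axis.values[mask]))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length intensity vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("pearson requires length >= 3")
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt(da @ da))
    nb = float(np.sqrt(db @ db))
    if na == 0.0 or nb == 0.0:
        raise ValueError("pearson is undefined for a constant vector")
    r = float((da @ db) / (na * nb))
    return float(np.clip(r, -1.0, 1.0))


def pearson_rows(matrix: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of every matrix row against one reference vector (vectorised)."""
    X = np.asarray(matrix, dtype=float)
    r = np.asarray(ref, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    rc = r - r.mean()
    num = Xc @ rc
    den = np.sqrt((Xc * Xc).sum(axis=1) * float(rc @ rc))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.clip(out, -1.0, 1.0)
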