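"""Containers and I/O for mass spectrometry imaging datasets.

An :class:`MSIDataset` holds one acquisition mode's worth of samples; each
:class:`Sample` stores its centroided peak lists in flat arrays (``mz``,
``intensity``, ``pixel_index``) for speed, with ``coords`` mapping pixel
indices to (x, y) raster positions.  Peaks are kept sorted by
(pixel, m/z).

Two interchange formats are supported:

* a documented CSV dialect: one ``peaks.csv`` with columns
  ``sample,x,y,mz,intensity`` plus a ``metadata.json`` sidecar carrying the
  mode and per-sample (group, age, grid shape);
* imzML (processed/centroided) via pyimzml, one file per sample, with the
  same sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

__all__ = ["Sample", "MSIDataset", "write_dataset", "read_dataset", "FormatError"]


class FormatError(ValueError):
    """Raised for unknown formats or malformed dataset files."""


@dataclass
class Sample:
    """One tissue section: metadata plus flat, pixel-indexed peak arrays."""

    sample_id: str
    group: str
    age: float
    shape: tuple[int, int]  # (nx, ny)
    coords: np.ndarray  # (n_pixels, 2) int, unique
    mz: np.ndarray  # (n_peaks,) float64
    intensity: np.ndarray  # (n_peaks,) float64, >= 0
    pixel_index: np.ndarray  # (n_peaks,) int, into coords

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        if len({tuple(c) for c in self.coords.tolist()}) != len(self.coords):
            raise ValueError(f"{self.sample_id}: duplicate pixel coordinates")
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.sample_id}: negative intensities")
        if len(self.mz) != len(self.intensity) or len(self.mz) != len(self.pixel_index):
            raise ValueError(f"{self.sample_id}: ragged peak arrays")
        order = np.lexsort((self.mz, self.pixel_index))
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.pixel_index = self.pixel_index[order]

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def spectrum(self, pixel: int) -> tuple[np.ndarray, np.ndarray]:
        """(m/z, intensity) arrays of one pixel, sorted by m/z."""
        sel = self.pixel_index == pixel
        return self.mz[sel], self.intensity[sel]

    def tic(self) -> np.ndarray:
        """Total ion current per pixel (zeros for peakless pixels)."""
        return np.bincount(
            self.pixel_index, weights=self.intensity, minlength=self.n_pixels
        )

    def with_peaks(
        self, mz: np.ndarray, intensity: np.ndarray, pixel_index: np.ndarray
    ) -> "Sample":
        return replace(self, mz=mz, intensity=intensity, pixel_index=pixel_index)


@dataclass
class MSIDataset:
    """A set of samples acquired in one ionization mode."""

    samples: list[Sample]
    mode: Literal["positive", "negative"] = "positive"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample {sample_id!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def total_pixels(self) -> int:
        return sum(s.n_pixels for s in self.samples)

    def total_peaks(self) -> int:
        return sum(s.n_peaks for s in self.samples)


def _metadata_dict(dataset: MSIDataset) -> dict:
    return {
        "mode": dataset.mode,
        "samples": [
            {
                "id": s.sample_id,
                "group": s.group,
                "age": s.age,
                "shape": list(s.shape),
            }
            for s in dataset.samples
        ],
    }


def write_dataset(
    dataset: MSIDataset, path: str | Path, format: str = "csv"
) -> Path:
    """Write a dataset to ``path`` (a directory, created if needed).

    ``format="csv"`` writes ``peaks.csv`` + ``metadata.json``;
    ``format="imzml"`` writes one ``<sample>.imzML``/``.ibd`` pair per
    sample (centroided, float64 m/z and intensity) + ``metadata.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = _metadata_dict(dataset)
    if format == "csv":
        lines = ["sample,x,y,mz,intensity"]
        for s in dataset:
            xs = s.coords[s.pixel_index]
            for (x, y), m, i in zip(xs.tolist(), s.mz.tolist(), s.intensity.tolist()):
                lines.append(f"{s.sample_id},{x},{y},{m!r},{i!r}")
        (path / "peaks.csv").write_text("\n".join(lines) + "\n")
    elif format == "imzml":
        from pyimzml.ImzMLWriter import ImzMLWriter

        for s in dataset:
            with ImzMLWriter(
                str(path / f"{s.sample_id}.imzML"),
                mz_dtype=np.float64,
                intensity_dtype=np.float64,
                mode="processed",
            ) as writer:
                for pix in range(s.n_pixels):
                    mz, inten = s.spectrum(pix)
                    x, y = s.coords[pix]
                    # imzML coordinates are 1-based
                    writer.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1, 1))
    else:
        raise FormatError(f"unknown dataset format {format!r}")
    meta["format"] = format
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def _read_csv_peaks(path: Path, meta: dict) -> MSIDataset:
    import pandas as pd

    f = path / "peaks.csv"
    try:
        df = pd.read_csv(f, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{f}: cannot parse ({exc})") from exc
    required = {"sample", "x", "y", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"{f}: header must contain {sorted(required)}")
    samples = []
    for sm in meta["samples"]:
        sub = df[df["sample"] == sm["id"]]
        nx, ny = sm["shape"]
        coords = np.array([(x, y) for x in range(nx) for y in range(ny)])
        key = {tuple(c): i for i, c in enumerate(coords.tolist())}
        try:
            pix = np.array(
                [key[(int(x), int(y))] for x, y in zip(sub["x"], sub["y"])]
            )
        except KeyError as exc:
            raise FormatError(f"{f}: pixel {exc} outside grid of {sm['id']}")
        samples.append(
            Sample(
                sample_id=sm["id"],
                group=sm["group"],
                age=float(sm["age"]),
                shape=(nx, ny),
                coords=coords,
                mz=sub["mz"].to_numpy(),
                intensity=sub["intensity"].to_numpy(),
                pixel_index=pix,
            )
        )
    return MSIDataset(samples=samples, mode=meta["mode"])


def _read_imzml(path: Path, meta: dict) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    samples = []
    for sm in meta["samples"]:
        f = path / f"{sm['id']}.imzML"
        if not f.exists():
            raise FormatError(f"missing imzML file {f}")
        parser = ImzMLParser(str(f))
        nx, ny = sm["shape"]
        coords = np.array([(x, y) for x in range(nx) for y in range(ny)])
        key = {tuple(c): i for i, c in enumerate(coords.tolist())}
        mzs, intens, pix = [], [], []
        for idx, (x, y, _z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(idx)
            mzs.append(np.asarray(mz, dtype=float))
            intens.append(np.asarray(inten, dtype=float))
            pix.append(np.full(len(mz), key[(x - 1, y - 1)]))
        samples.append(
            Sample(
                sample_id=sm["id"],
                group=sm["group"],
                age=float(sm["age"]),
                shape=(nx, ny),
                coords=coords,
                mz=np.concatenate(mzs) if mzs else np.empty(0),
                intensity=np.concatenate(intens) if intens else np.empty(0),
                pixel_index=np.concatenate(pix).astype(int) if pix else np.empty(0, int),
            )
        )
    return MSIDataset(samples=samples, mode=meta["mode"])


def read_dataset(path: str | Path, format: str | None = None) -> MSIDataset:
    """Read a dataset written by :func:`write_dataset`.

    ``format=None`` autodetects from the ``metadata.json`` sidecar.
    Malformed or truncated files raise :class:`FormatError` naming the file.
    """
    path = Path(path)
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise FormatError(f"missing metadata sidecar {meta_file}")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_file}: invalid JSON at {exc.pos}") from exc
    for k in ("mode", "samples"):
        if k not in meta:
            raise FormatError(f"{meta_file}: missing key {k!r}")
    fmt = format or meta.get("format", "csv")
    if fmt == "csv":
        return _read_csv_peaks(path, meta)
    if fmt == "imzml":
        return _read_imzml(path, meta)
    raise FormatError(f"unknown dataset format {fmt!r}")
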