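"""Centroided peak lists and the core :class:`Spectrum` container.

A spectrum is an ordered set of (m/z, intensity) peaks.  m/z is the
mass-to-charge ratio in Thomson; intensities are in arbitrary instrument
units for raw data, or dimensionless after standardization.  Peaks are kept
strictly ascending in m/z; zero or negative intensities are rejected at
ingest because the downstream power-law model is only defined for positive
signal.

The canonical interchange format is a TSV/CSV peak list: optional leading
``#``-comment lines carrying ``key=value`` metadata, a ``mz<sep>intensity``
header, then one row per peak.  Centroided mzML is supported read-only
through a minimal XML reader that consumes only the m/z and intensity
binary arrays.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import IngestError

logger = logging.getLogger(__name__)

__all__ = ["Scale", "Peak", "Spectrum", "read_peaklist", "write_peaklist"]


class Scale(str, enum.Enum):
    """Intensity scale tag: raw instrument units or standardized (dimensionless)."""

    raw = "raw"
    standardized = "standardized"


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """Immutable centroided spectrum: peaks strictly ascending in m/z.

    Construct directly only from already-canonical arrays; use
    :meth:`from_arrays` for arbitrary input (it sorts, merges duplicate m/z
    values and validates).
    """

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    scale: Scale = Scale.raw

    def __post_init__(self) -> None:
        mz = np.ascontiguousarray(self.mz, dtype=float)
        intensity = np.ascontiguousarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1 or mz.shape != intensity.shape:
            raise IngestError("mz and intensity must be 1-d arrays of equal length")
        if mz.size == 0:
            raise IngestError("spectrum must contain at least one peak")
        if not np.all(np.isfinite(mz)) or not np.all(np.isfinite(intensity)):
            raise IngestError("non-finite m/z or intensity value")
        if np.any(mz <= 0):
            raise IngestError("all m/z values must be > 0")
        if np.any(intensity <= 0):
            raise IngestError("all intensities must be > 0")
        if np.any(np.diff(mz) <= 0):
            raise IngestError("m/z values must be strictly ascending")
        object.__setattr__(self, "scale", Scale(self.scale))

    @classmethod
    def from_arrays(
        cls,
        mz,
        intensity,
        label: str = "",
        scale: Scale | str = Scale.raw,
    ) -> "Spectrum":
        """Build a spectrum from unordered arrays.

        Rows are sorted ascending by m/z; duplicate m/z values are merged by
        summing their intensities (centroided duplicates are instrument
        artifacts and summing preserves total ion signal) with a logged
        warning.  Nothing is dropped silently.
        """
        mz = np.asarray(mz, dtype=float).ravel()
        intensity = np.asarray(intensity, dtype=float).ravel()
        if mz.size != intensity.size:
            raise IngestError("mz and intensity must have the same length")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
        if uniq.size != mz.size:
            n_dup = int(mz.size - uniq.size)
            logger.warning(
                "merged %d duplicate m/z value(s) by summing intensities", n_dup
            )
            intensity = np.bincount(inverse, weights=intensity)
            mz = uniq
        return cls(mz=mz, intensity=intensity, label=label, scale=scale)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return int(self.mz.size)

    def __iter__(self) -> Iterator[Peak]:
        for m, i in zip(self.mz, self.intensity):
            yield Peak(float(m), float(i))

    @property
    def mz_range(self) -> tuple[float, float]:
        return float(self.mz[0]), float(self.mz[-1])

    @property
    def mz_span(self) -> float:
        return float(self.mz[-1] - self.mz[0])

    def slice_mz(self, lo: float, hi: float) -> np.ndarray:
        """Intensities of peaks with m/z in the half-open interval [lo, hi)."""
        i0 = int(np.searchsorted(self.mz, lo, side="left"))
        i1 = int(np.searchsorted(self.mz, hi, side="left"))
        return self.intensity[i0:i1]

    def with_intensity(self, intensity, scale: Scale | str | None = None) -> "Spectrum":
        """Copy with new intensities (same m/z grid)."""
        return replace(
            self,
            intensity=np.asarray(intensity, dtype=float),
            scale=Scale(scale) if scale is not None else self.scale,
        )


# ---------------------------------------------------------------------------
# tabular I/O


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path: Path, sep: str) -> Spectrum:
    meta = _read_metadata(path)
    try:
        frame = pd.read_csv(
            path, sep=sep, comment="#", header=0, float_precision="round_trip"
        )
    except Exception as exc:  # pandas raises several parser error types
        raise IngestError(f"cannot parse peak list {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise IngestError(f"{path}: expected at least 2 columns (mz, intensity)")
    mz = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy()
    intensity = pd.to_numeric(frame.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(mz) | ~np.isfinite(intensity))
    if bad.size:
        raise IngestError(f"{path}: non-numeric value in data row {bad[0]}")
    nonpos = np.flatnonzero(intensity <= 0)
    if nonpos.size:
        raise IngestError(
            f"{path}: non-positive intensity {intensity[nonpos[0]]:g} "
            f"in data row {nonpos[0]}"
        )
    badmz = np.flatnonzero(mz <= 0)
    if badmz.size:
        raise IngestError(f"{path}: non-positive m/z in data row {badmz[0]}")
    return Spectrum.from_arrays(
        mz,
        intensity,
        label=meta.get("label", path.stem),
        scale=meta.get("scale", Scale.raw),
    )


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in bda.iter() if cv.tag.endswith("cvParam")
    }
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    node = next(el for el in bda.iter() if el.tag.endswith("}binary"))
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, scan: str) -> Spectrum:
    """Minimal centroided-mzML reader (m/z and intensity arrays only)."""
    from lxml import etree

    mzs: list[np.ndarray] = []
    intensities: list[np.ndarray] = []
    tree = etree.parse(str(path))
    spectra = [el for el in tree.iter() if el.tag.endswith("}spectrum")]
    for spectrum_el in spectra:
        accessions = {
            cv.get("accession")
            for cv in spectrum_el.iter()
            if cv.tag.endswith("cvParam")
        }
        if "MS:1000128" in accessions:  # profile spectrum
            raise IngestError(
                f"{path}: profile-mode spectrum found; only centroided "
                "mzML is supported"
            )
        mz_arr = intensity_arr = None
        for bda in spectrum_el.iter():
            if not bda.tag.endswith("}binaryDataArray"):
                continue
            accs = {
                cv.get("accession")
                for cv in bda.iter()
                if cv.tag.endswith("cvParam")
            }
            if "MS:1000514" in accs:
                mz_arr = _decode_binary_array(bda)
            elif "MS:1000515" in accs:
                intensity_arr = _decode_binary_array(bda)
        if mz_arr is None or intensity_arr is None:
            raise IngestError(f"{path}: spectrum lacks m/z or intensity array")
        mzs.append(mz_arr)
        intensities.append(intensity_arr)
        if scan == "first":
            break
    if not mzs:
        raise IngestError(f"{path}: no spectra found in mzML")
    mz = np.concatenate(mzs)
    intensity = np.concatenate(intensities)
    keep = intensity > 0
    n_rejected = int(np.count_nonzero(~keep))
    if n_rejected:
        logger.warning(
            "%s: dropped %d non-positive-intensity centroid(s)", path, n_rejected
        )
    if not np.any(keep):
        raise IngestError(f"{path}: no positive-intensity peaks")
    return Spectrum.from_arrays(mz[keep], intensity[keep], label=path.stem)


def read_peaklist(path, format: str | None = None, scan: str = "sum") -> Spectrum:
    """Read a centroided peak list from TSV, CSV or mzML.

    Parameters
    ----------
    path : str or Path
    format : {"tsv", "csv", "mzml"}, optional
        Inferred from the file suffix when omitted.
    scan : {"sum", "first"}
        For mzML only: combine all centroided scans or use the first one.

    Returns
    -------
    Spectrum
        Sorted ascending by m/z, ``scale`` taken from metadata (default raw).
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"peak list not found: {path}")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mzml": "mzml"}.get(
            suffix, "tsv"
        )
    if format == "tsv":
        return _read_table(path, sep="\t")
    if format == "csv":
        return _read_table(path, sep=",")
    if format == "mzml":
        if scan not in ("sum", "first"):
            raise ValueError("scan must be 'sum' or 'first'")
        return _read_mzml(path, scan)
    raise ValueError(f"unknown peak list format: {format!r}")


def write_peaklist(spectrum: Spectrum, path, format: str = "tsv") -> None:
    """Write a spectrum as a TSV/CSV peak list.

    The file starts with ``#``-comment metadata lines (label, scale), then a
    header row and one row per peak with full float precision so that a
    read/write round trip is lossless.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported output format: {format!r}")
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(f"# label={spectrum.label}\n")
            fh.write(f"# scale={spectrum.scale.value}\n")
            fh.write(f"mz{sep}intensity\n")
            for m, i in zip(spectrum.mz, spectrum.intensity):
                fh.write(f"{m:.17g}{sep}{i:.17g}\n")
    except OSError as exc:
        raise IngestError(f"cannot write peak list {path}: {exc}") from exc
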