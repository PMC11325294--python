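"""Text-first file formats: traces, spectra, JCAMP-DX, library manifests.

All native formats are delimited text with a ``#``-prefixed JSON header
line, so files are inspectable and diff-able. Floats are written with
17 significant digits, which round-trips IEEE double exactly.

* trace files: columns ``time_fs``, ``amplitude``;
* spectrum files: columns ``wavenumber_cm1``, ``real``, ``imag``
  (complex data) or ``wavenumber_cm1``, ``magnitude`` (real data);
* spectral libraries: a directory of spectrum files plus
  ``manifest.json`` mapping entry names to files;
* JCAMP-DX: a reader for the plain AFFN ``(X++(Y..Y))`` dialect used
  by common IR databases, for importing conventional absorbance
  spectra.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .core import ComplexSpectrum, FormatError, FRSError, TimeTrace
from .analysis import SpectralLibrary

__all__ = [
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "read_jcamp",
    "read_library",
    "write_library",
]

_FLOAT_FMT = "%.17g"


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, complex):
        return {"real": obj.real, "imag": obj.imag}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _read_header(path: Path) -> tuple[dict, list[str]]:
    """Split a file into its JSON header dict and the data lines."""
    header: dict = {}
    data_lines: list[str] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("{"):
                    try:
                        header.update(json.loads(body))
                    except json.JSONDecodeError as exc:
                        raise FormatError(f"{path}: malformed JSON header: {exc}") from exc
            else:
                data_lines.append(line)
    return header, data_lines


def _parse_columns(path: Path, lines: list[str], ncols: int) -> np.ndarray:
    try:
        arr = np.array([[float(x) for x in ln.split()] for ln in lines])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] != ncols:
        raise FormatError(f"{path}: expected {ncols} columns, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: TimeTrace, path: os.PathLike | str) -> None:
    path = Path(path)
    header = {"format": "frs-trace", "version": 1, "meta": _jsonable(trace.meta)}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# time_fs amplitude\n")
        for ti, vi in zip(trace.t, trace.values):
            fh.write(f"{ti:.17g} {vi:.17g}\n")


def read_trace(path: os.PathLike | str) -> TimeTrace:
    path = Path(path)
    header, lines = _read_header(path)
    if header.get("format") != "frs-trace":
        raise FormatError(f"{path}: not an frs-trace file (missing/garbled header)")
    arr = _parse_columns(path, lines, 2)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: trace contains non-finite values")
    try:
        return TimeTrace(arr[:, 0], arr[:, 1], header.get("meta", {}))
    except FRSError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def write_spectrum(spec: ComplexSpectrum, path: os.PathLike | str) -> None:
    path = Path(path)
    is_complex = np.iscomplexobj(spec.values)
    header = {
        "format": "frs-spectrum",
        "version": 1,
        "columns": ["wavenumber_cm1", "real", "imag"] if is_complex else ["wavenumber_cm1", "magnitude"],
        "meta": _jsonable(spec.meta),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# " + " ".join(header["columns"]) + "\n")
        if is_complex:
            for ni, vi in zip(spec.nu, spec.values):
                fh.write(f"{ni:.17g} {vi.real:.17g} {vi.imag:.17g}\n")
        else:
            for ni, vi in zip(spec.nu, spec.values):
                fh.write(f"{ni:.17g} {float(vi):.17g}\n")


def read_spectrum(path: os.PathLike | str) -> ComplexSpectrum:
    path = Path(path)
    header, lines = _read_header(path)
    if header.get("format") != "frs-spectrum":
        raise FormatError(f"{path}: not an frs-spectrum file")
    cols = header.get("columns", [])
    if cols == ["wavenumber_cm1", "real", "imag"]:
        arr = _parse_columns(path, lines, 3)
        values: np.ndarray = arr[:, 1] + 1j * arr[:, 2]
    elif cols == ["wavenumber_cm1", "magnitude"]:
        arr = _parse_columns(path, lines, 2)
        values = arr[:, 1]
    else:
        raise FormatError(f"{path}: unknown column schema {cols}")
    try:
        return ComplexSpectrum(arr[:, 0], values, header.get("meta", {}))
    except FRSError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JCAMP-DX import
# ---------------------------------------------------------------------------

def read_jcamp(path: os.PathLike | str) -> tuple[np.ndarray, np.ndarray]:
    """Read a JCAMP-DX file with an AFFN ``(X++(Y..Y))`` data table.

    Returns ``(nu, values)`` with the abscissa converted to cm^-1 and
    sorted ascending (values reordered accordingly). Supported XUNITS:
    ``1/CM`` and ``MICROMETERS``. Compressed ordinate dialects
    (SQZ/DIF/DUP, PAC) are rejected with an explicit error.
    """
    path = Path(path)
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            if line.startswith("##"):
                label, _, value = line[2:].partition("=")
                label = label.strip().upper().replace(" ", "")
                value = value.strip()
                if label == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise FormatError(f"{path}: unsupported XYDATA form {value!r}")
                    in_data = True
                elif label == "END":
                    in_data = False
                else:
                    records[label] = value
            elif in_data:
                data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no XYDATA table found")
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in records:
            raise FormatError(f"{path}: missing required record ##{req}")
    xfactor = float(records.get("XFACTOR", "1"))
    yfactor = float(records.get("YFACTOR", "1"))
    npoints = int(float(records["NPOINTS"]))
    ys: list[float] = []
    for ln in data_lines:
        toks = ln.replace(",", " ").split()
        for tok in toks[1:]:
            try:
                ys.append(float(tok))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: unsupported (compressed?) ordinate token {tok!r}; "
                    "only plain AFFN tables are supported"
                ) from exc
    if len(ys) != npoints:
        raise FormatError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read")
    x = np.linspace(float(records["FIRSTX"]), float(records["LASTX"]), npoints) * xfactor
    y = np.asarray(ys) * yfactor
    xunits = records.get("XUNITS", "1/CM").upper()
    if xunits in ("1/CM", "CM-1", "CM^-1"):
        nu = x
    elif xunits == "MICROMETERS":
        if np.any(x <= 0):
            raise FormatError(f"{path}: non-positive wavelength cannot be converted")
        nu = 1e4 / x
    else:
        raise FormatError(f"{path}: unsupported XUNITS {records.get('XUNITS')!r}")
    order = np.argsort(nu)
    return nu[order], y[order]


# ---------------------------------------------------------------------------
# spectral libraries
# ---------------------------------------------------------------------------

def write_library(lib: SpectralLibrary, directory: os.PathLike | str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"format": "frs-library", "version": 1, "entries": {}}
    for name, vals in lib.entries.items():
        fname = f"{name}.csv"
        write_spectrum(ComplexSpectrum(lib.grid, np.asarray(vals, dtype=float), {"name": name}),
                       directory / fname)
        manifest["entries"][name] = fname
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_library(directory: os.PathLike | str) -> SpectralLibrary:
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"{directory}: missing manifest.json")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "frs-library":
        raise FormatError(f"{mpath}: not an frs-library manifest")
    grid: np.ndarray | None = None
    entries: dict[str, np.ndarray] = {}
    for name, fname in manifest.get("entries", {}).items():
        spec = read_spectrum(directory / fname)
        if np.iscomplexobj(spec.values):
            raise FormatError(f"{directory / fname}: library entries must be real magnitude spectra")
        if grid is None:
            grid = spec.nu
        elif spec.nu.shape != grid.shape or np.max(np.abs(spec.nu - grid)) > 1e-9:
            raise FormatError(f"{directory / fname}: entry grid differs from the library grid")
        entries[name] = spec.values.astype(float)
    if grid is None:
        raise FormatError(f"{directory}: library has no entries")
    return SpectralLibrary(grid=grid, entries=entries)
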