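"""Readers/writers for the text formats, external-dataset adapter, run config.

Formats
-------
* Spectrum CSV: two columns ``wavenumber_cm-1,intensity`` with header.
* Dipole CSV: columns ``t_fs,mx,my,mz`` with header.
* Library JSON: ``{"schema": "irmix-library/1", "entries": [...]}`` where
  each entry carries id, name, Hill formula, phase, its grid and the
  intensity vector.
* Mixtures JSON: ``{"schema": "irmix-mixtures/1", "mixtures": [...]}`` with
  ground-truth identities and fractions.

The external-dataset adapter maps a user-downloaded deposit of per-molecule
CSV spectra onto the library schema via a declarative mapping; it never
downloads anything.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from .dipole import DipoleTrajectory
from .exceptions import (
    AdapterError,
    FormatError,
    InvalidConfigurationError,
    SchemaValidationError,
)
from .identify import MixtureRecord
from .library import LibraryEntry, SpectralLibrary
from .spectra import RawSpectrum, Spectrum, WavenumberGrid

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_dipole",
    "read_library",
    "write_library",
    "read_mixtures",
    "write_mixtures",
    "adapt_external_dataset",
    "RunConfig",
    "write_manifest",
]

LIBRARY_SCHEMA = "irmix-library/1"
MIXTURES_SCHEMA = "irmix-mixtures/1"


def read_spectrum(path: str) -> RawSpectrum:
    """Read a two-column spectrum CSV with strict format checking.

    Errors name the offending CSV line (header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    expected = ["wavenumber_cm-1", "intensity"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {','.join(expected)!r}, got {list(df.columns)}")
    for col in expected:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
        df[col] = vals
    w = df["wavenumber_cm-1"].to_numpy(float)
    if len(w) >= 2:
        drops = np.where(np.diff(w) <= 0)[0]
        if len(drops):
            raise FormatError(f"{path}: wavenumbers not strictly increasing at line {drops[0] + 3}")
    if len(w) < 2:
        raise FormatError(f"{path}: a spectrum needs at least 2 data lines")
    return RawSpectrum(w, df["intensity"].to_numpy(float))


def write_spectrum(spec: Spectrum | RawSpectrum, path: str) -> None:
    """Write a spectrum to the two-column CSV format (full float precision)."""
    w = spec.wavenumbers
    x = spec.intensities
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavenumber_cm-1,intensity\n")
        for wi, xi in zip(w, x):
            fh.write(f"{float(wi)!r},{float(xi)!r}\n")


def read_dipole(path: str, temperature: float | None = None) -> DipoleTrajectory:
    """Read a dipole time-series CSV (columns ``t_fs,mx,my,mz``)."""
    df = pd.read_csv(path)
    expected = ["t_fs", "mx", "my", "mz"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {','.join(expected)!r}, got {list(df.columns)}")
    t = df["t_fs"].to_numpy(float)
    steps = np.diff(t)
    if len(t) < 2 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: time samples must be uniformly spaced")
    return DipoleTrajectory(
        timestep_fs=float(steps[0]),
        samples=df[["mx", "my", "mz"]].to_numpy(float),
        temperature=temperature,
    )


def _grid_to_json(grid: WavenumberGrid) -> dict:
    return {"start": grid.start, "step": grid.step, "n_points": grid.n_points}


def _grid_from_json(obj: dict, where: str) -> WavenumberGrid:
    try:
        return WavenumberGrid(float(obj["start"]), float(obj["step"]), int(obj["n_points"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaValidationError(f"{where}: invalid grid object ({exc})") from exc


def write_library(library: SpectralLibrary, path: str) -> None:
    """Serialize a library to the versioned JSON schema."""
    doc = {
        "schema": LIBRARY_SCHEMA,
        "entries": [
            {
                "id": e.id,
                "name": e.name,
                "formula": e.formula,
                "phase": e.phase,
                "grid": _grid_to_json(e.spectrum.grid),
                "intensities": e.spectrum.intensities.tolist(),
                "normalized": e.spectrum.normalized,
            }
            for e in library
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_library(path: str, require_formulas: bool = False) -> SpectralLibrary:
    """Read and schema-validate a library JSON file.

    Validation errors name the JSON path of the offending field.  Missing
    formulas are tolerated (with downstream warnings) unless
    ``require_formulas`` is set, as the atom filter does.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != LIBRARY_SCHEMA:
        raise SchemaValidationError(f"$.schema: expected {LIBRARY_SCHEMA!r}")
    entries_json = doc.get("entries")
    if not isinstance(entries_json, list) or not entries_json:
        raise SchemaValidationError("$.entries: must be a non-empty array")
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for i, rec in enumerate(entries_json):
        where = f"$.entries[{i}]"
        if not isinstance(rec, dict):
            raise SchemaValidationError(f"{where}: must be an object")
        for key in ("id", "phase", "grid", "intensities"):
            if key not in rec:
                raise SchemaValidationError(f"{where}.{key}: missing")
        if rec["id"] in seen:
            raise SchemaValidationError(f"{where}.id: duplicate id {rec['id']!r}")
        seen.add(rec["id"])
        if rec["phase"] not in ("gas", "liquid"):
            raise SchemaValidationError(f"{where}.phase: must be 'gas' or 'liquid'")
        if require_formulas and not rec.get("formula"):
            raise SchemaValidationError(f"{where}.formula: required but missing")
        grid = _grid_from_json(rec["grid"], f"{where}.grid")
        x = np.asarray(rec["intensities"], dtype=float)
        if x.size != grid.n_points:
            raise SchemaValidationError(
                f"{where}.intensities: length {x.size} != grid n_points {grid.n_points}"
            )
        entries.append(
            LibraryEntry(
                id=str(rec["id"]),
                spectrum=Spectrum(grid, x, normalized=bool(rec.get("normalized", False))),
                name=str(rec.get("name", rec["id"])),
                formula=rec.get("formula"),
                phase=rec["phase"],
            )
        )
    return SpectralLibrary(entries)


def write_mixtures(mixtures: list[MixtureRecord], path: str) -> None:
    doc = {
        "schema": MIXTURES_SCHEMA,
        "mixtures": [
            {
                "id": m.id,
                "true_components": list(m.true_components),
                "mole_fractions": list(m.mole_fractions),
                "grid": _grid_to_json(m.spectrum.grid),
                "intensities": m.spectrum.intensities.tolist(),
                "normalized": m.spectrum.normalized,
            }
            for m in mixtures
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_mixtures(path: str) -> list[MixtureRecord]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != MIXTURES_SCHEMA:
        raise SchemaValidationError(f"$.schema: expected {MIXTURES_SCHEMA!r}")
    out: list[MixtureRecord] = []
    for i, rec in enumerate(doc.get("mixtures", [])):
        where = f"$.mixtures[{i}]"
        for key in ("id", "true_components", "mole_fractions", "grid", "intensities"):
            if key not in rec:
                raise SchemaValidationError(f"{where}.{key}: missing")
        grid = _grid_from_json(rec["grid"], f"{where}.grid")
        out.append(
            MixtureRecord(
                id=str(rec["id"]),
                true_components=tuple(rec["true_components"]),
                mole_fractions=tuple(float(f) for f in rec["mole_fractions"]),
                spectrum=Spectrum(
                    grid,
                    np.asarray(rec["intensities"], dtype=float),
                    normalized=bool(rec.get("normalized", False)),
                ),
            )
        )
    return out


REQUIRED_MAPPING_KEYS = ("spectra_glob", "wavenumber_column", "intensity_column")


def adapt_external_dataset(path: str, mapping: dict) -> SpectralLibrary:
    """Map a local deposit of per-molecule spectrum CSVs onto the library schema.

    ``mapping`` is declarative:

    * ``spectra_glob`` — glob (relative to ``path``) selecting one CSV per
      pure component;
    * ``wavenumber_column`` / ``intensity_column`` — column names in those
      CSVs;
    * ``phase`` — phase label for all entries (default ``"liquid"``);
    * ``grid`` — optional ``{start, step, n_points}``; defaults to the
      common 0–4996 cm⁻¹, 4 cm⁻¹ grid;
    * ``formulas`` — optional mapping from entry id (the CSV file stem) to
      Hill formula.

    Entries are regridded and preprocessed (clip + unit-area normalization).
    Missing mapping keys raise an :class:`AdapterError` listing every gap;
    nothing is ever downloaded.
    """
    from .spectra import DEFAULT_GRID, preprocess, regrid

    if not os.path.isdir(path):
        raise FileNotFoundError(
            f"{path}: dataset directory not found — download the deposit manually "
            "and point the adapter at the extracted directory"
        )
    gaps = [k for k in REQUIRED_MAPPING_KEYS if k not in mapping]
    if gaps:
        raise AdapterError(f"mapping is missing required keys: {gaps}")
    grid = (
        _grid_from_json(mapping["grid"], "$.grid") if "grid" in mapping else DEFAULT_GRID
    )
    phase = mapping.get("phase", "liquid")
    formulas = mapping.get("formulas", {})
    files = sorted(glob.glob(os.path.join(path, mapping["spectra_glob"])))
    if not files:
        raise AdapterError(f"glob {mapping['spectra_glob']!r} matched no files under {path}")
    entries: list[LibraryEntry] = []
    for f in files:
        df = pd.read_csv(f)
        for col in (mapping["wavenumber_column"], mapping["intensity_column"]):
            if col not in df.columns:
                raise AdapterError(f"{f}: mapped column {col!r} not present")
        raw = RawSpectrum(
            df[mapping["wavenumber_column"]].to_numpy(float),
            df[mapping["intensity_column"]].to_numpy(float),
        )
        cid = os.path.splitext(os.path.basename(f))[0]
        entries.append(
            LibraryEntry(
                id=cid,
                spectrum=preprocess(regrid(raw, grid)),
                name=cid,
                formula=formulas.get(cid),
                phase=phase,
            )
        )
    return SpectralLibrary(entries)


@dataclass(frozen=True)
class RunConfig:
    """Validated benchmark run configuration.

    Unknown keys are rejected so silent typos cannot change a run.
    """

    algorithm: str = "nnls"
    lam: float = 0.0
    k_values: tuple[int, ...] = (2,)
    criteria: tuple[str, ...] = ("exact", "any")
    protocol: str = "distractor"
    sizes: tuple[int, ...] | None = None
    repeats: int = 8
    seed: int = 0
    increment_threshold: float = 0.01
    atom_filter_pool: int = 10

    def __post_init__(self) -> None:
        if self.algorithm not in ("ls", "nnls", "ls-ridge", "nnls-ridge", "pairwise"):
            raise InvalidConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.protocol not in ("distractor", "sweep"):
            raise InvalidConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.lam < 0 or self.repeats < 1 or self.increment_threshold < 0:
            raise InvalidConfigurationError("lam/repeats/increment_threshold out of range")
        if any(k < 1 for k in self.k_values):
            raise InvalidConfigurationError("k values must be >= 1")
        for c in self.criteria:
            if c not in ("exact", "any"):
                raise InvalidConfigurationError(f"unknown criterion {c!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("k_values", "criteria", "sizes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def write_manifest(out_path: str, config: dict, seed: int) -> None:
    """Write a reproducibility manifest next to a CLI output file."""
    import scipy

    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "irmix": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_path + ".manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
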