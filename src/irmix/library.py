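"""Pure-component spectral libraries and basis sets.

A :class:`SpectralLibrary` holds identified pure-component spectra (with
molecular formulas and phase labels) on one shared grid; a
:class:`BasisSet` is the ordered, normalized subset of library spectra a
mixture spectrum is decomposed against — the design matrix of the
least-squares deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .exceptions import InvalidBasisError, UnknownComponentError
from .spectra import Spectrum, WavenumberGrid

__all__ = ["LibraryEntry", "SpectralLibrary", "BasisSet"]


@dataclass(frozen=True)
class LibraryEntry:
    """One identified pure-component spectrum."""

    id: str
    spectrum: Spectrum
    name: str = ""
    formula: str | None = None
    phase: str = "liquid"


class SpectralLibrary:
    """Ordered collection of pure-component spectra on one grid.

    Entry order is significant: it fixes deterministic tie-breaking in
    coefficient ranking and pair selection downstream.
    """

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries: list[LibraryEntry] = list(entries)
        if not self.entries:
            raise InvalidBasisError("library must contain at least one entry")
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidBasisError(f"duplicate library ids: {dup}")
        grid = self.entries[0].spectrum.grid
        for e in self.entries:
            if e.spectrum.grid != grid:
                raise InvalidBasisError(f"entry {e.id!r} is on a different grid")
        self._by_id = {e.id: e for e in self.entries}
        self.grid: WavenumberGrid = grid

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._by_id

    def __getitem__(self, component_id: str) -> LibraryEntry:
        try:
            return self._by_id[component_id]
        except KeyError:
            raise UnknownComponentError(f"unknown component id {component_id!r}") from None

    def subset(self, ids: Iterable[str]) -> "SpectralLibrary":
        """Sub-library of the given ids, preserving library order."""
        wanted = set(ids)
        missing = wanted - set(self._by_id)
        if missing:
            raise UnknownComponentError(f"unknown component ids {sorted(missing)}")
        return SpectralLibrary(e for e in self.entries if e.id in wanted)

    def to_basis(self, ids: Iterable[str] | None = None) -> "BasisSet":
        """Basis set over ``ids`` (default: all entries), in library order."""
        lib = self if ids is None else self.subset(ids)
        return BasisSet(lib.ids, [e.spectrum for e in lib.entries])


class BasisSet:
    """Ordered normalized pure-component spectra forming a design matrix.

    ``matrix`` has shape (n_entries, n_points): one row per component.
    """

    def __init__(self, ids: list[str], spectra: list[Spectrum]):
        if not ids or len(ids) != len(spectra):
            raise InvalidBasisError("basis needs matching, non-empty ids and spectra")
        if len(set(ids)) != len(ids):
            raise InvalidBasisError("basis ids must be unique")
        grid = spectra[0].grid
        for cid, s in zip(ids, spectra):
            if s.grid != grid:
                raise InvalidBasisError(f"basis entry {cid!r} is on a different grid")
            if not s.normalized:
                raise InvalidBasisError(f"basis entry {cid!r} is not normalized")
        self.ids = list(ids)
        self.grid = grid
        self.matrix = np.vstack([s.intensities for s in spectra])

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, component_id: str) -> int:
        try:
            return self.ids.index(component_id)
        except ValueError:
            raise UnknownComponentError(f"{component_id!r} not in basis") from None

    def without(self, component_id: str) -> "BasisSet":
        """Copy of the basis with one component removed."""
        i = self.index_of(component_id)
        ids = self.ids[:i] + self.ids[i + 1 :]
        spectra = [
            Spectrum(self.grid, row, normalized=True)
            for j, row in enumerate(self.matrix)
            if j != i
        ]
        return BasisSet(ids, spectra)
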