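"""Core domain containers: conformations, spin states, charge tables.

The molecular system is a simplified heme site, Fe(C3N2)2(NH3) binding O2.
Its 14 heavy atoms carry the conventional chemical labels Fe, N1..N4,
C5..C10, N11 (the axial amine nitrogen), O12 (the Fe-bound oxygen) and O13.
Internally all atom references are 0-based indices; :data:`ATOM_LABELS`
fixes the label -> index mapping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateGeometryError

#: Elements the package knows about, in canonical feature order.
ELEMENT_ORDER: tuple[str, ...] = ("H", "C", "N", "O", "Fe")

ELEMENT_SET = frozenset(ELEMENT_ORDER)

#: Chemical labels of the 14 heavy atoms of the heme-O2 model, in index order.
ATOM_LABELS: dict[str, int] = {
    "Fe": 0,
    "N1": 1,
    "N2": 2,
    "N3": 3,
    "N4": 4,
    "C5": 5,
    "C6": 6,
    "C7": 7,
    "C8": 8,
    "C9": 9,
    "C10": 10,
    "N11": 11,
    "O12": 12,
    "O13": 13,
}

#: Index -> label, inverse of :data:`ATOM_LABELS`.
ATOM_NAMES: dict[int, str] = {v: k for k, v in ATOM_LABELS.items()}

#: Minimum inter-atomic distance below which a geometry is degenerate (Å).
COINCIDENCE_TOL = 1e-8


class SpinState(enum.Enum):
    """Electronic spin state of the complex, labelled by multiplicity."""

    SINGLET = 1
    TRIPLET = 3
    QUINTUPLET = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def multiplicity(self) -> int:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "SpinState":
        try:
            return cls[label.upper()]
        except KeyError:
            raise DataError(f"unknown spin state label {label!r}") from None


#: The three spin states in canonical (multiplicity) order.
SPIN_STATES: tuple[SpinState, ...] = (
    SpinState.SINGLET,
    SpinState.TRIPLET,
    SpinState.QUINTUPLET,
)


@dataclass
class Structure:
    """One conformation frame: element symbols plus Cartesian coordinates (Å)."""

    elements: tuple[str, ...]
    coords: np.ndarray
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise DataError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if len(self.elements) < 2:
            raise DataError("a structure needs at least 2 atoms")
        unknown = set(self.elements) - ELEMENT_SET
        if unknown:
            raise DataError(f"unknown element symbols: {sorted(unknown)}")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("non-finite coordinates")
        d = self.distance_matrix()
        np.fill_diagonal(d, np.inf)
        if d.min() < COINCIDENCE_TOL:
            i, j = np.unravel_index(int(np.argmin(d)), d.shape)
            raise DegenerateGeometryError(
                f"atoms {i} and {j} are coincident in frame {self.frame_id}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def composition(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.elements:
            counts[e] = counts.get(e, 0) + 1
        return counts


@dataclass
class ChargeTable:
    """Per-atom partial charges (e) of one frame for all three spin states.

    ``charges`` has shape (n_atoms, 3) with columns ordered singlet,
    triplet, quintuplet (the order of :data:`SPIN_STATES`).
    """

    frame_id: int
    atom_index: np.ndarray
    elements: tuple[str, ...]
    charges: np.ndarray

    def __post_init__(self) -> None:
        self.atom_index = np.asarray(self.atom_index, dtype=int)
        self.elements = tuple(self.elements)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.atom_index)
        if self.charges.shape != (n, 3):
            raise DataError(
                f"charges shape {self.charges.shape} != ({n}, 3) in frame "
                f"{self.frame_id}"
            )
        if len(self.elements) != n:
            raise DataError("elements/atom_index length mismatch")
        if not np.all(np.isfinite(self.charges)):
            raise DataError(f"non-finite charge in frame {self.frame_id}")
        if len(np.unique(self.atom_index)) != n:
            raise DataError(f"duplicate atom_index in frame {self.frame_id}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_index)

    def charge(self, spin: SpinState) -> np.ndarray:
        return self.charges[:, SPIN_STATES.index(spin)]


@dataclass
class Dataset:
    """Aligned structures and charge tables, paired by list position."""

    structures: list[Structure]
    tables: list[ChargeTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tables and len(self.tables) != len(self.structures):
            raise DataError("structures and tables differ in length")

    def __len__(self) -> int:
        return len(self.structures)
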