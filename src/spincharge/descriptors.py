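"""Geometry descriptors: atom-centered symmetry functions and internal coordinates.

Two featurization schemes are provided.

**Symmetry functions.** Each atom i is described by a fixed-length vector of
radial and angular terms that are invariant under rotation, translation and
permutation of same-element atoms:

* radial, one component per element J::

      G_i,J = sum_{j != i, j in J} exp(-eta (R_ij - Rs)^2) fc(R_ij)

* angular, one component per unordered element pair {J, K}::

      G_i,JK = 2^(1-zeta) sum_{ {j,k} } (1 + lam cos theta_jik)^zeta
               * exp(-eta (R_ij^2 + R_ik^2 + R_jk^2))
               * fc(R_ij) fc(R_ik) fc(R_jk)

  where the sum runs over unordered neighbor pairs {j, k} covering {J, K},
  each pair counted once, and theta_jik is the angle at vertex i.

fc is the smooth cosine cutoff ``0.5 (cos(pi r / Rc) + 1)`` for r <= Rc and
0 beyond. With the default Rc = 99 Å every atom of a small molecule is
inside the cutoff; the cutoff exists so descriptors stay continuous if
atoms ever cross Rc. Components that are identically zero for every atom
purely by composition (e.g. the Fe-Fe angular pair when the molecule holds
a single Fe) are dropped from the layout; for the heme-O2 model with
hydrogens (elements H, C, N, O, Fe) this yields p = 19 components.

**Internal coordinates.** A manually selected set of distances, bond angles
and dihedrals; the default definition is the 11-parameter set describing
the heme-O2 binding geometry (eight Fe/O distances, the Fe-O12-O13 angle,
and two ring dihedrals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, LayoutError
from .structure import ATOM_LABELS, ELEMENT_ORDER, Structure

__all__ = [
    "SymmetryFunctionParams",
    "DescriptorLayout",
    "InternalDescriptorDefinition",
    "cutoff",
    "radial_term",
    "angular_term",
    "build_layout",
    "featurize",
    "featurize_frames",
    "distance",
    "angle",
    "dihedral",
    "internal_descriptors",
    "default_internal_definition",
]

_EPS = 1e-8


@dataclass(frozen=True)
class SymmetryFunctionParams:
    """Hyperparameters of the radial/angular symmetry functions.

    Defaults follow the single-function-per-component setup used for the
    heme model: eta = 1 Å^-2, Rs = 1 Å, Rc = 99 Å (all atoms inside),
    lam = +1, zeta = 1.
    """

    eta: float = 1.0
    rs: float = 1.0
    rc: float = 99.0
    lam: float = 1.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ConfigError("Rc must be positive")
        if self.zeta <= 0:
            raise ConfigError("zeta must be positive")
        if self.lam not in (-1.0, 1.0):
            raise ConfigError("lambda must be -1 or +1")
        if self.eta < 0:
            raise ConfigError("eta must be non-negative")


@dataclass(frozen=True)
class DescriptorLayout:
    """Fixed component ordering of a symmetry-function vector.

    Radial components (one per element, in ``element_order``) come first,
    then angular components (one per unordered element pair, lexicographic
    in ``element_order``), minus any composition-dropped pairs.
    """

    element_order: tuple[str, ...]
    radial_components: tuple[str, ...]
    angular_components: tuple[tuple[str, str], ...]
    dropped_components: tuple[tuple[str, str], ...] = ()

    @property
    def size(self) -> int:
        return len(self.radial_components) + len(self.angular_components)

    def component_names(self) -> list[str]:
        return [f"radial_{e}" for e in self.radial_components] + [
            f"angular_{j}_{k}" for j, k in self.angular_components
        ]


def cutoff(r, rc: float):
    """Cosine cutoff weight: 1 at r=0, 0 at r>=Rc, smooth in between."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ConfigError("distance must be non-negative")
    if rc <= 0:
        raise ConfigError("Rc must be positive")
    w = np.where(r_arr < rc, 0.5 * (np.cos(np.pi * r_arr / rc) + 1.0), 0.0)
    return float(w) if np.isscalar(r) or w.ndim == 0 else w


def _check_distances(structure: Structure, d: np.ndarray) -> None:
    off = d + np.eye(structure.n_atoms) * 1.0
    if off.min() < _EPS:
        i, j = np.unravel_index(int(np.argmin(off)), off.shape)
        raise DegenerateGeometryError(
            f"atoms {i} and {j} coincide in frame {structure.frame_id}"
        )


def radial_term(
    structure: Structure,
    i: int,
    element: str,
    params: SymmetryFunctionParams = SymmetryFunctionParams(),
) -> float:
    """Radial symmetry function of atom i for neighbor element ``element``."""
    d = structure.distance_matrix()
    _check_distances(structure, d)
    total = 0.0
    for j, ej in enumerate(structure.elements):
        if j == i or ej != element:
            continue
        rij = d[i, j]
        total += math.exp(-params.eta * (rij - params.rs) ** 2) * cutoff(
            rij, params.rc
        )
    return total


def angular_term(
    structure: Structure,
    i: int,
    elem_j: str,
    elem_k: str,
    params: SymmetryFunctionParams = SymmetryFunctionParams(),
) -> float:
    """Angular symmetry function of atom i for the unordered pair {J, K}.

    Each unordered neighbor pair is counted once, so the value is symmetric
    in (J, K). Returns 0 when no qualifying pair exists.
    """
    d = structure.distance_matrix()
    _check_distances(structure, d)
    coords = structure.coords
    n = structure.n_atoms
    prefactor = 2.0 ** (1.0 - params.zeta)
    total = 0.0
    for j in range(n):
        if j == i:
            continue
        for k in range(j + 1, n):
            if k == i:
                continue
            pair = {structure.elements[j], structure.elements[k]}
            if pair != {elem_j, elem_k}:
                continue
            rij, rik, rjk = d[i, j], d[i, k], d[j, k]
            vj = coords[j] - coords[i]
            vk = coords[k] - coords[i]
            cos_t = float(np.dot(vj, vk) / (rij * rik))
            cos_t = max(-1.0, min(1.0, cos_t))
            total += (
                (1.0 + params.lam * cos_t) ** params.zeta
                * math.exp(-params.eta * (rij**2 + rik**2 + rjk**2))
                * cutoff(rij, params.rc)
                * cutoff(rik, params.rc)
                * cutoff(rjk, params.rc)
            )
    return prefactor * total


def build_layout(
    composition: dict[str, int],
    element_order: tuple[str, ...] = ELEMENT_ORDER,
) -> DescriptorLayout:
    """Build the descriptor layout for a molecular composition.

    The layout is a pure function of composition. An angular pair {J, K} is
    dropped when no atom of the molecule can have two *distinct* neighbors
    covering the pair — e.g. any pair requiring two atoms of an element the
    molecule holds only once.
    """
    if not composition:
        raise ConfigError("empty composition")
    unknown = set(composition) - set(element_order)
    if unknown:
        raise LayoutError(f"elements {sorted(unknown)} not in element order")
    present = [e for e in element_order if composition.get(e, 0) > 0]
    radial = tuple(present)
    angular: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []
    for a_i, ej in enumerate(present):
        for ek in present[a_i:]:
            if _pair_realizable(composition, ej, ek):
                angular.append((ej, ek))
            else:
                dropped.append((ej, ek))
    return DescriptorLayout(
        element_order=tuple(element_order),
        radial_components=radial,
        angular_components=tuple(angular),
        dropped_components=tuple(dropped),
    )


def _pair_realizable(composition: dict[str, int], ej: str, ek: str) -> bool:
    # Some atom i must remain able to see distinct neighbors of elements
    # {ej, ek} after excluding itself from the neighbor pool.
    for center in composition:
        pool = dict(composition)
        pool[center] -= 1
        if ej == ek:
            if pool.get(ej, 0) >= 2:
                return True
        elif pool.get(ej, 0) >= 1 and pool.get(ek, 0) >= 1:
            return True
    return False


def featurize(
    structure: Structure,
    layout: DescriptorLayout,
    params: SymmetryFunctionParams = SymmetryFunctionParams(),
) -> np.ndarray:
    """Symmetry-function vectors for every atom; shape (n_atoms, layout.size).

    Vectorized equivalent of summing :func:`radial_term` / :func:`angular_term`
    per component (they agree to 1e-10; the naive forms are kept as the
    readable reference and for scalar use).
    """
    if not set(structure.elements) <= set(layout.element_order):
        raise LayoutError(
            f"structure elements {sorted(set(structure.elements))} exceed "
            f"layout element order {layout.element_order}"
        )
    n = structure.n_atoms
    d = structure.distance_matrix()
    _check_distances(structure, d)
    fc = cutoff(d, params.rc)
    elems = np.array(structure.elements)
    out = np.zeros((n, layout.size))

    # radial block
    gauss = np.exp(-params.eta * (d - params.rs) ** 2) * fc
    np.fill_diagonal(gauss, 0.0)
    for c, elem in enumerate(layout.radial_components):
        mask = elems == elem
        out[:, c] = gauss[:, mask].sum(axis=1)

    # angular block
    n_rad = len(layout.radial_components)
    sq = d**2
    prefactor = 2.0 ** (1.0 - params.zeta)
    for i in range(n):
        others = np.arange(n) != i
        idx = np.nonzero(others)[0]
        if idx.size < 2:
            continue
        vec = structure.coords[idx] - structure.coords[i]
        dist_i = d[i, idx]
        unit = vec / dist_i[:, None]
        cos_t = np.clip(unit @ unit.T, -1.0, 1.0)
        # pairwise term matrix over neighbor indices (a, b)
        expo = np.exp(
            -params.eta * (sq[i, idx][:, None] + sq[i, idx][None, :] + sq[np.ix_(idx, idx)])
        )
        fc_pair = fc[i, idx][:, None] * fc[i, idx][None, :] * fc[np.ix_(idx, idx)]
        term = (1.0 + params.lam * cos_t) ** params.zeta * expo * fc_pair
        e_nb = elems[idx]
        for c, (ej, ek) in enumerate(layout.angular_components):
            mj = e_nb == ej
            mk = e_nb == ek
            if ej == ek:
                sub = term[np.ix_(mj, mj)]
                val = np.triu(sub, k=1).sum()
            else:
                val = term[np.ix_(mj, mk)].sum()
            out[i, n_rad + c] = prefactor * val
    return out


def featurize_frames(
    structures,
    layout: DescriptorLayout,
    params: SymmetryFunctionParams = SymmetryFunctionParams(),
) -> np.ndarray:
    """Stack per-atom feature matrices over frames: (n_frames, n_atoms, p)."""
    return np.stack([featurize(s, layout, params) for s in structures])


# ---------------------------------------------------------------------------
# internal-coordinate descriptors


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in Å."""
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees, in [0, 180]."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("zero-length bond vector in angle")
    cos_t = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_t)))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180].

    The sign follows the right-hand convention about the b->c axis; the
    planar trans arrangement gives +180.
    """
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


@dataclass(frozen=True)
class InternalDescriptorDefinition:
    """Which distances/angles/dihedrals make up an internal-coordinate vector."""

    distance_pairs: tuple[tuple[int, int], ...] = ()
    angle_triples: tuple[tuple[int, int, int], ...] = ()
    dihedral_quads: tuple[tuple[int, int, int, int], ...] = ()

    @property
    def size(self) -> int:
        return (
            len(self.distance_pairs)
            + len(self.angle_triples)
            + len(self.dihedral_quads)
        )

    def component_names(self) -> list[str]:
        from .structure import ATOM_NAMES

        def nm(i: int) -> str:
            return ATOM_NAMES.get(i, str(i))

        return (
            [f"d_{nm(i)}_{nm(j)}" for i, j in self.distance_pairs]
            + [f"a_{nm(i)}_{nm(j)}_{nm(k)}" for i, j, k in self.angle_triples]
            + [
                f"t_{nm(i)}_{nm(j)}_{nm(k)}_{nm(l)}"
                for i, j, k, l in self.dihedral_quads
            ]
        )


def default_internal_definition() -> InternalDescriptorDefinition:
    """The 11 manually selected structural parameters of the heme-O2 model.

    Eight distances (Fe-N1, Fe-N2, Fe-N3, Fe-N4, Fe-N11, Fe-O12, Fe-O13,
    O12-O13), one angle (Fe-O12-O13) and two dihedrals (N2-Fe-N1-C10 and
    N1-Fe-N2-C5).
    """
    L = ATOM_LABELS
    return InternalDescriptorDefinition(
        distance_pairs=(
            (L["Fe"], L["N1"]),
            (L["Fe"], L["N2"]),
            (L["Fe"], L["N3"]),
            (L["Fe"], L["N4"]),
            (L["Fe"], L["N11"]),
            (L["Fe"], L["O12"]),
            (L["Fe"], L["O13"]),
            (L["O12"], L["O13"]),
        ),
        angle_triples=((L["Fe"], L["O12"], L["O13"]),),
        dihedral_quads=(
            (L["N2"], L["Fe"], L["N1"], L["C10"]),
            (L["N1"], L["Fe"], L["N2"], L["C5"]),
        ),
    )


def internal_descriptors(
    structure: Structure, definition: InternalDescriptorDefinition
) -> np.ndarray:
    """Internal-coordinate vector (distances Å, angles deg, dihedrals deg)."""
    c = structure.coords
    for tup in (
        definition.distance_pairs + definition.angle_triples + definition.dihedral_quads
    ):
        for i in tup:
            if not 0 <= i < structure.n_atoms:
                raise LayoutError(f"atom index {i} out of range")
    vals = [distance(c[i], c[j]) for i, j in definition.distance_pairs]
    vals += [angle(c[i], c[j], c[k]) for i, j, k in definition.angle_triples]
    vals += [dihedral(c[i], c[j], c[k], c[l]) for i, j, k, l in definition.dihedral_quads]
    return np.asarray(vals, dtype=float)


def internal_descriptors_frames(
    structures, definition: InternalDescriptorDefinition
) -> np.ndarray:
    """Stack internal-coordinate vectors over frames: (n_frames, size)."""
    return np.stack([internal_descriptors(s, definition) for s in structures])
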