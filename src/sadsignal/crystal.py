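"""Unit cells, symmetry operators, atom sites and unique-reflection enumeration.

Conventions used throughout the package:

* fractional coordinates, wrapped to ``[0, 1)``;
* the resolution variable is ``s = sin(theta)/lambda = 1/(2 d)`` in 1/Angstrom;
* Miller indices are integer triples, and of a Friedel pair ``h`` / ``-h`` the
  lexicographically greater triple is kept as the representative (so ``h > 0``
  is preferred, then ``k > 0``, then ``l > 0``);
* a reflection is *centric* iff some rotation of the space group maps ``h``
  to ``-h``; centric reflections carry no anomalous difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import InvalidCellError, UndefinedReflectionError

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "AtomSite",
    "UniqueReflections",
    "cell_volume",
    "d_spacing",
    "enumerate_unique_reflections",
    "site_weight",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angles must lie in (0, 180): {self}")
        if self.metric_tensor_determinant <= 0:
            raise InvalidCellError(f"degenerate cell (non-positive volume): {self}")

    @cached_property
    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (3x3, Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @cached_property
    def metric_tensor_determinant(self) -> float:
        return float(np.linalg.det(self.metric_tensor))

    @cached_property
    def volume(self) -> float:
        """Cell volume in Angstrom^3 (square root of det G)."""
        return float(np.sqrt(self.metric_tensor_determinant))

    @cached_property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (1/Angstrom^2)."""
        return np.linalg.inv(self.metric_tensor)

    @cached_property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix mapping fractional to Cartesian coordinates (Angstrom)."""
        return np.linalg.cholesky(self.metric_tensor).T

    def d_spacing(self, hkl) -> np.ndarray | float:
        """Resolution d (Angstrom) of one or many reflections."""
        h = np.asarray(hkl, dtype=float)
        scalar = h.ndim == 1
        h = np.atleast_2d(h)
        if np.any(np.all(h == 0, axis=1)):
            raise UndefinedReflectionError("d-spacing undefined for (0,0,0)")
        inv_d2 = np.einsum("ni,ij,nj->n", h, self.reciprocal_metric_tensor, h)
        d = 1.0 / np.sqrt(inv_d2)
        return float(d[0]) if scalar else d

    def s(self, hkl) -> np.ndarray | float:
        """sin(theta)/lambda = 1/(2 d) in 1/Angstrom."""
        d = self.d_spacing(hkl)
        return 1.0 / (2.0 * d)


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in Angstrom^3."""
    return cell.volume


def d_spacing(cell: UnitCell, hkl) -> np.ndarray | float:
    """Resolution of reflection(s) ``hkl`` in Angstrom."""
    return cell.d_spacing(hkl)


@dataclass(frozen=True)
class SymmetryOps:
    """Explicit list of symmetry operators (integer rotations + translations).

    Operators act on fractional coordinates as ``x' = R @ x + t``.  The list
    must contain the identity.  No space-group symbol parsing is done; common
    primitive settings are provided as constructors.
    """

    rotations: np.ndarray  # (n, 3, 3) int
    translations: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotations, dtype=int).reshape(-1, 3, 3)
        tra = np.asarray(self.translations, dtype=float).reshape(-1, 3) % 1.0
        if len(rot) != len(tra) or len(rot) == 0:
            raise ValueError("rotations and translations must be equal-length, nonempty")
        ident = np.any(
            [np.array_equal(r, np.eye(3, dtype=int)) and np.allclose(t, 0) for r, t in zip(rot, tra)]
        )
        if not ident:
            raise ValueError("identity operator missing")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "translations", tra)

    @property
    def n_sym(self) -> int:
        return len(self.rotations)

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls(np.eye(3, dtype=int)[None], np.zeros((1, 3)))

    @classmethod
    def p1bar(cls) -> "SymmetryOps":
        """Identity plus inversion (P-1): every reflection is centric."""
        return cls(
            np.stack([np.eye(3, dtype=int), -np.eye(3, dtype=int)]),
            np.zeros((2, 3)),
        )

    @classmethod
    def p21(cls) -> "SymmetryOps":
        """P2(1): twofold screw along b, operators (x,y,z) and (-x, y+1/2, -z)."""
        r2 = np.diag([-1, 1, -1])
        return cls(
            np.stack([np.eye(3, dtype=int), r2]),
            np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.0]]),
        )

    @classmethod
    def p2(cls) -> "SymmetryOps":
        """P2: twofold along b, operators (x,y,z) and (-x, y, -z)."""
        r2 = np.diag([-1, 1, -1])
        return cls(np.stack([np.eye(3, dtype=int), r2]), np.zeros((2, 3)))


@dataclass(frozen=True)
class AtomSite:
    """One atom site: element, fractional position, occupancy, isotropic B.

    ``site_weight`` is 1 on a general position and ``1/m`` on a special
    position fixed by ``m`` symmetry operators (a site on a twofold counts as
    half a site).
    """

    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 0.0
    site_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.b_iso < 0:
            raise ValueError(f"negative B factor: {self.b_iso}")
        if not 0 < self.occupancy <= 1:
            raise ValueError(f"occupancy outside (0, 1]: {self.occupancy}")
        object.__setattr__(self, "frac", tuple(float(x) % 1.0 for x in self.frac))


def site_weight(sym: SymmetryOps, position) -> float:
    """1 / (number of operators fixing ``position`` modulo lattice translations)."""
    x = np.asarray(position, dtype=float) % 1.0
    images = (np.einsum("nij,j->ni", sym.rotations, x) + sym.translations) % 1.0
    diff = (images - x + 0.5) % 1.0 - 0.5
    fixing = int(np.sum(np.all(np.abs(diff) < 1e-6, axis=1)))
    return 1.0 / max(fixing, 1)


@dataclass
class UniqueReflections:
    """One representative per symmetry orbit of reflections, Friedel mates merged.

    ``n_refl`` (the N_refl of the signal formulas) counts unique *acentric*
    entries only.
    """

    cell: UnitCell
    hkl: np.ndarray  # (n, 3) int
    d: np.ndarray  # (n,) Angstrom
    centric: np.ndarray  # (n,) bool
    sym: SymmetryOps = field(default_factory=SymmetryOps.p1)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def s(self) -> np.ndarray:
        return 1.0 / (2.0 * self.d)

    @property
    def n_refl(self) -> int:
        """Number of unique acentric entries."""
        return int(np.sum(~self.centric))

    def acentric(self) -> "UniqueReflections":
        m = ~self.centric
        return UniqueReflections(self.cell, self.hkl[m], self.d[m], self.centric[m], self.sym)

    def select(self, mask) -> "UniqueReflections":
        mask = np.asarray(mask)
        return UniqueReflections(self.cell, self.hkl[mask], self.d[mask], self.centric[mask], self.sym)

    def truncate(self, d_min: float) -> "UniqueReflections":
        return self.select(self.d >= d_min)


def _lex_encode(hkl: np.ndarray, m: int) -> np.ndarray:
    """Encode integer triples so that integer order == lexicographic order."""
    base = 2 * m + 1
    h = hkl.astype(np.int64)
    return (h[..., 0] + m) * base * base + (h[..., 1] + m) * base + (h[..., 2] + m)


def enumerate_unique_reflections(
    cell: UnitCell, sym: SymmetryOps, d_min: float
) -> UniqueReflections:
    """Enumerate unique reflections with ``d >= d_min``.

    Friedel mates count as a single entry holding both members; the stored
    representative of each orbit is its lexicographically greatest index
    triple.  The centric flag marks reflections whose index is rotated onto
    its negative by some symmetry operator.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    # conservative index bounds from the reciprocal cell axis lengths
    gstar = cell.reciprocal_metric_tensor
    hmax = np.floor(np.sqrt(np.diag(np.linalg.inv(gstar))) / d_min).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[~np.all(grid == 0, axis=1)]
    inv_d2 = np.einsum("ni,ij,nj->n", grid.astype(float), gstar, grid.astype(float))
    keep = inv_d2 <= (1.0 / d_min) ** 2
    hkl = grid[keep]
    m = int(np.max(np.abs(hkl)))
    # orbit under rotations (acting on row index vectors) plus Friedel inversion
    equivs = np.einsum("nj,rji->rni", hkl, sym.rotations)  # h' = h @ R
    orbit = np.concatenate([equivs, -equivs], axis=0)  # (2 n_ops, n, 3)
    enc = _lex_encode(orbit, m)
    rep_enc = enc.max(axis=0)
    is_rep = _lex_encode(hkl, m) == rep_enc
    centric = np.any(np.all(equivs == -hkl[None, :, :], axis=2), axis=0)
    hkl = hkl[is_rep]
    d = 1.0 / np.sqrt(inv_d2[keep][is_rep])
    order = np.argsort(_lex_encode(hkl, m))[::-1]
    return UniqueReflections(cell, hkl[order], d[order], centric[is_rep][order], sym)
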