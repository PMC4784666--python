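"""Direct-summation structure factors and Bijvoet-pair anomalous differences.

Structure-factor decomposition for a crystal with an anomalous substructure
(single anomalous wavelength):

* ``F_P`` — all ordinary (non- or weakly-anomalous) atoms;
* ``F_H`` — real scattering (f0 + f') of the substructure atoms;
* ``F_A`` — imaginary scattering (i f'') of the substructure atoms, a vector
  perpendicular to ``F_H`` with ``|F_A| / |F_H| = f'' / (f0 + f')`` when the
  substructure is a single element type.

The Bijvoet mates are ``F+ = |F_n + i A|`` and ``F- = |F_n - i A|`` where
``F_n`` is the full non-anomalous structure factor and ``A`` the complex
f''-weighted substructure sum.  The anomalous difference is
``delta_ano = F+ - F-``; to first order in ``F_A / F`` it equals
``-2 F_A sin(alpha)`` with ``alpha = phase(F_H) - phi_c`` and ``phi_c`` the
phase of the non-anomalous structure factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import AtomSite, SymmetryOps, UnitCell, UniqueReflections
from .errors import NoSubstructureError, UndefinedReflectionError
from .scattering import ScatteringModel

__all__ = [
    "CrystalModel",
    "IdealAnomalousData",
    "structure_factor",
    "bijvoet_pair_exact",
    "ideal_anomalous_differences",
    "approx_anomalous_difference",
]

_CHUNK = 128  # atoms per summation block, keeps phase matrices small


@dataclass
class CrystalModel:
    """Ground-truth crystal: cell, symmetry, atoms and scattering model."""

    cell: UnitCell
    sym: SymmetryOps
    ordinary_atoms: list[AtomSite]
    substructure_atoms: list[AtomSite]
    minor_sites: list[AtomSite] = field(default_factory=list)
    scattering: ScatteringModel = field(default_factory=ScatteringModel)

    @property
    def n_sites(self) -> float:
        """Unique substructure sites (sum of site weights)."""
        return float(sum(a.site_weight for a in self.substructure_atoms))

    @property
    def mean_substructure_b(self) -> float:
        return float(np.mean([a.b_iso for a in self.substructure_atoms]))

    def all_atoms(self) -> list[AtomSite]:
        return self.ordinary_atoms + self.substructure_atoms + self.minor_sites


@dataclass
class IdealAnomalousData:
    """Noise-free per-reflection anomalous quantities of a known model.

    ``delta_ano`` is the exact ``F+ - F-`` of a model whose only anomalous
    scatterers are the substructure atoms (minor sites keep their real
    scattering but contribute no f'').  ``phi_c`` is the phase of the full
    non-anomalous structure factor, ``alpha = phase(F_H) - phi_c``, and
    ``ratio_a = F_A / F_H`` equals ``f''/(f0 + f')`` for a single-element
    substructure.
    """

    reflections: UniqueReflections
    delta_ano: np.ndarray
    phi_c: np.ndarray
    alpha: np.ndarray
    f_a: np.ndarray
    f_h: np.ndarray

    @property
    def ratio_a(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.f_h > 0, self.f_a / self.f_h, np.nan)

    def acentric(self) -> "IdealAnomalousData":
        m = ~self.reflections.centric
        return IdealAnomalousData(
            self.reflections.select(m),
            self.delta_ano[m],
            self.phi_c[m],
            self.alpha[m],
            self.f_a[m],
            self.f_h[m],
        )


def _atom_sum(
    atoms: list[AtomSite],
    scattering: ScatteringModel,
    cell: UnitCell,
    sym: SymmetryOps,
    hkl: np.ndarray,
    s: np.ndarray,
    part: str,
) -> np.ndarray:
    """Direct summation over atoms and their symmetry copies.

    ``part`` selects the scattering weight: ``"real"`` uses ``f0(s) + f'``,
    ``"imag"`` uses the constant ``f''`` (without the factor i).
    """
    total = np.zeros(len(hkl), dtype=complex)
    if not atoms:
        return total
    # group atoms by (element, B, occ*weight) is overkill; chunk instead
    for start in range(0, len(atoms), _CHUNK):
        block = atoms[start : start + _CHUNK]
        x = np.array([a.frac for a in block])  # (m, 3)
        b = np.array([a.b_iso for a in block])
        w = np.array([a.occupancy * a.site_weight for a in block])
        if part == "real":
            f = np.stack([np.asarray(scattering.f_real(a.element, s)) for a in block], axis=1)
        else:
            f = np.broadcast_to(
                np.array([scattering.f_imag(a.element) for a in block]), (len(hkl), len(block))
            )
        att = np.exp(-np.multiply.outer(s**2, b))  # (n, m)
        weight = f * att * w  # (n, m)
        for rot, tra in zip(sym.rotations, sym.translations):
            xs = (x @ rot.T + tra) % 1.0
            total += np.einsum("nm,nm->n", weight, np.exp(2j * np.pi * (hkl @ xs.T)))
    return total


def _as_hkl_s(cell: UnitCell, hkl) -> tuple[np.ndarray, np.ndarray, bool]:
    h = np.asarray(hkl, dtype=int)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise UndefinedReflectionError("structure factor undefined for (0,0,0)")
    s = np.atleast_1d(np.asarray(cell.s(h), dtype=float))
    return h, s, scalar


def structure_factor(
    atoms: list[AtomSite],
    scattering: ScatteringModel,
    cell: UnitCell,
    sym: SymmetryOps,
    hkl,
    include_anomalous: bool = False,
) -> np.ndarray | complex:
    """Complex structure factor F(h) by direct summation over symmetry copies.

    ``F(h) = sum_j w_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h . x_j)`` with
    ``f_j = f0 + f' (+ i f'')``.
    """
    h, s, scalar = _as_hkl_s(cell, hkl)
    f = _atom_sum(atoms, scattering, cell, sym, h, s, "real")
    if include_anomalous:
        f = f + 1j * _atom_sum(atoms, scattering, cell, sym, h, s, "imag")
    return complex(f[0]) if scalar else f


def _model_sums(model: CrystalModel, hkl: np.ndarray, s: np.ndarray) -> dict[str, np.ndarray]:
    """All component sums needed for Bijvoet pairs and the ideal reference."""
    sc, cell, sym = model.scattering, model.cell, model.sym
    return {
        "F_P": _atom_sum(model.ordinary_atoms, sc, cell, sym, hkl, s, "real")
        + _atom_sum(model.minor_sites, sc, cell, sym, hkl, s, "real"),
        "F_H": _atom_sum(model.substructure_atoms, sc, cell, sym, hkl, s, "real"),
        "A_sub": _atom_sum(model.substructure_atoms, sc, cell, sym, hkl, s, "imag"),
        "A_minor": _atom_sum(model.minor_sites, sc, cell, sym, hkl, s, "imag")
        + _atom_sum(model.ordinary_atoms, sc, cell, sym, hkl, s, "imag"),
    }


def bijvoet_pair_exact(model: CrystalModel, hkl) -> tuple[np.ndarray, np.ndarray]:
    """Exact Bijvoet amplitudes (F+, F-) with all f'' contributions included.

    Uses ``F(h) = F_n + i A`` and ``F(-h) = conj(F_n - i A)``, so
    ``F+ = |F_n + i A|`` and ``F- = |F_n - i A|`` — no small-F_A
    approximation.
    """
    h, s, scalar = _as_hkl_s(model.cell, hkl)
    sums = _model_sums(model, h, s)
    f_n = sums["F_P"] + sums["F_H"]
    a = sums["A_sub"] + sums["A_minor"]
    fp = np.abs(f_n + 1j * a)
    fm = np.abs(f_n - 1j * a)
    return (float(fp[0]), float(fm[0])) if scalar else (fp, fm)


def ideal_anomalous_differences(
    model: CrystalModel,
    reflections: UniqueReflections,
    phase_convention: str = "full",
) -> IdealAnomalousData:
    """Exact noise-free anomalous differences of the substructure-only model.

    Minor sites and ordinary atoms contribute real scattering only; their
    (weak) f'' is excluded by definition.  ``phase_convention`` selects the
    reference phase phi_c: ``"full"`` uses phase(F_P + F_H) (default),
    ``"protein"`` uses phase(F_P) alone.
    """
    if not model.substructure_atoms:
        raise NoSubstructureError("model has no substructure atoms")
    hkl = reflections.hkl
    s = reflections.s
    sums = _model_sums(model, hkl, s)
    f_n = sums["F_P"] + sums["F_H"]
    a = sums["A_sub"]
    delta = np.abs(f_n + 1j * a) - np.abs(f_n - 1j * a)
    delta = np.where(reflections.centric, 0.0, delta)  # centric: exactly none
    phi_c = np.angle(f_n if phase_convention == "full" else sums["F_P"])
    alpha = np.angle(sums["F_H"]) - phi_c
    alpha = (alpha + np.pi) % (2 * np.pi) - np.pi
    return IdealAnomalousData(
        reflections=reflections,
        delta_ano=delta,
        phi_c=phi_c,
        alpha=alpha,
        f_a=np.abs(a),
        f_h=np.abs(sums["F_H"]),
    )


def approx_anomalous_difference(f_a, alpha) -> np.ndarray | float:
    """First-order anomalous difference ``-2 F_A sin(alpha)``.

    ``alpha = phase(F_H) - phi_c``; valid when F_A is small against the total
    structure factor.  Antisymmetric under ``alpha -> -alpha``.
    """
    f_a = np.asarray(f_a, dtype=float)
    if np.any(f_a < 0):
        raise ValueError("F_A amplitudes must be non-negative")
    val = -2.0 * f_a * np.sin(alpha)
    return float(val) if np.ndim(val) == 0 else val
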