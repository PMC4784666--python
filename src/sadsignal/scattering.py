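"""Atomic scattering-factor models.

The form factor of an anomalously scattering atom is taken as
``f = f0(s) + f' + i f''`` with the resolution-dependent real part ``f0``
evaluated from a sum-of-Gaussians parameterization
``f0(s) = sum_i a_i exp(-b_i s^2) + c`` (s = sin(theta)/lambda), and the
anomalous corrections ``f'`` and ``f''`` constant with resolution.

For substructure atoms with isotropic displacement ``B`` the effective
imaginary scattering at reflection resolution ``s`` is the B-attenuated
factor ``f_hB = f'' exp(-B s^2)``; the dimensionless spread of these values
over a reflection set is summarized by their second moment
``f_B = rms(f_hB) / mean(f_hB) >= 1``, which is 1 exactly when all values
are equal (e.g. B = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingElementError

__all__ = [
    "GaussianFormFactor",
    "ScatteringModel",
    "f0_at_s",
    "f_hB",
    "second_moment_fB",
    "load_scattering_table",
]


@dataclass(frozen=True)
class GaussianFormFactor:
    """Sum-of-Gaussians form-factor curve f0(s) = sum a_i exp(-b_i s^2) + c."""

    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float = 0.0

    def __call__(self, s) -> np.ndarray | float:
        s2 = np.square(np.asarray(s, dtype=float))
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        val = np.sum(a * np.exp(-np.multiply.outer(s2, b)), axis=-1) + self.c
        return float(val) if np.isscalar(s) or np.ndim(s) == 0 else val

    @classmethod
    def single(cls, z: float, b: float = 10.0) -> "GaussianFormFactor":
        """One-Gaussian fallback for synthetic elements: f0(s) = Z exp(-b s^2)."""
        return cls((float(z),), (float(b),), 0.0)


def _it92(element: str) -> GaussianFormFactor:
    """International Tables 4-Gaussian coefficients via gemmi."""
    import gemmi

    el = gemmi.Element(element.capitalize())
    if el.atomic_number == 0:
        raise MissingElementError(f"unknown element {element!r}")
    it = el.it92
    if it is None:
        raise MissingElementError(f"no form-factor coefficients for {element!r}")
    return GaussianFormFactor(tuple(it.a), tuple(it.b), it.c)


@dataclass
class ScatteringModel:
    """Per-element form factors plus constant anomalous corrections f', f''.

    Elements not registered explicitly are looked up in the International
    Tables coefficients (with f' = f'' = 0) on first use.
    """

    form_factors: dict[str, GaussianFormFactor] = field(default_factory=dict)
    fprime: dict[str, float] = field(default_factory=dict)
    fdprime: dict[str, float] = field(default_factory=dict)

    def _key(self, element: str) -> str:
        return element.strip().upper()

    def register(
        self,
        element: str,
        form_factor: GaussianFormFactor | None = None,
        fprime: float = 0.0,
        fdprime: float = 0.0,
    ) -> "ScatteringModel":
        if fdprime < 0:
            raise InvalidParameterError("f'' must be non-negative")
        key = self._key(element)
        self.form_factors[key] = form_factor if form_factor is not None else _it92(element)
        self.fprime[key] = float(fprime)
        self.fdprime[key] = float(fdprime)
        return self

    def form_factor(self, element: str) -> GaussianFormFactor:
        key = self._key(element)
        if key not in self.form_factors:
            self.form_factors[key] = _it92(element)
        return self.form_factors[key]

    def f0(self, element: str, s) -> np.ndarray | float:
        return self.form_factor(element)(s)

    def f_real(self, element: str, s) -> np.ndarray | float:
        """Real part of the form factor, f0(s) + f'."""
        return self.f0(element, s) + self.fprime.get(self._key(element), 0.0)

    def f_imag(self, element: str) -> float:
        """Imaginary (anomalous) part f'', constant with resolution."""
        return self.fdprime.get(self._key(element), 0.0)


def f0_at_s(model: ScatteringModel, element: str, s) -> np.ndarray | float:
    """Resolution-dependent form factor f0 at s = sin(theta)/lambda."""
    return model.f0(element, s)


def f_hB(fdprime: float, b_iso: float, s) -> np.ndarray | float:
    """B-attenuated anomalous scattering factor f_hB = f'' exp(-B s^2)."""
    if b_iso < 0:
        raise InvalidParameterError(f"negative B factor: {b_iso}")
    if fdprime < 0:
        raise InvalidParameterError(f"negative f'': {fdprime}")
    val = fdprime * np.exp(-b_iso * np.square(np.asarray(s, dtype=float)))
    return float(val) if np.ndim(s) == 0 else val


def second_moment_fB(values) -> float:
    """Second moment f_B = rms(values) / mean(values) of scattering factors.

    Equals 1 for constant input (B = 0) and grows with the spread of the
    attenuated factors across the reflection set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("empty scattering-factor list")
    if np.any(v <= 0):
        raise InvalidParameterError("scattering factors must be positive")
    # rms/mean >= 1 by Cauchy-Schwarz; guard against rounding below 1
    return max(1.0, float(np.sqrt(np.mean(v**2)) / np.mean(v)))


def load_scattering_table(path) -> ScatteringModel:
    """Load a scattering model from a CSV table.

    Columns: ``element, a1..a4, b1..b4, c, fprime, fdprime`` (any number of
    a/b pairs may be given; blank entries are skipped).
    """
    df = pd.read_csv(path)
    if "element" not in df.columns:
        raise InvalidParameterError("scattering table needs an 'element' column")
    model = ScatteringModel()
    a_cols = sorted(c for c in df.columns if c.startswith("a") and c[1:].isdigit())
    b_cols = sorted(c for c in df.columns if c.startswith("b") and c[1:].isdigit())
    for _, row in df.iterrows():
        a = tuple(float(row[c]) for c in a_cols if pd.notna(row[c]))
        b = tuple(float(row[c]) for c in b_cols if pd.notna(row[c]))
        ff = GaussianFormFactor(a, b, float(row.get("c", 0.0) or 0.0))
        model.register(
            str(row["element"]),
            ff,
            float(row.get("fprime", 0.0) or 0.0),
            float(row.get("fdprime", 0.0) or 0.0),
        )
    return model
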