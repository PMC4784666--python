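"""Anomalous signal, useful anomalous correlation, and the model-phased
anomalous difference Fourier.

Core quantities
---------------
* ``CC_ano`` — Pearson correlation between observed anomalous differences
  ``F+ - F-`` and the ideal differences of a substructure-only-anomalous
  model; the principal accuracy metric of a SAD data set.
* ``S_ano`` — mean value of the model-phased anomalous difference Fourier at
  the substructure coordinates, normalized to the map rms; the principal
  information metric.
* The closed-form link ``S_ano = CC_ano sqrt(N_refl / n_sites) / f_B`` where
  ``N_refl`` counts unique acentric reflections, ``n_sites`` unique
  substructure sites, and ``f_B`` is the second moment of the B-attenuated
  anomalous scattering factors.

The anomalous difference Fourier uses coefficients
``delta_ano,h exp[i(phi_c,h - pi/2)]`` on the stored Friedel representatives
with Hermitian mates implied, synthesized as
``rho(x) = (1/V) sum_h c_h exp(-2 pi i h.x)`` over the full sphere; maps are
therefore real.  Map values at substructure sites are evaluated by direct
summation at the exact coordinates (no grid, no interpolation, no peak
search), and the map rms comes from the Parseval identity
``<rho^2> = sum_h |c_h|^2 / V^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .crystal import UnitCell, UniqueReflections
from .errors import EmptyDataError, InvalidParameterError, UndefinedMetricError
from .scattering import f_hB, second_moment_fB
from .structure_factors import CrystalModel, ideal_anomalous_differences

logger = logging.getLogger(__name__)

__all__ = [
    "MapSample",
    "SignalReport",
    "observed_anomalous_differences",
    "useful_anomalous_correlation",
    "error_model_stats",
    "adf_at_points",
    "adf_grid",
    "map_rms",
    "measured_anomalous_signal",
    "predicted_anomalous_signal",
    "ideal_anomalous_signal",
    "max_anomalous_signal",
    "sites_scaling_signal",
    "substructure_f_b",
    "estimate_signal",
    "truncation_scan",
]


# ---------------------------------------------------------------------------
# observed differences and correlations


def observed_anomalous_differences(reflections: pd.DataFrame) -> pd.DataFrame:
    """Acentric complete Bijvoet pairs with ``delta = Fplus - Fminus``.

    Centric entries and pairs missing either member are excluded; exclusion
    counts are logged.
    """
    df = reflections.copy()
    n_in = len(df)
    complete = df["Fplus"].notna() & df["Fminus"].notna()
    acentric = ~df["centric"].astype(bool)
    out = df[complete & acentric].copy()
    logger.info(
        "observed differences: %d in, %d centric excluded, %d incomplete excluded, %d kept",
        n_in,
        int((~acentric).sum()),
        int((~complete & acentric).sum()),
        len(out),
    )
    if out.empty:
        raise EmptyDataError("no complete acentric Bijvoet pairs")
    out["delta"] = out["Fplus"] - out["Fminus"]
    return out


def useful_anomalous_correlation(delta_obs, delta_ideal) -> float:
    """CC_ano: Pearson correlation of observed vs ideal anomalous differences."""
    x = np.asarray(delta_obs, dtype=float)
    y = np.asarray(delta_ideal, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and ideal difference lists must be matched")
    if x.size < 3:
        raise UndefinedMetricError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def error_model_stats(var_other: float, var_eps: float, var_useful: float) -> tuple[float, float]:
    """Normalized variance ``E^2`` and the expected ``CC_ano = 1/sqrt(1+E^2)``."""
    if min(var_other, var_eps) < 0 or var_useful < 0:
        raise InvalidParameterError("variances must be non-negative")
    if var_useful == 0:
        raise UndefinedMetricError("E^2 undefined for zero useful variance")
    e2 = (var_other + var_eps) / var_useful
    return float(e2), float(1.0 / np.sqrt(1.0 + e2))


# ---------------------------------------------------------------------------
# anomalous difference Fourier


def _coefficients(delta, phi_c) -> np.ndarray:
    return np.asarray(delta, dtype=float) * np.exp(1j * (np.asarray(phi_c) - np.pi / 2.0))


def adf_at_points(delta, phi_c, hkl, cell: UnitCell, positions) -> np.ndarray:
    """Anomalous difference Fourier evaluated exactly at fractional positions.

    The sum runs over the stored reflections and their implied Friedel mates
    (conjugate coefficients), so the synthesized density is real.
    """
    delta = np.asarray(delta, dtype=float)
    hkl = np.asarray(hkl)
    if len(delta) != len(hkl) or len(delta) != len(np.asarray(phi_c)):
        raise ValueError("delta, phi_c and hkl must be aligned")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    coef = _coefficients(delta, phi_c)
    phases = np.exp(-2j * np.pi * (hkl @ pos.T))  # (n_refl, n_pos)
    rho = (2.0 / cell.volume) * np.real(coef @ phases)
    return rho


def map_rms(delta, cell: UnitCell) -> float:
    """Map rms via Parseval: ``sqrt(2 sum delta^2) / V`` (full-sphere sum)."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise EmptyDataError("no coefficients")
    return float(np.sqrt(2.0 * np.sum(delta**2)) / cell.volume)


def adf_grid(delta, phi_c, hkl, cell: UnitCell, n: int = 96) -> np.ndarray:
    """FFT synthesis of the anomalous difference Fourier on an n^3 grid.

    A test oracle / visualization aid; site evaluation in the metrics always
    uses the exact direct summation.
    """
    hkl = np.asarray(hkl, dtype=int)
    if np.any(np.abs(hkl) >= n // 2):
        raise InvalidParameterError("grid too coarse for the index range")
    coef = _coefficients(delta, phi_c)
    grid = np.zeros((n, n, n), dtype=complex)
    idx = hkl % n
    np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), coef)
    mates = (-hkl) % n
    np.add.at(grid, (mates[:, 0], mates[:, 1], mates[:, 2]), np.conj(coef))
    rho = np.fft.fftn(grid) / cell.volume
    return np.real(rho)


@dataclass
class MapSample:
    """ADF values at substructure sites plus the map rms."""

    site_values: np.ndarray
    rms: float

    @property
    def s_ano(self) -> float:
        if self.rms == 0:
            raise UndefinedMetricError("anomalous signal undefined for a zero map")
        return float(np.mean(self.site_values) / self.rms)


def measured_anomalous_signal(
    delta, phi_c, hkl, cell: UnitCell, site_positions
) -> MapSample:
    """Measured S_ano: mean ADF value at the site coordinates over the map rms."""
    sites = np.atleast_2d(np.asarray(site_positions, dtype=float))
    if sites.size == 0:
        raise InvalidParameterError("need at least one substructure site")
    values = adf_at_points(delta, phi_c, hkl, cell, sites)
    return MapSample(site_values=values, rms=map_rms(delta, cell))


# ---------------------------------------------------------------------------
# closed-form signal predictions


def _check_signal_args(n_refl: float, n_sites: float, f_b: float) -> None:
    if n_refl < 1:
        raise InvalidParameterError("need at least one reflection")
    if n_sites <= 0:
        raise InvalidParameterError("n_sites must be positive")
    if f_b < 1:
        raise InvalidParameterError("f_B is a second moment and cannot be < 1")


def predicted_anomalous_signal(cc_ano: float, n_refl: float, n_sites: float, f_b: float) -> float:
    """Expected signal ``S_ano = CC_ano sqrt(N_refl / n_sites) / f_B``."""
    _check_signal_args(n_refl, n_sites, f_b)
    if not -1.0 <= cc_ano <= 1.0:
        raise InvalidParameterError("CC_ano must lie in [-1, 1]")
    return cc_ano * float(np.sqrt(n_refl / n_sites)) / f_b


def ideal_anomalous_signal(n_refl: float, n_sites: float, f_b: float) -> float:
    """Noise-free limit ``sqrt(N_refl / n_sites) / f_B`` (CC_ano = 1)."""
    return predicted_anomalous_signal(1.0, n_refl, n_sites, f_b)


def max_anomalous_signal(n_refl: float) -> float:
    """Upper bound ``sqrt(N_refl)``: single site, B = 0, perfect data."""
    _check_signal_args(n_refl, 1.0, 1.0)
    return float(np.sqrt(n_refl))


def sites_scaling_signal(n_refl: float, n_sites: float, e2: float, f_b: float) -> float:
    """Signal with the error budget per site made explicit.

    ``S_ano = (1/f_B) sqrt(N_refl / (n_sites + e^2))`` where ``e^2`` is the
    total mean-square error relative to the mean-square useful difference of
    a single site, so ``E^2 = e^2 / n_sites``.
    """
    _check_signal_args(n_refl, n_sites, f_b)
    if e2 < 0:
        raise InvalidParameterError("e^2 must be non-negative")
    return float(np.sqrt(n_refl / (n_sites + e2))) / f_b


def substructure_f_b(model: CrystalModel, reflections: UniqueReflections) -> float:
    """Second moment f_B of the B-attenuated f'' over unique acentric entries.

    Uses the mean substructure B (the convention when sites have unequal B)
    and the substructure element's f''.
    """
    acentric = reflections.acentric()
    fdp = model.scattering.f_imag(model.substructure_atoms[0].element)
    values = f_hB(fdp, model.mean_substructure_b, acentric.s)
    return second_moment_fB(values)


# ---------------------------------------------------------------------------
# headline report


@dataclass
class SignalReport:
    """Everything the signal framework computes for one data set."""

    cc_ano: float
    e2: float
    f_b: float
    n_refl: int
    n_sites: float
    s_ano_pred: float
    s_ano_ideal: float
    s_ano_max: float
    s_ano_measured: float | None = None
    solve_probability: float | None = None
    n_excluded_centric: int = 0
    mean_substructure_b: float = 0.0
    d_min: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_signal(
    reflections: pd.DataFrame,
    model: CrystalModel,
    calibration=None,
    phase_convention: str = "full",
) -> SignalReport:
    """Full signal analysis of a merged SAD data set against a known model.

    Computes ideal anomalous differences from the model, correlates them with
    the observations (CC_ano), evaluates the model-phased anomalous
    difference Fourier at the substructure coordinates (measured S_ano), and
    reports the closed-form predictions alongside.
    """
    obs = observed_anomalous_differences(reflections)
    cell, sym = model.cell, model.sym
    hkl = obs[["h", "k", "l"]].to_numpy(dtype=int)
    refl = UniqueReflections(
        cell=cell,
        hkl=hkl,
        d=cell.d_spacing(hkl),
        centric=np.zeros(len(obs), dtype=bool),
        sym=sym,
    )
    ideal = ideal_anomalous_differences(model, refl, phase_convention)
    delta_obs = obs["delta"].to_numpy()
    cc = useful_anomalous_correlation(delta_obs, ideal.delta_ano)
    ms_ideal = float(np.mean(ideal.delta_ano**2))
    e2 = float(np.mean((delta_obs - ideal.delta_ano) ** 2) / ms_ideal) if ms_ideal else float("inf")
    f_b = substructure_f_b(model, refl)
    n_refl = len(obs)
    n_sites = model.n_sites
    sites = np.array([a.frac for a in model.substructure_atoms])
    sample = measured_anomalous_signal(delta_obs, ideal.phi_c, hkl, cell, sites)
    s_pred = predicted_anomalous_signal(cc, n_refl, n_sites, f_b)
    report = SignalReport(
        cc_ano=cc,
        e2=e2,
        f_b=f_b,
        n_refl=n_refl,
        n_sites=n_sites,
        s_ano_pred=s_pred,
        s_ano_ideal=ideal_anomalous_signal(n_refl, n_sites, f_b),
        s_ano_max=max_anomalous_signal(n_refl),
        s_ano_measured=sample.s_ano,
        n_excluded_centric=int(reflections["centric"].astype(bool).sum()),
        mean_substructure_b=model.mean_substructure_b,
        d_min=float(obs["d"].min()),
    )
    if calibration is not None:
        from .solvability import solve_probability

        report.solve_probability = solve_probability(sample.s_ano, calibration)
    return report


def truncation_scan(
    reflections: pd.DataFrame,
    model: CrystalModel,
    d_min_list,
    calibration=None,
) -> pd.DataFrame:
    """Recompute all overall metrics with data truncated at each resolution cutoff.

    Every row reports the *overall* values for reflections with ``d >= d_min``
    (not shell values): adding a high-resolution shell changes N_refl, CC_ano
    and f_B together, and the net effect on S_ano can go either way.
    """
    rows = []
    for d_min in sorted(d_min_list, reverse=True):
        subset = reflections[reflections["d"] >= d_min]
        if subset.empty:
            raise EmptyDataError(f"no reflections at d >= {d_min}")
        rep = estimate_signal(subset, model, calibration)
        rows.append(
            {
                "d_min": d_min,
                "n_refl": rep.n_refl,
                "cc_ano": rep.cc_ano,
                "f_b": rep.f_b,
                "s_ano_pred": rep.s_ano_pred,
                "s_ano_measured": rep.s_ano_measured,
            }
        )
    return pd.DataFrame(rows)
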