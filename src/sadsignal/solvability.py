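"""Mapping anomalous signal to a probability of solving the substructure.

Empirically, substructure determination on real SAD data sets succeeds for
about half the data sets at an anomalous signal near 9, rarely below a
signal of about 7, and for most data sets above about 10-15.  The default
calibration encodes those anchors as a logistic curve

    P(S) = 1 / (1 + exp(-(S - s50) / width))

with midpoint ``s50 = 9`` and ``width = 1.5`` (so P(7) ~ 0.21 and
P(13) ~ 0.93).  The logistic form and the width are an interpretation of the
published bands, not a fit; both are configuration and can be recalibrated
from a user's own success/failure statistics.

A substructure counts as *solved* when at least ``site_fraction`` of the true
sites are matched within ``distance_cutoff`` Angstrom (allowing symmetry
equivalents) — the criterion under which the anchors were established.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from .errors import InvalidParameterError

__all__ = ["SolvabilityCalibration", "solve_probability"]


@dataclass(frozen=True)
class SolvabilityCalibration:
    """Logistic signal-to-solvability curve plus the solved-site criterion."""

    s50: float = 9.0  # anomalous signal at 50% success
    width: float = 1.5  # logistic scale parameter
    site_fraction: float = 0.5  # fraction of sites found to call it solved
    distance_cutoff: float = 3.0  # A, site-matching tolerance

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("width must be positive")
        if not 0 < self.site_fraction <= 1:
            raise InvalidParameterError("site_fraction must lie in (0, 1]")
        if self.distance_cutoff <= 0:
            raise InvalidParameterError("distance_cutoff must be positive")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SolvabilityCalibration":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def solve_probability(s_ano, calibration: SolvabilityCalibration | None = None):
    """Probability that the anomalous substructure can be solved at signal ``s_ano``.

    Strictly increasing in ``s_ano``; exactly 0.5 at the calibration midpoint.
    """
    calib = calibration or SolvabilityCalibration()
    s = np.asarray(s_ano, dtype=float)
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError("anomalous signal must be finite")
    p = expit((s - calib.s50) / calib.width)
    return float(p) if np.ndim(s_ano) == 0 else p
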