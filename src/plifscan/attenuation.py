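"""Beer-Lambert attenuation of excitation and emitted fluorescence.

Both the exciting laser light (path l1 through the aerosol to the probed
point) and the emitted fluorescence (path l2 to the camera) are attenuated by
the aerosol itself.  The detected-to-ideal fluorescence ratio is

    Sd / S = 10 ** (-(A_ex + A_em) / 2)

where each absorbance is the extinction coefficient times the path integral
of local concentration,

    A = eps * integral_0^L C(l) dl .

Because A is linear in a uniform concentration, an attenuation rate measured
(or quoted) at one concentration fixes the rate at any other concentration on
the same path - the basis of the :func:`scale_attenuation` anchor arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "PathConcentration",
    "AttenuationResult",
    "absorbance",
    "detected_ratio",
    "scale_attenuation",
    "attenuation_vs_distance",
    "average_concentration",
]

#: default fluorescein extinction coefficients per (mg/L)*mm, order-of-magnitude
#: literature-style values for 450 nm excitation and the 500-600 nm band; the
#: anchored-scaling API should be preferred whenever a measured rate is known.
DEFAULT_EPS_EX = 8.0e-5
DEFAULT_EPS_EM = 4.0e-5


@dataclass(frozen=True)
class OpticalProperties:
    """Extinction coefficients, per (mg/L)*mm."""

    eps_ex: float = DEFAULT_EPS_EX
    eps_em: float = DEFAULT_EPS_EM

    def __post_init__(self) -> None:
        if self.eps_ex < 0 or self.eps_em < 0:
            raise ValueError("extinction coefficients must be >= 0")

    @classmethod
    def from_attenuation_anchor(
        cls,
        attenuation_percent: float,
        concentration_mg_l: float,
        path_ex_mm: float,
        path_em_mm: float,
    ) -> "OpticalProperties":
        """Solve for a common extinction coefficient reproducing a known rate.

        Splits the back-solved total absorbance evenly per unit path between
        excitation and emission (eps_ex = eps_em).
        """
        if not 0 < attenuation_percent < 100:
            raise ValueError("attenuation_percent must lie in (0, 100)")
        a_total = -2.0 * np.log10(1.0 - attenuation_percent / 100.0)
        eps = a_total / (concentration_mg_l * (path_ex_mm + path_em_mm))
        return cls(eps_ex=eps, eps_em=eps)


@dataclass
class PathConcentration:
    """Concentration profile along an optical path.

    ``profile`` is either a callable C(l) in mg/L for l in mm, or a sampled
    (positions, concentrations) pair covering [0, path_length].
    """

    profile: Callable[[np.ndarray], np.ndarray] | tuple[Sequence[float], Sequence[float]]
    path_length_mm: float

    def __post_init__(self) -> None:
        if self.path_length_mm <= 0:
            raise ValueError("path_length_mm must be > 0")

    def sample(self, n_nodes: int = 101) -> tuple[np.ndarray, np.ndarray]:
        if callable(self.profile):
            l = np.linspace(0.0, self.path_length_mm, max(n_nodes, 101))
            c = np.asarray(self.profile(l), dtype=float)
        else:
            l = np.asarray(self.profile[0], dtype=float)
            c = np.asarray(self.profile[1], dtype=float)
            if l.shape != c.shape or l.ndim != 1 or l.size < 2:
                raise ValueError("sampled profile needs matching 1D position/value arrays")
        if np.any(c < 0):
            raise ValueError("concentration samples must be >= 0")
        return l, c

    @classmethod
    def uniform(cls, concentration_mg_l: float, path_length_mm: float) -> "PathConcentration":
        return cls(profile=lambda l: np.full_like(np.asarray(l, float), concentration_mg_l),
                   path_length_mm=path_length_mm)


@dataclass(frozen=True)
class AttenuationResult:
    A_ex: float
    A_em: float

    @property
    def ratio(self) -> float:
        return detected_ratio(self.A_ex, self.A_em)

    @property
    def attenuation_percent(self) -> float:
        return 100.0 * (1.0 - self.ratio)


def absorbance(eps: float, path: PathConcentration, n_nodes: int = 101) -> float:
    """A = eps * integral of C(l) dl, by composite trapezoidal quadrature."""
    if eps < 0:
        raise ValueError("extinction coefficient must be >= 0")
    l, c = path.sample(n_nodes)
    return float(eps * np.trapezoid(c, l))


def detected_ratio(a_ex: float, a_em: float) -> float:
    """Detected-to-ideal fluorescence ratio 10**(-(A_ex + A_em)/2)."""
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be >= 0")
    return float(10.0 ** (-(a_ex + a_em) / 2.0))


def scale_attenuation(anchor_percent: float, anchor_conc: float, target_conc: float) -> float:
    """Attenuation rate at ``target_conc`` given a measured rate at ``anchor_conc``.

    Back-solves the total absorbance A = -2 log10(1 - anchor/100), scales it
    linearly with concentration (Beer-Lambert absorbance is linear in a
    uniform concentration), and converts back to a percentage.
    """
    if not 0 < anchor_percent < 100:
        raise ValueError("anchor_percent must lie in (0, 100)")
    if anchor_conc <= 0 or target_conc <= 0:
        raise ValueError("concentrations must be > 0")
    a_total = -2.0 * np.log10(1.0 - anchor_percent / 100.0)
    a_scaled = a_total * target_conc / anchor_conc
    return float(100.0 * (1.0 - 10.0 ** (-a_scaled / 2.0)))


def attenuation_vs_distance(
    optics: OpticalProperties,
    uniform_conc: float,
    distances_mm: Sequence[float],
) -> np.ndarray:
    """Detected ratio as a function of detection distance at uniform concentration.

    Excitation and emission path lengths are both set to the quoted distance;
    the curve is log-linear (log10 ratio proportional to distance).
    """
    d = np.asarray(distances_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be non-decreasing")
    if uniform_conc < 0:
        raise ValueError("concentration must be >= 0")
    a_total = (optics.eps_ex + optics.eps_em) * uniform_conc * d
    return 10.0 ** (-a_total / 2.0)


def average_concentration(
    atomization_rate_ml_s: float,
    duration_s: float,
    solution_conc_g_l: float,
    chamber_volume_l: float,
) -> float:
    """Chamber-average aerosol concentration in mg/L.

    Dispensed fluorophore mass (rate x time x solution concentration) divided
    by the chamber volume:  (mL/s * s * g/L) -> mg dispensed over L of chamber.
    """
    if chamber_volume_l <= 0:
        raise ValueError("chamber_volume_l must be > 0")
    if atomization_rate_ml_s < 0 or duration_s < 0 or solution_conc_g_l < 0:
        raise ValueError("rate, duration and solution concentration must be >= 0")
    mass_mg = atomization_rate_ml_s * duration_s * solution_conc_g_l  # mL*g/L = mg
    return mass_mg / chamber_volume_l
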