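"""Optical model shared by the synthetic forward model and the MBLL inversion.

The modified Beer-Lambert law (MBLL) relates the change in optical density at
wavelength ``lambda`` to the changes in oxy- and deoxy-hemoglobin concentration::

    dOD(lambda, t) = log10(I0(lambda) / I(lambda, t))
                   = (eps_HbO2(lambda) * dHbO2(t) + eps_Hb(lambda) * dHb(t)) * d * DPF(lambda)

With two wavelengths this is a 2x2 linear system per sample; inverting it
recovers (dHbO2, dHb) from the measured intensities.

Units: extinction coefficients in cm^-1 per micromolar (uM), source-detector
separation ``d`` in cm, concentrations in uM, DPF unitless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Molar extinction coefficients, cm^-1 M^-1, from the standard compiled
# hemoglobin spectra. Keyed by wavelength in nm; columns (HbO2, Hb).
EXTINCTION_PER_M = {
    730.0: (390.0, 1102.2),
    850.0: (1058.0, 691.32),
}


def dpf_general(wavelength_nm: float, age_years: float) -> float:
    """Age- and wavelength-adjusted differential pathlength factor.

    General DPF equation for the adult head:
    ``DPF = 223.3 + 0.05624*A^0.8493 - 5.723e-7*l^3 + 0.001245*l^2 - 0.9025*l``
    with age ``A`` in years and wavelength ``l`` in nm.
    """
    a, l = float(age_years), float(wavelength_nm)
    return 223.3 + 0.05624 * a**0.8493 - 5.723e-7 * l**3 + 0.001245 * l**2 - 0.9025 * l


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 extinction matrix in cm^-1 uM^-1; rows wavelengths, cols (HbO2, Hb)."""
    rows = []
    for wl in wavelengths:
        if wl not in EXTINCTION_PER_M:
            raise ValueError(f"no tabulated extinction coefficients for {wl} nm")
        rows.append(EXTINCTION_PER_M[wl])
    return np.asarray(rows, dtype=float) * 1e-6  # per M -> per uM


@dataclass
class OpticalParams:
    """Conversion parameters of the two-wavelength continuous-wave system.

    Parameters
    ----------
    wavelengths : pair of nm, default (730, 850).
    epsilon : 2x2 extinction matrix [cm^-1 uM^-1], rows = wavelengths,
        columns = (HbO2, Hb). Defaults to the tabulated values.
    d : source-detector separation in cm (2.5 for this sensor pad).
    dpf : per-wavelength differential pathlength factor; by default the
        general age/wavelength formula evaluated at ``age``.
    i0 : per-wavelength reference (baseline) intensity in detector units.
        When ``None``, converters estimate it from an initial rest window.
    """

    wavelengths: tuple[float, float] = (730.0, 850.0)
    epsilon: np.ndarray | None = None
    d: float = 2.5
    dpf: tuple[float, float] | None = None
    i0: tuple[float, float] | None = None
    age: float = 76.0

    def __post_init__(self) -> None:
        if self.epsilon is None:
            self.epsilon = extinction_matrix(self.wavelengths)
        else:
            self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (2, 2):
            raise ValueError("epsilon must be a 2x2 matrix")
        if not np.isfinite(np.linalg.cond(self.epsilon)) or np.linalg.cond(self.epsilon) > 1e12:
            raise ValueError("extinction matrix is singular or near-singular")
        if self.d <= 0:
            raise ValueError("source-detector separation must be positive")
        if self.dpf is None:
            self.dpf = tuple(dpf_general(wl, self.age) for wl in self.wavelengths)
        if any(v <= 0 for v in self.dpf):
            raise ValueError("DPF values must be positive")

    @property
    def pathlength(self) -> np.ndarray:
        """Effective optical path length per wavelength, cm."""
        return self.d * np.asarray(self.dpf, dtype=float)
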