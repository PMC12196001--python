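"""Modified Beer-Lambert conversion between optical density and haemoglobin.

For a source-detector channel measured at two wavelengths, the change in
optical density at wavelength lambda is modelled as

    dOD(lambda) = [ eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR ]
                  * d * DPF(lambda)

with concentrations in micromolar (uM), source-detector distance ``d`` in
cm, molar extinction coefficients ``eps`` in 1/(uM * cm) and the
dimensionless differential pathlength factor DPF.  Stacking the two
wavelengths gives a 2x2 linear system per sample; the forward map (used by
the simulator) and its inverse (used by preprocessing) share the same
geometry so that the conversion round-trips exactly.

The default extinction coefficients at 760/850 nm come from the standard
haemoglobin compilation (Gratzer/Prahl values, rescaled to uM^-1 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

WAVELENGTHS_NM = (760, 850)

#: rows: wavelength (760, 850 nm); columns: (HbO, HbR); units: 1/(uM cm).
DEFAULT_EXTINCTION = (
    (5.860e-4, 1.54852e-3),
    (1.058e-3, 6.9132e-4),
)

DEFAULT_DPF = (6.0, 6.0)
DEFAULT_DISTANCE_CM = 3.0


@dataclass(frozen=True)
class ChannelGeometry:
    """Optical constants of one channel.

    Attributes
    ----------
    distance_cm
        Source-detector separation (cm).
    dpf
        Differential pathlength factor per wavelength (760, 850 nm).
    extinction
        2x2 extinction matrix, rows = wavelengths, columns = (HbO, HbR),
        in 1/(uM cm).
    """

    distance_cm: float = DEFAULT_DISTANCE_CM
    dpf: tuple[float, float] = DEFAULT_DPF
    extinction: tuple[tuple[float, float], tuple[float, float]] = field(
        default=DEFAULT_EXTINCTION
    )

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise GeometryError(f"distance_cm must be > 0, got {self.distance_cm}")
        if any(d <= 0 for d in self.dpf):
            raise GeometryError(f"DPF values must be > 0, got {self.dpf}")
        m = np.asarray(self.extinction, dtype=float)
        if m.shape != (2, 2) or not np.all(np.isfinite(m)):
            raise GeometryError("extinction must be a finite 2x2 matrix")
        if np.linalg.det(m) == 0.0:
            raise GeometryError("extinction matrix is singular")

    def coupling_matrix(self) -> np.ndarray:
        """2x2 matrix M with dOD = M @ (dHbO, dHbR)."""
        eps = np.asarray(self.extinction, dtype=float)
        scale = self.distance_cm * np.asarray(self.dpf, dtype=float)
        return eps * scale[:, None]


def od_from_hemo(
    hbo: np.ndarray, hbr: np.ndarray, geometry: ChannelGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer-Lambert map: concentration changes (uM) -> dOD per wavelength.

    Accepts arrays of any matching shape (time along the last axis or
    scalars); returns ``(od_760, od_850)`` with the same shape.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    m = geometry.coupling_matrix()
    od760 = m[0, 0] * hbo + m[0, 1] * hbr
    od850 = m[1, 0] * hbo + m[1, 1] * hbr
    return od760, od850


def hemo_from_od(
    od_760: np.ndarray, od_850: np.ndarray, geometry: ChannelGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse Beer-Lambert map: dOD per wavelength -> (dHbO, dHbR) in uM.

    Solves the per-sample 2x2 linear system exactly, so it is the exact
    inverse of :func:`od_from_hemo` under the same geometry.
    """
    od_760 = np.asarray(od_760, dtype=float)
    od_850 = np.asarray(od_850, dtype=float)
    m = geometry.coupling_matrix()
    minv = np.linalg.inv(m)
    hbo = minv[0, 0] * od_760 + minv[0, 1] * od_850
    hbr = minv[1, 0] * od_760 + minv[1, 1] * od_850
    return hbo, hbr
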