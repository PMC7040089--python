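"""Two-wavelength hemodynamic inversion.

A measured mean-time change is first converted to a brain absorption change
with the Monte-Carlo sensitivity factor, ``dmu_a(lambda) = d<t> / MTSF``,
then the absorption changes at 760 and 830 nm are inverted through the molar
extinction coefficients of oxy- and deoxyhemoglobin,

    dmu_a(lambda) = eps_HbO2(lambda) dC_HbO2 + eps_Hb(lambda) dC_Hb,

solving the 2x2 linear system per frame.  Concentrations are in uM, mu_a in
mm^-1 (natural log convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mtof import MTOFSeries
from .sensitivity import SensitivityFactors

#: decadic cm^-1 M^-1  ->  natural-log mm^-1 uM^-1
_EPS_SCALE = np.log(10.0) * 1e-7


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients in natural-log mm^-1 uM^-1.

    ``eps[wavelength] = (eps_HbO2, eps_Hb)``.  The 2x2 matrix for a
    wavelength pair must be well conditioned (condition number < 100).
    """

    eps: dict[float, tuple[float, float]]
    source: str = ""

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        eps = {
            float(r.wavelength_nm): (float(r.eps_hbo2) * _EPS_SCALE, float(r.eps_hb) * _EPS_SCALE)
            for r in df.itertuples()
        }
        src = df["source"].iloc[0] if "source" in df else str(path)
        return cls(eps, src)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        with resources.as_file(
            resources.files("trbci.data").joinpath("extinction_hb.csv")
        ) as p:
            return cls.from_csv(p)

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """Rows = wavelengths, columns = (HbO2, Hb)."""
        try:
            E = np.array([self.eps[wl] for wl in wavelengths])
        except KeyError as e:
            raise KeyError(f"wavelength {e.args[0]} nm missing from extinction table")
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond >= 100:
            raise ValueError(
                f"extinction matrix ill-conditioned (condition number {cond:.3g})"
            )
        return E


@dataclass
class AbsorptionChange:
    """Per-frame brain absorption change at one wavelength, mm^-1."""

    delta_mua: np.ndarray
    wavelength_nm: float
    sampling_period_s: float = 0.3
    channel: str | None = None


@dataclass
class HbTimeCourse:
    """Oxy-/deoxyhemoglobin concentration changes per frame, uM."""

    delta_hbo2: np.ndarray
    delta_hb: np.ndarray
    sampling_period_s: float = 0.3
    channel: str | None = None


def delta_mua_from_mtof(
    delta_t: MTOFSeries | np.ndarray,
    sens: SensitivityFactors,
    wavelength_nm: float | None = None,
) -> AbsorptionChange:
    """Invert the mean-time change to a brain absorption change (Beer-style).

    ``dmu_a = d<t> / MTSF`` with the per-wavelength brain sensitivity factor;
    MTSF is negative, so a mean-time decrease maps to increased absorption.
    """
    if isinstance(delta_t, MTOFSeries):
        values = delta_t.delta_t
        wl = delta_t.wavelength_nm if wavelength_nm is None else wavelength_nm
        period = delta_t.sampling_period_s
        channel = delta_t.channel
    else:
        values = np.asarray(delta_t, dtype=float)
        wl = wavelength_nm
        period = 0.3
        channel = None
    if wl is None or float(wl) not in sens.mtsf:
        raise KeyError(f"sensitivity factor for wavelength {wl} nm not available")
    mtsf = sens.mtsf[float(wl)]
    if mtsf == 0:
        raise ValueError("MTSF is zero")
    return AbsorptionChange(values / mtsf, float(wl), period, channel)


def hb_concentrations(
    mua_a: AbsorptionChange, mua_b: AbsorptionChange, table: ExtinctionTable
) -> HbTimeCourse:
    """Solve the per-frame 2x2 extinction system for (dC_HbO2, dC_Hb)."""
    if mua_a.delta_mua.shape != mua_b.delta_mua.shape:
        raise ValueError("wavelength series must have equal length")
    E = table.matrix((mua_a.wavelength_nm, mua_b.wavelength_nm))
    rhs = np.stack([mua_a.delta_mua, mua_b.delta_mua])
    sol = np.linalg.solve(E, rhs)
    return HbTimeCourse(sol[0], sol[1], mua_a.sampling_period_s, mua_a.channel)


def forward_mua(
    delta_hbo2: np.ndarray,
    delta_hb: np.ndarray,
    table: ExtinctionTable,
    wavelengths: tuple[float, float] = (760.0, 830.0),
) -> np.ndarray:
    """Forward extinction map: concentrations (uM) -> per-wavelength dmu_a.

    Returns an array of shape (n_wavelengths, n_frames); the exact inverse of
    :func:`hb_concentrations`.
    """
    E = table.matrix(wavelengths)
    return E @ np.stack([np.asarray(delta_hbo2, float), np.asarray(delta_hb, float)])
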