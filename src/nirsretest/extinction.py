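"""Hemoglobin extinction coefficients and the Beer-Lambert matrix.

Decadic molar extinction coefficients, cm^-1 M^-1, from the widely used
compiled in-vitro hemoglobin spectra (Gratzer/Kollias compilation) at the
two LED wavelengths of the simulated instrument.  The convention
throughout the package is decadic optical density, OD = -log10(I/I0),
paired with these decadic coefficients; forward simulation and inversion
share this one table, so concentration round trips are exact by
construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXTINCTION", "extinction_matrix"]

# wavelength (nm) -> (epsilon_HbO, epsilon_HbR), cm^-1 M^-1 (decadic)
EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (1486.5865, 3843.707),
    850.0: (2526.391, 1798.643),
}


def extinction_matrix(wavelengths=(760.0, 850.0)) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR).

    Units are cm^-1 uM^-1 so that ``E @ [dHbO, dHbR] * d * DPF`` gives
    optical density for concentrations in micromolar and distance in cm.
    """
    rows = []
    for wl in wavelengths:
        if wl not in EXTINCTION:
            raise KeyError(f"no extinction coefficients tabulated at {wl} nm")
        rows.append(EXTINCTION[wl])
    e = np.asarray(rows, dtype=float) * 1e-6  # per uM
    if abs(np.linalg.det(e)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return e
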