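"""Spectral pre-treatments: SNV, Savitzky-Golay derivatives, and combinations.

Six method names are recognised: ``raw``, ``snv``, ``d1``, ``d2``,
``snv_d1``, ``snv_d2``. SNV (standard normal variate) standardizes each
spectrum to mean 0 / sample SD 1, removing additive offsets and
multiplicative scatter. The derivatives are Savitzky-Golay local polynomial
derivatives (default window 15 points, polynomial order 2), expressed per nm
so the numbers do not depend on the grid step, and trimmed to the interior
bands where the full window fits -- edges are dropped rather than padded,
because padding fabricates signal exactly where informative bands can sit
close to the grid boundary. For the combined methods SNV is applied first.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectraMatrix
from .errors import DegenerateDataError, InvalidParameterError

__all__ = ["METHODS", "snv", "sg_derivative", "preprocess"]

METHODS = ("raw", "snv", "d1", "d2", "snv_d1", "snv_d2")


def snv(X: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: standardize each spectrum row.

    Each row becomes ``(row - mean(row)) / sd(row)`` with the sample SD
    (denominator n-1). Raises :class:`DegenerateDataError` naming the sample
    if any row has zero variance.
    """
    vals = X.values
    if vals.shape[1] < 2:
        raise InvalidParameterError("SNV needs at least 2 bands per spectrum")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        names = ", ".join(X.sample_ids[i] for i in flat[:5])
        raise DegenerateDataError(
            f"zero-variance spectrum for sample(s): {names}"
        )
    return SpectraMatrix(
        values=(vals - mean) / sd,
        wavelengths=X.wavelengths.copy(),
        sample_ids=list(X.sample_ids),
    )


def sg_derivative(
    X: SpectraMatrix, order: int, window: int = 15, polyorder: int = 2
) -> SpectraMatrix:
    """Savitzky-Golay derivative of each spectrum, in signal units per nm.

    Output keeps only the ``n_bands - window + 1`` interior bands where the
    full window fits; the wavelength axis is trimmed to match.
    """
    if order not in (1, 2):
        raise InvalidParameterError(f"derivative order must be 1 or 2, got {order}")
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"window must be an odd count >= 3, got {window}")
    if window > X.n_bands:
        raise InvalidParameterError(
            f"window {window} exceeds band count {X.n_bands}"
        )
    if polyorder < order:
        raise InvalidParameterError(
            f"polyorder {polyorder} must be >= derivative order {order}"
        )
    if polyorder >= window:
        raise InvalidParameterError(
            f"polyorder {polyorder} must be < window {window}"
        )
    deriv = savgol_filter(
        X.values, window_length=window, polyorder=polyorder, deriv=order,
        delta=X.step, axis=1, mode="interp",
    )
    half = (window - 1) // 2
    sl = slice(half, X.n_bands - half)
    return SpectraMatrix(
        values=deriv[:, sl],
        wavelengths=X.wavelengths[sl].copy(),
        sample_ids=list(X.sample_ids),
    )


def preprocess(
    X: SpectraMatrix,
    method: str,
    window: int = 15,
    polyorder: int = 2,
    snv_first: bool = True,
) -> SpectraMatrix:
    """Apply one of the six named pre-treatments.

    ``snv_first`` controls the composition order of the combined methods
    (default: SNV, then derivative).
    """
    if method not in METHODS:
        raise InvalidParameterError(
            f"unknown preprocessing method '{method}'; choose from {METHODS}"
        )
    if method == "raw":
        return X
    if method == "snv":
        return snv(X)
    order = 1 if method.endswith("d1") else 2
    if method in ("d1", "d2"):
        return sg_derivative(X, order, window, polyorder)
    if snv_first:
        return sg_derivative(snv(X), order, window, polyorder)
    return snv(sg_derivative(X, order, window, polyorder))
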