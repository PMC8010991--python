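"""In-memory containers shared across modules.

The central one is :class:`SpectraMatrix`: a samples x bands block of
reflectance (or any row-wise transform of it) together with the wavelength
axis in nanometres and per-sample identifiers. It is intentionally a thin
dataclass around numpy arrays -- all heavy lifting happens in the functional
modules -- but it validates its own invariants on construction so that a
malformed matrix fails loudly at the boundary, not deep inside a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

__all__ = ["SpectraMatrix"]


@dataclass
class SpectraMatrix:
    """Samples x wavelengths signal block.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_bands)
        Reflectance / absorbance / transformed signal. Must be finite.
    wavelengths : ndarray, shape (n_bands,)
        Strictly increasing, evenly spaced wavelength axis in nm.
    sample_ids : sequence of str
        One identifier per row.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D samples x bands matrix")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.values.shape[1]:
            raise SchemaError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band count {self.values.shape[1]}"
            )
        if self.wavelengths.size >= 2:
            steps = np.diff(self.wavelengths)
            if np.any(steps <= 0):
                raise SchemaError("wavelengths must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-8):
                raise SchemaError("wavelengths must be evenly spaced")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise SchemaError(
                f"non-finite value at sample row {bad[0]}, band column {bad[1]}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise SchemaError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def step(self) -> float:
        """Wavelength grid spacing in nm."""
        if self.wavelengths.size < 2:
            raise SchemaError("step undefined for a single-band matrix")
        return float(self.wavelengths[1] - self.wavelengths[0])

    def take(self, row_indices) -> "SpectraMatrix":
        """Row subset preserving order of ``row_indices``."""
        idx = np.asarray(row_indices)
        return SpectraMatrix(
            values=self.values[idx],
            wavelengths=self.wavelengths.copy(),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            values=self.values.copy(),
            wavelengths=self.wavelengths.copy(),
            sample_ids=list(self.sample_ids),
        )
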