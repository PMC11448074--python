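"""Core in-memory containers for mass spectra and detected peak lists.

A :class:`Spectrum` is a pair of equal-length arrays (m/z in Da, intensity in
arbitrary units) plus a record of the preprocessing steps already applied to
it.  The processing state lets downstream operations refuse out-of-order
application (e.g. TIC normalization before baseline subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical order of the preprocessing states a spectrum moves through.
PIPELINE_STATES = ("raw", "sqrt", "baseline_subtracted", "tic_normalized")


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass(frozen=True)
class Spectrum:
    """One mass spectrum with processing-state provenance.

    Parameters
    ----------
    mz : ndarray
        Mass-to-charge values in Da, strictly increasing.
    intensity : ndarray
        Non-negative intensities in arbitrary units, same length as ``mz``.
    state : tuple of str
        Ordered record of applied steps; always starts with ``"raw"``.
    spectrum_id : str
        Identifier used to key feature-matrix rows.
    """

    mz: np.ndarray
    intensity: np.ndarray
    state: tuple[str, ...] = ("raw",)
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if mz.shape != intensity.shape:
            raise ValueError(
                f"mz and intensity lengths differ: {mz.size} vs {intensity.size}"
            )
        if mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def current_state(self) -> str:
        return self.state[-1]

    def require_state(self, expected: str, operation: str) -> None:
        """Raise :class:`PipelineOrderError` unless the spectrum is in ``expected`` state."""
        if self.current_state != expected:
            raise PipelineOrderError(
                f"{operation} requires a spectrum in state {expected!r}, "
                f"got {self.current_state!r} (history: {' -> '.join(self.state)})"
            )

    def advanced(self, new_state: str, intensity: np.ndarray) -> "Spectrum":
        """Return a copy with ``intensity`` replaced and ``new_state`` appended."""
        return replace(self, intensity=np.asarray(intensity, float), state=self.state + (new_state,))


@dataclass(frozen=True)
class PeakList:
    """Detected peaks of a single spectrum.

    ``mz``, ``intensity`` and ``snr`` are parallel arrays; ``snr`` is the peak
    apex intensity divided by the spectrum's robust noise level.
    """

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    source_spectrum_id: str = ""

    def __post_init__(self) -> None:
        for name in ("mz", "intensity", "snr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("mz, intensity and snr must have identical shapes")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak mz values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class LabeledSpectrum:
    """A spectrum plus its cohort metadata (strain, class, extraction method)."""

    spectrum: Spectrum
    strain_id: str
    class_label: str
    method: str
    replicate_index: int = field(default=1)

    @property
    def spectrum_id(self) -> str:
        return self.spectrum.spectrum_id
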