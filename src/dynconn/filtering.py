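"""Band-pass filtering of component time courses.

A fifth-order Butterworth band-pass on [0.01, 0.15] Hz is applied to every
component time course before connectivity estimation.  The filter is
applied forward-backward (zero phase) so that connectivity windows are not
shifted in time; "order" names the design order of the band-pass
prototype, so the effective attenuation of the two-pass application is
doubled.  Edge transients on short series are suppressed by odd-symmetric
signal extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """Band edges in Hz, design order, and the sampling interval (TR)."""

    low_hz: float = 0.01
    high_hz: float = 0.15
    order: int = 5
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= nyquist:
            raise ValueError(
                f"high_hz={self.high_hz} not below Nyquist {nyquist} "
                f"for TR={self.tr_seconds}s"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")

    @property
    def fs(self) -> float:
        return 1.0 / self.tr_seconds


def bandpass(timecourses: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth band-pass, column-wise.

    Parameters
    ----------
    timecourses
        T x R matrix (T timepoints, R components).
    spec
        Band edges / order / TR.

    Returns
    -------
    T x R filtered matrix.
    """
    x = np.asarray(timecourses, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in time courses")
    if x.shape[0] <= 3 * spec.order:
        raise ValueError(
            f"series too short ({x.shape[0]} samples) for order-{spec.order} filtering"
        )
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=spec.fs, output="sos"
    )
    out = signal.sosfiltfilt(sos, x, axis=0, padtype="odd")
    return out if np.asarray(timecourses).ndim > 1 else out[:, 0]
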