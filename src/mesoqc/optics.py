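"""Small detection-path optics helpers.

Infinity-corrected objectives reach their nominal magnification only with
the tube lens focal length they were designed for; pairing them with a
different tube lens rescales the magnification by the focal-length ratio.
"""

from __future__ import annotations

__all__ = ["tube_lens_magnification_scale", "effective_magnification"]


def tube_lens_magnification_scale(f_used_mm: float, f_nominal_mm: float) -> float:
    """Magnification scale factor from swapping the tube lens.

    E.g. a 200 mm-design objective behind a 180 mm tube lens runs at
    180/200 = 0.9 of its nominal magnification.
    """
    if f_used_mm <= 0 or f_nominal_mm <= 0:
        raise ValueError("tube lens focal lengths must be positive")
    return f_used_mm / f_nominal_mm


def effective_magnification(nominal_magnification: float, f_used_mm: float,
                            f_nominal_mm: float) -> float:
    """Actual magnification of an objective behind a non-design tube lens."""
    if nominal_magnification <= 0:
        raise ValueError("nominal magnification must be positive")
    return nominal_magnification * tube_lens_magnification_scale(f_used_mm, f_nominal_mm)
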