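"""Blade-element mechanical-sensitivity gradient for a flapping wing.

In a strip-wise (blade-element) decomposition of a flapping wing rotating
about the shoulder, a strip at spanwise position r moves with speed
proportional to r, so its aerodynamic force scales as c(r) * r^2 * dr and
its contribution to the inertial moment as m(r) * r^2 * dr.  Dividing by
the strip area c(r) * dr, the per-area force and per-area inertial moment
both grow as r^2 — chord taper cancels from the per-area law.  This r^2
gradient is the mechanical-sensitivity profile against which the fitted
per-slice evolutionary rate and disparity profiles are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensitivityProfile", "sensitivity_profile", "predicted_rate_shape"]


@dataclass
class SensitivityProfile:
    positions: np.ndarray          # r/R in [0, 1]
    per_area_force: np.ndarray     # normalized to 1 at the tip
    per_area_inertia: np.ndarray
    chord: np.ndarray | None = None
    exponent: float = 2.0


def sensitivity_profile(positions, chord_profile=None, exponent: float = 2.0) -> SensitivityProfile:
    """Relative per-area aerodynamic force and inertial moment along the span.

    Both scale as (r/R)**exponent (default square law), normalized to 1 at
    the tip; an optional chord profile is carried along for section-total
    quantities but does not alter the per-area law.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    r = np.asarray(positions, dtype=float)
    if (r < 0).any() or (r > 1).any():
        raise ValueError("positions must lie in [0, 1]")
    sens = r ** exponent
    chord = None
    if chord_profile is not None:
        chord = np.asarray(chord_profile, dtype=float)
        if chord.shape != r.shape or (chord <= 0).any():
            raise ValueError("chord profile must be positive and match positions")
    return SensitivityProfile(positions=r, per_area_force=sens,
                              per_area_inertia=sens.copy(), chord=chord,
                              exponent=exponent)


def predicted_rate_shape(profile: SensitivityProfile, hypothesis: str = "gradient",
                         wrist_frac: float = 0.4) -> np.ndarray:
    """Qualitative per-slice rate templates implied by mechanical sensitivity.

    hypothesis : {"gradient", "modular"}
        "gradient" — rates track the sensitivity profile smoothly along the
        span; "modular" — rates take two discrete levels (the mean
        sensitivity of each side of the wrist at ``wrist_frac`` of span),
        stepping up distally.

    Templates are shapes, not magnitudes: no link-function amplitude is
    implied.
    """
    r = profile.positions
    s = profile.per_area_force
    if hypothesis == "gradient":
        return s.copy()
    if hypothesis == "modular":
        distal = r >= wrist_frac
        if not distal.any() or distal.all():
            raise ValueError("wrist_frac must fall inside the position range")
        out = np.empty_like(s)
        out[~distal] = s[~distal].mean()
        out[distal] = s[distal].mean()
        return out
    raise ValueError(f"unknown hypothesis {hypothesis!r}")
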