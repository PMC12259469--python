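"""Poiseuille hemodynamics of a single idealized vessel.

For laminar flow of an incompressible Newtonian fluid in a cylindrical pipe,
the pressure drop is ΔP = R·Q with resistance

    R = 8 µ L / (π r⁴)

(µ dynamic viscosity, L pipe length, r radius).  Because R scales with
r⁻⁴, the relative resistance change between two calibers depends on the
diameter ratio alone: a narrowing of the embryonic left coronary artery from
66.377 µm to 58.492 µm (an 11.879% diameter reduction) raises its resistance
by about 66%.  Operations are unit-agnostic but require consistent units.
"""

from __future__ import annotations

import math

__all__ = ["resistance", "pressure_drop", "percent_diameter_reduction",
           "resistance_change_from_diameters"]


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")


def resistance(mu: float, L: float, r: float) -> float:
    """Poiseuille resistance R = 8·µ·L / (π·r⁴) of a cylindrical pipe."""
    _require_positive(mu=mu, L=L, r=r)
    return 8.0 * mu * L / (math.pi * r ** 4)


def pressure_drop(R: float, Q: float) -> float:
    """Pressure drop ΔP = R·Q across a pipe of resistance R at flow Q."""
    _require_positive(R=R)
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    return R * Q


def percent_diameter_reduction(d_ref: float, d_new: float) -> float:
    """Relative caliber loss, 100·(d_ref − d_new)/d_ref, in percent."""
    _require_positive(d_ref=d_ref, d_new=d_new)
    return 100.0 * (d_ref - d_new) / d_ref


def resistance_change_from_diameters(d_ref: float, d_new: float) -> float:
    """Percent resistance change implied by a caliber change, µ and L fixed.

    From R ∝ r⁻⁴ the radius factor cancels in the ratio:
    100·((d_ref/d_new)⁴ − 1).  Positive when the vessel narrows.
    """
    _require_positive(d_ref=d_ref, d_new=d_new)
    return 100.0 * ((d_ref / d_new) ** 4 - 1.0)
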