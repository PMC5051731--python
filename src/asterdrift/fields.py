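"""Radially symmetric sigmoid drift fields.

A drift field assigns every point in the oocyte a weight in (0, 1) that
mixes directed (centripetal) motion with Brownian motion.  The attractive
field is anchored at the chromatin edge (weight ~1 next to chromatin,
decaying outward); the repulsive field is anchored at the cell boundary
(weight ~1 at the cortex, decaying inward).  Both share the same form

    phi(r) = 1 / (1 + exp((r - r_half) / s))

where ``r`` is the distance from the field's origin, ``r_half`` the
half-maximum distance and ``1/s`` the steepness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DriftField", "sigmoid_field"]

# exp argument clip; beyond this the sigmoid is 0/1 to double precision
_EXP_CLIP = 700.0


class InvalidFieldError(ValueError):
    """Raised for a drift field with non-positive steepness scale."""


@dataclass(frozen=True)
class DriftField:
    """Sigmoid weight field, radially symmetric about its origin.

    Parameters
    ----------
    r_half : float
        Distance (um) from the origin at which the weight is 0.5.
    s : float
        Decay length (um); ``1/s`` is the steepness factor. Must be > 0.
    origin : {"chromatin_edge", "cell_boundary"}
        Where ``r = 0`` is measured from. Attractive fields originate at
        the chromatin edge, repulsive fields at the cell boundary.
    """

    r_half: float
    s: float
    origin: str = "chromatin_edge"

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise InvalidFieldError(f"field steepness scale s must be > 0, got {self.s}")
        if self.origin not in ("chromatin_edge", "cell_boundary"):
            raise InvalidFieldError(f"unknown field origin {self.origin!r}")

    def weight(self, r):
        """Evaluate the field at distance ``r`` (um) from its origin."""
        return sigmoid_field(r, self)


def sigmoid_field(r, field: DriftField):
    """Evaluate ``1 / (1 + exp((r - r_half)/s))``; monotone non-increasing in r.

    Accepts scalars or arrays.  Values lie strictly in (0, 1) for finite
    arguments (up to floating-point saturation in the far tails).
    """
    if not field.s > 0:
        raise InvalidFieldError(f"field steepness scale s must be > 0, got {field.s}")
    z = np.clip((np.asarray(r, dtype=float) - field.r_half) / field.s, -_EXP_CLIP, _EXP_CLIP)
    out = 1.0 / (1.0 + np.exp(z))
    if np.ndim(r) == 0:
        return float(out)
    return out
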