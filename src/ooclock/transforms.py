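"""Age transformations linking chronological age to the clock response.

Three transforms are supported:

* ``identity`` — response is age in years (within-species chronological clocks).
* ``relative`` — response is age divided by the species' maximum lifespan,
  a value in (0, 1]; this is what makes a single prediction equation
  meaningful across species with very different lifespans.
* ``loglinear`` — log(age + offset) below a maturity knot, continued linearly
  above it with matched value and slope.  Off by default; provided for
  experimentation with juvenile-heavy designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError

KINDS = ("identity", "relative", "loglinear")


def relative_age(age_years, max_lifespan_years):
    """Chronological age divided by the species maximum lifespan.

    Vectorized; raises if any age is nonpositive or exceeds the lifespan.
    """
    age = np.asarray(age_years, float)
    lifespan = np.asarray(max_lifespan_years, float)
    if np.any(lifespan <= 0):
        raise ValidationError("max_lifespan_years must be positive")
    if np.any(age <= 0):
        raise ValidationError("age_years must be positive")
    if np.any(age > lifespan):
        idx = np.argwhere(np.atleast_1d(age > lifespan)).ravel()
        raise ValidationError(f"age exceeds maximum lifespan at index {idx[:5].tolist()}")
    out = age / lifespan
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AgeTransform:
    """Forward/inverse map between age in years and the regression response."""

    kind: str = "identity"
    maturity_offset: float = 0.0
    knot: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if self.kind == "loglinear" and self.knot is not None and self.knot <= -self.maturity_offset:
            raise ValidationError("loglinear knot must exceed -maturity_offset")

    def forward(self, age_years, max_lifespan_years=None):
        age = np.asarray(age_years, float)
        if self.kind == "identity":
            out = age.copy()
        elif self.kind == "relative":
            if max_lifespan_years is None:
                raise ValidationError("relative transform requires max_lifespan_years")
            out = np.asarray(relative_age(age, max_lifespan_years), float)
        else:
            off = self.maturity_offset
            if np.any(age + off <= 0):
                raise ValidationError("loglinear transform requires age + offset > 0")
            if self.knot is None:
                out = np.log(age + off)
            else:
                k = self.knot
                out = np.where(
                    age <= k,
                    np.log(age + off),
                    np.log(k + off) + (age - k) / (k + off),
                )
        return float(out) if out.ndim == 0 else out

    def inverse(self, response, max_lifespan_years=None):
        y = np.asarray(response, float)
        if self.kind == "identity":
            out = y.copy()
        elif self.kind == "relative":
            if max_lifespan_years is None:
                raise ValidationError("relative transform requires max_lifespan_years")
            out = y * np.asarray(max_lifespan_years, float)
        else:
            off = self.maturity_offset
            if self.knot is None:
                out = np.exp(y) - off
            else:
                k = self.knot
                yk = np.log(k + off)
                out = np.where(y <= yk, np.exp(np.minimum(y, yk)) - off,
                               k + (y - yk) * (k + off))
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "maturity_offset": self.maturity_offset,
            "knot": self.knot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransform":
        return cls(
            kind=d.get("kind", "identity"),
            maturity_offset=float(d.get("maturity_offset", 0.0) or 0.0),
            knot=None if d.get("knot") is None else float(d["knot"]),
        )
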