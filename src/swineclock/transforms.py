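"""Invertible mappings between chronological age and the clock regression response.

Three transforms are supported:

``identity``
    Response is age in years. Used for the single-species (pig) clocks.
``relative``
    Response is age divided by the species' maximum recorded lifespan, so
    animals of species with very different lifespans are aligned on [0, 1].
``loglinear``
    Piecewise response used for cross-species *chronological* clocks:
    logarithmic before the species' maturity age ``m`` and linear after,
    continuous with a continuous first derivative at the knot:

        f(a) = log((a + k) / (m + k))   for a <= m
        f(a) = (a - m) / (m + k)        for a >  m

    with offset ``k`` (default 1 year). The log branch compresses the rapid
    early-life methylation drift; the linear branch leaves adult ages on an
    interpretable scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AgeTransform",
    "DEFAULT_MAX_LIFESPAN",
    "DEFAULT_MATURITY",
    "relative_age",
    "loglinear",
    "inverse_loglinear",
]

TRANSFORM_KINDS = ("identity", "relative", "loglinear")

#: Maximum recorded lifespans (years). The pig value is the conservative
#: figure for Sus scrofa; the human value is the longest documented lifespan.
DEFAULT_MAX_LIFESPAN: dict[str, float] = {"pig": 23.0, "human": 122.0}

#: Age of sexual maturity (years) used as the log-linear knot. These are
#: package defaults on the customary scale for each species, exposed in config.
DEFAULT_MATURITY: dict[str, float] = {"pig": 1.0, "human": 15.0}


@dataclass(frozen=True)
class AgeTransform:
    """Specification of the age -> response mapping attached to a clock."""

    kind: str = "identity"
    max_lifespan_by_species: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_LIFESPAN)
    )
    maturity_by_species: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MATURITY)
    )
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(
                f"unknown transform kind {self.kind!r}; expected one of {TRANSFORM_KINDS}"
            )
        for sp, v in self.max_lifespan_by_species.items():
            if not v > 0:
                raise ValueError(f"max lifespan for {sp!r} must be > 0, got {v}")
        for sp, v in self.maturity_by_species.items():
            if not v > 0:
                raise ValueError(f"maturity for {sp!r} must be > 0, got {v}")

    # -- species parameter lookup -------------------------------------------------
    def _lifespan(self, species: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.max_lifespan_by_species[s] for s in species], float)
        except KeyError as e:
            raise KeyError(f"no max lifespan recorded for species {e.args[0]!r}") from None

    def _maturity(self, species: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.maturity_by_species[s] for s in species], float)
        except KeyError as e:
            raise KeyError(f"no maturity recorded for species {e.args[0]!r}") from None

    # -- forward / inverse --------------------------------------------------------
    def forward(self, age_years, species) -> np.ndarray:
        """Map chronological age (years) to the regression response."""
        age = np.atleast_1d(np.asarray(age_years, dtype=float))
        sp = np.broadcast_to(np.atleast_1d(np.asarray(species, dtype=object)), age.shape)
        if np.any(age < 0):
            raise ValueError("age_years must be non-negative")
        if self.kind == "identity":
            out = age.copy()
        elif self.kind == "relative":
            out = age / self._lifespan(sp)
            if np.any(out > 1):
                warnings.warn(
                    "relative age > 1: sample older than the recorded species maximum",
                    stacklevel=2,
                )
        else:  # loglinear
            m = self._maturity(sp)
            k = self.offset
            out = np.where(
                age <= m,
                np.log((age + k) / (m + k)),
                (age - m) / (m + k),
            )
        return out if np.ndim(age_years) else float(out[0])

    def inverse(self, y, species) -> np.ndarray:
        """Map a response value back to chronological age (years)."""
        yv = np.atleast_1d(np.asarray(y, dtype=float))
        sp = np.broadcast_to(np.atleast_1d(np.asarray(species, dtype=object)), yv.shape)
        if self.kind == "identity":
            out = yv.copy()
        elif self.kind == "relative":
            out = yv * self._lifespan(sp)
        else:
            m = self._maturity(sp)
            k = self.offset
            out = np.where(yv <= 0, (m + k) * np.exp(yv) - k, yv * (m + k) + m)
        return out if np.ndim(y) else float(out[0])

    # -- serialization ------------------------------------------------------------
    def to_params(self) -> dict:
        return {
            "kind": self.kind,
            "max_lifespan_by_species": dict(self.max_lifespan_by_species),
            "maturity_by_species": dict(self.maturity_by_species),
            "offset": self.offset,
        }

    @classmethod
    def from_params(cls, params: Mapping) -> "AgeTransform":
        return cls(
            kind=params["kind"],
            max_lifespan_by_species=dict(params.get("max_lifespan_by_species", {})),
            maturity_by_species=dict(params.get("maturity_by_species", {})),
            offset=float(params.get("offset", 1.0)),
        )


def relative_age(age_years, species, transform: AgeTransform | None = None):
    """Age divided by the species' maximum recorded lifespan."""
    t = transform if transform is not None else AgeTransform(kind="relative")
    if t.kind != "relative":
        t = AgeTransform(
            kind="relative",
            max_lifespan_by_species=t.max_lifespan_by_species,
            maturity_by_species=t.maturity_by_species,
            offset=t.offset,
        )
    return t.forward(age_years, species)


def loglinear(age_years, species, transform: AgeTransform | None = None):
    """Piecewise log/linear response with knot at the species maturity age."""
    t = transform if transform is not None else AgeTransform(kind="loglinear")
    if t.kind != "loglinear":
        t = AgeTransform(
            kind="loglinear",
            max_lifespan_by_species=t.max_lifespan_by_species,
            maturity_by_species=t.maturity_by_species,
            offset=t.offset,
        )
    return t.forward(age_years, species)


def inverse_loglinear(y, species, transform: AgeTransform | None = None):
    """Exact inverse of :func:`loglinear` on both branches."""
    t = transform if transform is not None else AgeTransform(kind="loglinear")
    if t.kind != "loglinear":
        t = AgeTransform(
            kind="loglinear",
            max_lifespan_by_species=t.max_lifespan_by_species,
            maturity_by_species=t.maturity_by_species,
            offset=t.offset,
        )
    return t.inverse(y, species)
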