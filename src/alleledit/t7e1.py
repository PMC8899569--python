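"""T7 endonuclease I (T7E1) densitometry to variant frequency conversion.

T7E1 cleaves heteroduplexes at mismatch bubbles, so after denature/re-anneal
of an edited amplicon pool the cleaved fraction reflects heteroduplex
formation between distinct alleles.  With a variant fraction p (as a
proportion), random re-annealing leaves a homoduplex fraction of
(1 - p)^2 + p^2 ... the standard single-variant estimator assumes the
cleaved fraction f = 1 - (1 - p)^2 and inverts it:

    variant frequency (%) = 100 x (1 - sqrt(1 - f))

Densitometry inputs are relative band densities (e.g. ImageJ gel lane
measurements); fraction cleaved = sum(cleavage bands) / (cleavage + uncut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

_EPS = 1e-12


@dataclass(frozen=True)
class GelDensities:
    """Relative band densities for one T7E1 lane."""

    cleaved_band_densities: tuple[float, ...]
    uncut_density: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleaved_band_densities",
                           tuple(float(d) for d in self.cleaved_band_densities))
        if any(d < 0 for d in self.cleaved_band_densities) or self.uncut_density < 0:
            raise ValueError("band densities must be nonnegative")
        if not self.cleaved_band_densities and self.uncut_density == 0:
            raise ValueError("at least one band density required")


def fraction_cleaved(g: GelDensities | None = None,
                     cleaved: Sequence[float] | None = None,
                     uncut: float | None = None) -> float:
    """Total cleavage-band density over total lane density, in [0, 1]."""
    if g is None:
        g = GelDensities(tuple(cleaved or ()), float(uncut or 0.0))
    total_cleaved = sum(g.cleaved_band_densities)
    total = total_cleaved + g.uncut_density
    if total <= 0:
        raise ValueError("all band densities are zero; fraction undefined")
    return total_cleaved / total


def t7e1_variant_frequency(fraction: float) -> float:
    """Variant frequency (%) = 100 x (1 - sqrt(1 - fraction cleaved)).

    Monotone increasing on [0, 1]; values within 1e-12 outside the bounds are
    treated as float noise and clipped, anything further out is an error.
    """
    f = float(fraction)
    if -_EPS <= f < 0.0:
        f = 0.0
    elif 1.0 < f <= 1.0 + _EPS:
        f = 1.0
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction cleaved {fraction} outside [0, 1]")
    return 100.0 * (1.0 - math.sqrt(1.0 - f))


def expected_fraction_cleaved(variant_frequency_percent: float) -> float:
    """Forward model: noiseless cleaved fraction for a variant frequency p%.

    f = 1 - (1 - p/100)^2 — the inverse of :func:`t7e1_variant_frequency`.
    """
    p = float(variant_frequency_percent)
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"variant frequency {p} outside [0, 100]")
    return 1.0 - (1.0 - p / 100.0) ** 2
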