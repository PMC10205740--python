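"""Damage scores for stained epidermis.

Two scalar measures of UV-induced cell damage are in play:

* ``S_nuclei = N_dmg / N_all`` — the classical pathologist score, the ratio
  of damaged nuclei to all nuclei visible in the epidermis (a weak label).
* ``S_area = A_dmg / A_epi`` — the area-based score derived from a 3-class
  segmentation mask: damaged-pixel area over total epidermis-pixel area,
  where the epidermis area includes the damaged pixels (damage is a subset
  of the epidermis, so the score is always in [0, 1]).

Mask label convention throughout the package: 0 = background / other
tissue, 1 = healthy epidermis, 2 = damaged epidermis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND, HEALTHY, DAMAGED = 0, 1, 2
MASK_CLASSES = (BACKGROUND, HEALTHY, DAMAGED)


class UndefinedScoreError(ValueError):
    """Raised when a score's denominator is empty (no nuclei / no epidermis).

    An image in which no epidermis is detected must surface as a failure,
    not be silently scored 0.
    """


@dataclass(frozen=True)
class NucleiCounts:
    """Raw terms of S_nuclei: damaged and total nucleus counts."""

    n_dmg: int
    n_all: int

    def __post_init__(self):
        if not 0 <= self.n_dmg <= self.n_all:
            raise ValueError(f"need 0 <= n_dmg <= n_all, got ({self.n_dmg}, {self.n_all})")


@dataclass(frozen=True)
class AreaSummary:
    """Raw terms of S_area: damaged and total epidermis pixel counts."""

    a_dmg: int
    a_epi: int

    def __post_init__(self):
        if self.a_dmg < 0 or self.a_dmg > self.a_epi:
            raise ValueError(f"need 0 <= a_dmg <= a_epi, got ({self.a_dmg}, {self.a_epi})")


@dataclass(frozen=True)
class ScorePair:
    """Per-sample damage scores; at least one of the two must be present."""

    s_nuclei: float | None = None
    s_area: float | None = None

    def __post_init__(self):
        if self.s_nuclei is None and self.s_area is None:
            raise ValueError("at least one of s_nuclei / s_area must be present")
        for name, v in (("s_nuclei", self.s_nuclei), ("s_area", self.s_area)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def s_nuclei_from_counts(counts: NucleiCounts) -> float:
    if counts.n_all == 0:
        raise UndefinedScoreError("S_nuclei undefined: no nuclei counted")
    return counts.n_dmg / counts.n_all


def s_area_from_mask(mask: np.ndarray) -> tuple[ScorePair, AreaSummary]:
    """S_area from a 3-class label mask.

    ``a_epi`` counts both healthy and damaged epidermis pixels; a mask with
    no epidermis at all raises :class:`UndefinedScoreError`.
    """
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), MASK_CLASSES)
    if bad.size:
        raise ValueError(f"mask contains classes outside {{0,1,2}}: {bad.tolist()}")
    a_dmg = int((mask == DAMAGED).sum())
    a_epi = a_dmg + int((mask == HEALTHY).sum())
    if a_epi == 0:
        raise UndefinedScoreError("S_area undefined: mask contains no epidermis")
    return ScorePair(s_area=a_dmg / a_epi), AreaSummary(a_dmg=a_dmg, a_epi=a_epi)


def cross_score(pair: ScorePair, target: str) -> float:
    """Read a score of kind ``target`` ("nuclei" or "area") out of ``pair``.

    When the requested kind is absent the other score is returned unchanged:
    the two scores estimate the same underlying damage level, and the
    identity conversion is exactly how the cross-score columns of the model
    comparison are computed.
    """
    if target not in ("nuclei", "area"):
        raise ValueError(f"target must be 'nuclei' or 'area', got {target!r}")
    own = pair.s_nuclei if target == "nuclei" else pair.s_area
    if own is not None:
        return own
    other = pair.s_area if target == "nuclei" else pair.s_nuclei
    return other
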