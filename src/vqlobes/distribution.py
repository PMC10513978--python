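"""Relative lobar tracer distributions.

The quantification endpoint everywhere in this package is a
:class:`LobarDistribution`: the percentage of total lung counts attributed to
each of the five lobes (RUL, RML, RLL, LUL, LLL), plus the derived right- and
left-lung totals.  Percentages always sum to 100 across the five lobes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["LOBE_NAMES", "LOBE_CODES", "RIGHT_LOBES", "LEFT_LOBES",
           "REGION_NAMES", "LobarDistribution"]

#: Anatomical ordering of the five lung lobes.
LOBE_NAMES: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL")

#: Integer label codes used in lobe label maps (0 is background).
LOBE_CODES: dict[str, int] = {"RUL": 1, "RML": 2, "RLL": 3, "LUL": 4, "LLL": 5}

RIGHT_LOBES: tuple[str, ...] = ("RUL", "RML", "RLL")
LEFT_LOBES: tuple[str, ...] = ("LUL", "LLL")

#: The seven reported regions: five lobes plus the two whole lungs.
REGION_NAMES: tuple[str, ...] = LOBE_NAMES + ("right_lung", "left_lung")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LobarDistribution:
    """Relative tracer percentages for the five lobes.

    Parameters
    ----------
    rul, rml, rll, lul, lll
        Percentage of counts in each lobe; the five must sum to 100.
    tracer
        ``"V"`` (ventilation) or ``"Q"`` (perfusion).
    method
        Provenance tag, e.g. ``"truth"``, ``"planar"``, ``"lobar_3d"``.
    absent
        Lobes reported as 0 because they are missing from the label map
        (lobectomy case); flagged rather than silently zero.
    """

    rul: float
    rml: float
    rll: float
    lul: float
    lll: float
    tracer: str = "V"
    method: str = "truth"
    absent: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vals = self.values()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite lobar percentages: {vals}")
        if np.any(vals < -_SUM_TOL) or np.any(vals > 100 + 1e-6):
            raise ValueError(f"lobar percentages outside [0, 100]: {vals}")
        total = float(vals.sum())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"lobar percentages sum to {total}, expected 100")

    def values(self) -> np.ndarray:
        """The five lobe percentages in anatomical order."""
        return np.array([self.rul, self.rml, self.rll, self.lul, self.lll],
                        dtype=float)

    @property
    def right_lung(self) -> float:
        return self.rul + self.rml + self.rll

    @property
    def left_lung(self) -> float:
        return self.lul + self.lll

    def region(self, name: str) -> float:
        """Percentage for any of the seven report regions."""
        if name in ("right_lung", "left_lung"):
            return getattr(self, name)
        return float(self.values()[LOBE_NAMES.index(name)])

    def as_dict(self, include_lungs: bool = True) -> dict[str, float]:
        d = dict(zip(LOBE_NAMES, self.values()))
        if include_lungs:
            d["right_lung"] = self.right_lung
            d["left_lung"] = self.left_lung
        return d

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, float],
        tracer: str = "V",
        method: str = "truth",
        absent: tuple[str, ...] = (),
    ) -> "LobarDistribution":
        """Normalise per-lobe counts to percentages summing to 100.

        Raises
        ------
        ValueError
            If the total count over all lobes is zero (nothing to normalise).
        """
        raw = np.array([float(counts.get(name, 0.0)) for name in LOBE_NAMES])
        if np.any(raw < 0):
            raise ValueError(f"negative lobar counts: {dict(counts)}")
        total = raw.sum()
        if total <= 0:
            raise ValueError("total lobar count is zero; cannot form a "
                             "relative distribution")
        pct = 100.0 * raw / total
        return cls(*pct, tracer=tracer, method=method, absent=tuple(absent))
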