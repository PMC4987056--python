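"""Core spectral container and ppm region bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["Spectrum", "RegionSet", "DEFAULT_REGIONS"]


@dataclass
class Spectrum:
    """A 1D NMR spectrum on a strictly increasing ppm axis.

    ``intensity`` may be complex (before phase correction) or real.  Every
    processing operation returns a new ``Spectrum`` and appends one entry
    ``(operation name, parameters)`` to ``history``; quality-control scalars
    (TSP area, TSP FWHM, applied phase angle, applied ppm shift, ...)
    accumulate in ``qc``.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    material: str = "plasma"
    sample_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)
    history: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    qc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be one-dimensional")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")

    # -- helpers ----------------------------------------------------------
    @property
    def real(self) -> np.ndarray:
        return np.real(self.intensity)

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.intensity)

    @property
    def step(self) -> float:
        """Median ppm grid step (the axis may have excised gaps)."""
        return float(np.median(np.diff(self.ppm)))

    def evolve(self, op: str, params: dict[str, Any], **changes: Any) -> "Spectrum":
        """Copy with updated fields and one appended history entry."""
        new = replace(
            self,
            ppm=changes.pop("ppm", self.ppm),
            intensity=changes.pop("intensity", self.intensity),
            meta=dict(self.meta),
            history=self.history + [(op, dict(params))],
            qc=dict(self.qc),
            **changes,
        )
        return new

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for the half-open ppm interval [lo, hi)."""
        return (self.ppm >= lo) & (self.ppm < hi)


@dataclass(frozen=True)
class RegionSet:
    """Named half-open ppm intervals used for clipping and excision."""

    clip: tuple[float, float] = (-0.5, 9.0)
    # the water bounds leave the urinary ascorbate signal at 4.52 ppm
    # outside the deleted artifact region
    water: tuple[float, float] = (4.55, 4.95)
    tsp: tuple[float, float] = (-0.2, 0.2)
    urea: tuple[float, float] | None = None  # urine only

    def excised(self) -> list[tuple[str, tuple[float, float]]]:
        out = [("water", self.water), ("tsp", self.tsp)]
        if self.urea is not None:
            out.append(("urea", self.urea))
        return out

    def validate(self) -> None:
        lo, hi = self.clip
        if not lo < hi:
            raise ValueError("clip bounds must be ordered")
        for name, (a, b) in self.excised():
            if not a < b:
                raise ValueError(f"region {name!r} bounds must be ordered")


def default_regions(material: str) -> RegionSet:
    """Standard regions: water 4.55-4.95 ppm, TSP +-0.2 ppm, and for urine
    the urea band 5.5-6.1 ppm."""
    if material == "urine":
        return RegionSet(urea=(5.5, 6.1))
    return RegionSet()


DEFAULT_REGIONS = {
    "plasma": default_regions("plasma"),
    "urine": default_regions("urine"),
}
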