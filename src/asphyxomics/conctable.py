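"""Samples-by-metabolites concentration container shared across stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ConcentrationTable"]


@dataclass
class ConcentrationTable:
    """Concentration matrix: rows are samples, columns metabolites.

    ``units`` maps each metabolite to ``"mM"`` (identified, TSP-referenced)
    or ``"a.u."`` (unidentified signals with unknown proton counts, never
    reported in mM).  ``meta`` carries the aligned sample annotations
    (animal id, group, material, time point, endpoints).
    """

    values: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    meta: pd.DataFrame | None = None
    creatinine_normalized: bool = False
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("concentrations must be non-negative")
        for col in self.values.columns:
            self.units.setdefault(col, "mM")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def identified(self) -> list[str]:
        return [m for m in self.metabolites if self.units.get(m) == "mM"]

    def subset(self, sample_ids) -> "ConcentrationTable":
        meta = self.meta.loc[sample_ids] if self.meta is not None else None
        return ConcentrationTable(
            values=self.values.loc[sample_ids].copy(),
            units=dict(self.units),
            meta=meta,
            creatinine_normalized=self.creatinine_normalized,
            flags={k: list(v) for k, v in self.flags.items()},
        )

    # -- round-trippable CSV output (units in a sidecar) ------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, index_label="sample_id")
        sidecar = path.with_suffix(".units.csv")
        pd.Series(self.units, name="unit").rename_axis("metabolite").to_csv(sidecar)
        if self.meta is not None:
            self.meta.to_csv(path.with_suffix(".meta.csv"), index_label="sample_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConcentrationTable":
        path = Path(path)
        values = pd.read_csv(path, index_col="sample_id")
        units: dict[str, str] = {}
        sidecar = path.with_suffix(".units.csv")
        if sidecar.exists():
            units = pd.read_csv(sidecar, index_col="metabolite")["unit"].to_dict()
        meta = None
        meta_path = path.with_suffix(".meta.csv")
        if meta_path.exists():
            meta = pd.read_csv(meta_path, index_col="sample_id")
        return cls(values=values, units=units, meta=meta)
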