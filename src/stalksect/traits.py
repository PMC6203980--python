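"""The 21 anatomical traits of a stalk cross-section.

Section-level geometry: PAD, AAD (mm), CCR (mm), SA (mm^2), AR.
Bundle counts: VB total; PVB (peripheral layer) and CVB_2..CVB_4
(central layers 2..4).  Bundle areas: PA, CA_2..CA_4 and their per-layer
area ratios PAR, CAR_2..CAR_4 (each layer's bundle area divided by that
layer's own area — under equal-area layers the denominators are all
~SA/4).  MA = TA / VB is the mean bundle area, TA the total bundle area
and Rsection = TA / SA.

A bundle belongs wholly to the layer containing its centroid; the trait
scheme is defined on the default four equal-area layers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .bundles import VascularBundle
from .errors import InputError
from .layers import LayerMap
from .segment import StalkSection

#: Table order of the trait abbreviations (hyphens as underscores).
TRAIT_NAMES = [
    "PAD", "AAD", "CCR", "SA",
    "VB", "PVB", "CVB_2", "CVB_3", "CVB_4",
    "PA", "CA_2", "CA_3", "CA_4",
    "PAR", "CAR_2", "CAR_3", "CAR_4",
    "MA", "TA", "Rsection", "AR",
]


@dataclass
class TraitVector:
    PAD: float
    AAD: float
    CCR: float
    SA: float
    VB: int
    PVB: int
    CVB_2: int
    CVB_3: int
    CVB_4: int
    PA: float
    CA_2: float
    CA_3: float
    CA_4: float
    PAR: float
    CAR_2: float
    CAR_3: float
    CAR_4: float
    MA: float
    TA: float
    Rsection: float
    AR: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)


def compute_traits(
    section: StalkSection,
    layers: LayerMap,
    bundles: list[VascularBundle],
) -> TraitVector:
    """Aggregate section, layer, and bundle measurements into the 21-trait
    vector.  Requires the four-layer decomposition the trait scheme is
    defined on."""
    if layers.n_layers != 4:
        raise InputError(
            f"trait scheme is defined on 4 layers, got {layers.n_layers}"
        )
    counts = [0, 0, 0, 0]
    areas = [0.0, 0.0, 0.0, 0.0]
    for b in bundles:
        if not 1 <= b.layer_id <= 4:
            raise InputError(f"bundle {b.uid} has layer_id {b.layer_id} outside 1..4")
        counts[b.layer_id - 1] += 1
        areas[b.layer_id - 1] += b.area_mm2
    vb = sum(counts)
    ta = sum(areas)
    la = layers.layer_areas_mm2
    return TraitVector(
        PAD=section.PAD,
        AAD=section.AAD,
        CCR=section.CCR,
        SA=section.SA,
        VB=vb,
        PVB=counts[0],
        CVB_2=counts[1],
        CVB_3=counts[2],
        CVB_4=counts[3],
        PA=areas[0],
        CA_2=areas[1],
        CA_3=areas[2],
        CA_4=areas[3],
        PAR=areas[0] / la[0],
        CAR_2=areas[1] / la[1],
        CAR_3=areas[2] / la[2],
        CAR_4=areas[3] / la[3],
        MA=ta / vb if vb > 0 else 0.0,
        TA=ta,
        Rsection=ta / section.SA,
        AR=section.AR,
    )


def summarize_traits(
    table: pd.DataFrame, group: str | None = None
) -> pd.DataFrame:
    """Per-trait summary (mean, sd, quartiles), optionally by group label.

    Returns one row per (group, trait) with columns mean, sd, min, q25,
    median, q75, max, n.
    """
    trait_cols = [c for c in table.columns if c in TRAIT_NAMES]
    unknown = [
        c
        for c in table.columns
        if c not in TRAIT_NAMES and c not in ("source_id", "BS", group)
    ]
    if not trait_cols:
        raise InputError("table contains no recognized trait columns")
    if unknown:
        raise InputError(f"unknown trait columns: {unknown}")

    def _summ(df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for t in trait_cols:
            v = df[t].to_numpy(dtype=float)
            rows.append(
                {
                    "trait": t,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                    "min": v.min(),
                    "q25": np.quantile(v, 0.25),
                    "median": np.quantile(v, 0.5),
                    "q75": np.quantile(v, 0.75),
                    "max": v.max(),
                    "n": len(v),
                }
            )
        return pd.DataFrame(rows)

    if group is None:
        return _summ(table)
    parts = []
    for g, df in table.groupby(group, sort=True):
        s = _summ(df)
        s.insert(0, group, g)
        parts.append(s)
    return pd.concat(parts, ignore_index=True)
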