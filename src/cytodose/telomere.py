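"""q-FISH telomere-length analysis via T/C% ratios.

Telomere length is read out as fluorescence of each telomeric probe signal
relative to the chromosome-2 centromere signal of the same metaphase (the
internal reference, whose sequence length is stable across cells), expressed
as a percentage: T/C% = 100 * T / C.  Because both signals share a metaphase,
the ratio is invariant to overall staining/exposure intensity.  Groups
(dose x harvest time) are compared nonparametrically with the Mann-Whitney
U test, either on pooled per-telomere values (default) or on per-metaphase
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings as _warnings

import numpy as np
import pandas as pd

from .scoring import mann_whitney_u

__all__ = [
    "TelomereMeasurement",
    "TelomereSummary",
    "tc_percent",
    "compare_doses",
    "summarize",
    "read_telomere_tsv",
    "write_telomere_tsv",
    "MIN_CHROMOSOMES",
]

#: scoring depth per experimental point at which the per-group sample is
#: considered adequate (chromosomes analyzed; each carries two telomeres)
MIN_CHROMOSOMES = 1800


@dataclass(frozen=True)
class TelomereMeasurement:
    """Fluorescence readout of one metaphase."""

    metaphase_id: str
    dose: float
    harvest_time: int  # hours after exposure
    telomere_intensities: tuple[float, ...]
    centromere2_intensity: float

    def __post_init__(self) -> None:
        if self.centromere2_intensity <= 0:
            raise ValueError("centromere-2 reference intensity must be > 0")
        tel = tuple(float(t) for t in self.telomere_intensities)
        if len(tel) == 0:
            raise ValueError("at least one telomere intensity per metaphase")
        if any(t < 0 for t in tel):
            raise ValueError("telomere intensities must be >= 0")
        object.__setattr__(self, "telomere_intensities", tel)

    @property
    def tc_values(self) -> np.ndarray:
        """Per-telomere T/C% values of this metaphase."""
        return 100.0 * np.asarray(self.telomere_intensities) / self.centromere2_intensity


@dataclass(frozen=True)
class TelomereSummary:
    dose: float
    harvest_time: int
    n_telomeres: int
    mean_tc: float
    sem_tc: float
    u_vs_sham: float | None
    p_vs_sham: float | None

    @property
    def meets_scoring_depth(self) -> bool:
        # two telomeres per chromosome end-pair convention: compare telomere
        # count against the chromosomes-analyzed depth x 2 ends
        return self.n_telomeres >= MIN_CHROMOSOMES


def tc_percent(telomere_intensity: float, centromere_intensity: float) -> float:
    """T/C% = 100 * telomere fluorescence / centromere-2 fluorescence."""
    if centromere_intensity <= 0:
        raise ValueError("reference centromere intensity must be > 0")
    if telomere_intensity < 0:
        raise ValueError("telomere intensity must be >= 0")
    return 100.0 * telomere_intensity / centromere_intensity


def _group_values(
    measurements: Iterable[TelomereMeasurement],
    dose: float,
    harvest_time: int,
    unit: str,
) -> np.ndarray:
    vals = []
    for m in measurements:
        if m.dose == dose and m.harvest_time == harvest_time:
            if unit == "telomere":
                vals.extend(m.tc_values)
            else:
                vals.append(float(m.tc_values.mean()))
    return np.asarray(vals, dtype=float)


def compare_doses(
    measurements: Sequence[TelomereMeasurement],
    dose_a: float,
    dose_b: float,
    harvest_time: int,
    unit: str = "telomere",
) -> tuple[float, float, dict]:
    """Mann-Whitney comparison of T/C% between two dose groups.

    ``unit="telomere"`` pools every telomere of the group (default);
    ``unit="metaphase"`` compares per-metaphase mean T/C%.  Returns
    ``(U, p, effect)`` where ``effect`` reports group means and their
    difference (dose_b - dose_a) in T/C percentage points.
    """
    if unit not in ("telomere", "metaphase"):
        raise ValueError(f"unit must be 'telomere' or 'metaphase', got {unit!r}")
    a = _group_values(measurements, dose_a, harvest_time, unit)
    b = _group_values(measurements, dose_b, harvest_time, unit)
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"missing group: dose {dose_a if a.size == 0 else dose_b} Gy "
            f"at {harvest_time} h"
        )
    u, p = mann_whitney_u(a, b)
    effect = {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(b.mean() - a.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
    return u, p, effect


def summarize(
    measurements: Sequence[TelomereMeasurement],
    sham_dose: float = 0.0,
    unit: str = "telomere",
) -> list[TelomereSummary]:
    """Per (dose, harvest time) T/C% summary with comparison against sham."""
    groups = sorted({(m.dose, m.harvest_time) for m in measurements})
    out = []
    for dose, t in groups:
        vals = _group_values(measurements, dose, t, unit)
        n_tel = len(_group_values(measurements, dose, t, "telomere"))
        if n_tel < MIN_CHROMOSOMES:
            _warnings.warn(
                f"group ({dose} Gy, {t} h) has {n_tel} telomeres, below the "
                f"{MIN_CHROMOSOMES}-chromosome scoring depth",
                stacklevel=2,
            )
        u = p = None
        if dose != sham_dose:
            sham_vals = _group_values(measurements, sham_dose, t, unit)
            if sham_vals.size:
                u, p = mann_whitney_u(sham_vals, vals)
        out.append(
            TelomereSummary(
                dose=dose,
                harvest_time=t,
                n_telomeres=n_tel,
                mean_tc=float(vals.mean()),
                sem_tc=float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else 0.0,
                u_vs_sham=u,
                p_vs_sham=p,
            )
        )
    return out


# per-metaphase TSV: metaphase_id, dose_gy, time_h, centromere2_intensity,
# telomere_intensities (comma-separated)

def write_telomere_tsv(
    measurements: Iterable[TelomereMeasurement], path: str | Path
) -> None:
    rows = [
        {
            "metaphase_id": m.metaphase_id,
            "dose_gy": m.dose,
            "time_h": m.harvest_time,
            "centromere2_intensity": m.centromere2_intensity,
            "telomere_intensities": ",".join(
                f"{t:.6g}" for t in m.telomere_intensities
            ),
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_telomere_tsv(path: str | Path) -> list[TelomereMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"metaphase_id": str})
    required = {
        "metaphase_id",
        "dose_gy",
        "time_h",
        "centromere2_intensity",
        "telomere_intensities",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"telomere TSV needs columns {sorted(required)}")
    return [
        TelomereMeasurement(
            metaphase_id=str(row.metaphase_id),
            dose=float(row.dose_gy),
            harvest_time=int(row.time_h),
            telomere_intensities=tuple(
                float(t) for t in str(row.telomere_intensities).split(",")
            ),
            centromere2_intensity=float(row.centromere2_intensity),
        )
        for row in df.itertuples(index=False)
    ]
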