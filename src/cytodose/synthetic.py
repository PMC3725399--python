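"""Synthetic per-cell aberration records and telomere intensity tables.

The generator emulates the statistical structure the downstream analysis
assumes.  Per cell at dose D, the number of excess acentric fragments is
Poisson with mean ``c_f + alpha_f*D + beta_f*D^2`` and the number of
exchanges Poisson with mean ``c_e + alpha_e*D + beta_e*D^2``; each exchange
is stable (a balanced translocation) with probability ``p_stable``,
otherwise its unstable subtype is drawn uniformly among dicentric, centric
ring and unbalanced translocation.  Only simple aberrations are generated,
so the minimal-break identity breaks = 2*exchanges + fragments holds
exactly.  Default rates anchor the control frequencies near 4.4% aberrant
cells and 0.4% exchanges, with the study design of 500 control cells and
200 cells per irradiated dose at 0, 0.1, 0.25, 0.5 and 1 Gy.

Telomere tables draw, per metaphase, a log-normal centromere-2 reference
intensity and 92 per-telomere T/C% values (46 chromosomes x 2 telomere
end-pairs) from a truncated normal with configurable sham mean (default
33%), spread, and per-dose shift (default: no dose effect, the null the
assay reported).

A single integer seed drives one root generator; the scoring and telomere
streams are spawned from it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .scoring import (
    AberrationCategory,
    AberrationEvent,
    AberrationSubtype,
    CellRecord,
    ScoringTable,
)
from .telomere import TelomereMeasurement

__all__ = [
    "SimulationConfig",
    "simulate_scoring",
    "simulate_telomeres",
    "table1_fixture",
]

_UNSTABLE_SUBTYPES = (
    AberrationSubtype.DICENTRIC,
    AberrationSubtype.CENTRIC_RING,
    AberrationSubtype.UNBALANCED_TRANSLOCATION,
)


def _lq(params: tuple[float, float, float], d: float) -> float:
    c, a, b = params
    return c + a * d + b * d * d


@dataclass(frozen=True)
class TelomereConfig:
    """Generating distribution of the q-FISH arm."""

    sham_mean_tc: float = 33.0  # sham T/C% level
    sd_tc: float = 12.0  # per-telomere spread of T/C%
    dose_shift: dict[float, float] = field(default_factory=dict)  # T/C% points
    telomeres_per_metaphase: int = 92
    metaphases_per_group: int = 25  # 25 x 92 = 2300 telomeres > 1800 depth
    harvest_times: tuple[int, ...] = (24, 48)
    centromere_log_mean: float = 7.0
    centromere_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.sd_tc < 0 or self.sham_mean_tc <= 0:
            raise ValueError("telomere mean must be > 0 and sd >= 0")
        if self.telomeres_per_metaphase < 1 or self.metaphases_per_group < 1:
            raise ValueError("telomere sample sizes must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generating parameters of the synthetic experiment."""

    doses: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 1.0)
    cells_control: int = 500
    cells_per_dose: int = 200
    # per-cell LQ rates (c, alpha, beta): fragments and exchanges
    fragment_rate: tuple[float, float, float] = (0.036, 0.20, 0.03)
    exchange_rate: tuple[float, float, float] = (0.008, 0.01, 0.12)
    p_stable: float = 0.5
    telomere: TelomereConfig = field(default_factory=TelomereConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses) or len(self.doses) == 0:
            raise ValueError("doses must be a non-empty list of values >= 0 Gy")
        if self.cells_control < 1 or self.cells_per_dose < 1:
            raise ValueError("cell counts must be >= 1")
        if not 0 <= self.p_stable <= 1:
            raise ValueError("p_stable must be in [0, 1]")
        for rates in (self.fragment_rate, self.exchange_rate):
            if len(rates) != 3 or any(r < 0 for r in rates):
                raise ValueError("LQ rate parameters must be 3 values >= 0")

    def n_cells(self, dose: float) -> int:
        return self.cells_control if dose == min(self.doses) else self.cells_per_dose


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    scoring_seq, telomere_seq = root.spawn(2)
    return np.random.default_rng(scoring_seq), np.random.default_rng(telomere_seq)


def simulate_scoring(config: SimulationConfig) -> list[CellRecord]:
    """Draw one synthetic mFISH scoring experiment (deterministic per seed)."""
    rng, _ = _streams(config.seed)
    records: list[CellRecord] = []
    for dose in config.doses:
        n = config.n_cells(dose)
        mu_f = _lq(config.fragment_rate, dose)
        mu_e = _lq(config.exchange_rate, dose)
        n_frag = rng.poisson(mu_f, size=n)
        n_exch = rng.poisson(mu_e, size=n)
        for i in range(n):
            events: list[AberrationEvent] = []
            for _ in range(n_frag[i]):
                events.append(
                    AberrationEvent(
                        category=AberrationCategory.EXCESS_FRAGMENT,
                        subtype=AberrationSubtype.TERMINAL_FRAGMENT,
                    )
                )
            for _ in range(n_exch[i]):
                if rng.random() < config.p_stable:
                    events.append(
                        AberrationEvent(
                            category=AberrationCategory.STABLE_EXCHANGE,
                            subtype=AberrationSubtype.BALANCED_TRANSLOCATION,
                        )
                    )
                else:
                    subtype = _UNSTABLE_SUBTYPES[rng.integers(len(_UNSTABLE_SUBTYPES))]
                    events.append(
                        AberrationEvent(
                            category=AberrationCategory.UNSTABLE_EXCHANGE,
                            subtype=subtype,
                        )
                    )
            records.append(
                CellRecord(
                    cell_id=f"d{dose:g}-c{i:04d}",
                    dose=dose,
                    events=tuple(events),
                )
            )
    return records


def simulate_telomeres(config: SimulationConfig) -> list[TelomereMeasurement]:
    """Draw one synthetic q-FISH experiment (deterministic per seed)."""
    _, rng = _streams(config.seed)
    tc = config.telomere
    measurements: list[TelomereMeasurement] = []
    for time_h in tc.harvest_times:
        for dose in config.doses:
            shift = tc.dose_shift.get(dose, 0.0)
            mean = tc.sham_mean_tc + shift
            for m in range(tc.metaphases_per_group):
                cent = float(
                    rng.lognormal(tc.centromere_log_mean, tc.centromere_log_sd)
                )
                tc_values = rng.normal(
                    mean, tc.sd_tc, size=tc.telomeres_per_metaphase
                )
                tc_values = np.clip(tc_values, 0.0, None)
                measurements.append(
                    TelomereMeasurement(
                        metaphase_id=f"t{time_h}-d{dose:g}-m{m:03d}",
                        dose=dose,
                        harvest_time=time_h,
                        telomere_intensities=tuple(tc_values / 100.0 * cent),
                        centromere2_intensity=cent,
                    )
                )
    return measurements


def table1_fixture() -> ScoringTable:
    """The packaged per-dose mFISH scoring counts of the calibration study.

    500 control and 200 cells per irradiated dose, with printed break,
    aberrant-cell, exchange and total-aberration counts.  Note the break
    count is scored, not derived: at 1 Gy the printed 88 breaks exceed the
    minimal-break identity value 2*exchanges + fragments = 86, reflecting
    complex aberrations requiring extra breaks.
    """
    resource = importlib.resources.files("cytodose.data").joinpath(
        "mfish_scoring_counts.csv"
    )
    with importlib.resources.as_file(resource) as path:
        return ScoringTable.read_csv(path)
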