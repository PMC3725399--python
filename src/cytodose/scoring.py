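"""mFISH aberration scoring: event classification, break counting, per-dose
frequency tables, and the exact/nonparametric tests used to flag dose effects.

Structural aberrations detected by whole-karyotype painting are recorded per
cell in three categories: excess acentric fragments (fragments not associated
with an exchange), stable exchanges (balanced translocations) and unstable
exchanges (dicentrics, centric rings, unbalanced translocations).  A cell is
aberrant if it carries any structural aberration.  The break number of a cell
is the minimal number of chromosome breaks necessary and sufficient to produce
the observed aberrations: two per exchange, one per excess fragment (an
optional per-event override accommodates complex aberrations).
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AberrationCategory",
    "AberrationSubtype",
    "AberrationEvent",
    "CellRecord",
    "ScoringTable",
    "ENDPOINTS",
    "classify_event",
    "count_breaks",
    "tabulate",
    "fisher_exact",
    "mann_whitney_u",
    "read_cell_records",
    "write_cell_records",
]


class AberrationCategory(str, enum.Enum):
    EXCESS_FRAGMENT = "excess_fragment"
    STABLE_EXCHANGE = "stable_exchange"
    UNSTABLE_EXCHANGE = "unstable_exchange"


class AberrationSubtype(str, enum.Enum):
    BALANCED_TRANSLOCATION = "balanced_translocation"
    DICENTRIC = "dicentric"
    CENTRIC_RING = "centric_ring"
    UNBALANCED_TRANSLOCATION = "unbalanced_translocation"
    TERMINAL_FRAGMENT = "terminal_fragment"


#: subtype -> category, the painting-nomenclature grouping
SUBTYPE_CATEGORY: dict[AberrationSubtype, AberrationCategory] = {
    AberrationSubtype.BALANCED_TRANSLOCATION: AberrationCategory.STABLE_EXCHANGE,
    AberrationSubtype.DICENTRIC: AberrationCategory.UNSTABLE_EXCHANGE,
    AberrationSubtype.CENTRIC_RING: AberrationCategory.UNSTABLE_EXCHANGE,
    AberrationSubtype.UNBALANCED_TRANSLOCATION: AberrationCategory.UNSTABLE_EXCHANGE,
    AberrationSubtype.TERMINAL_FRAGMENT: AberrationCategory.EXCESS_FRAGMENT,
}

#: coded descriptors accepted by :func:`classify_event` (case-insensitive)
EVENT_CODES: dict[str, AberrationSubtype] = {
    "dic": AberrationSubtype.DICENTRIC,
    "r": AberrationSubtype.CENTRIC_RING,
    "t(bal)": AberrationSubtype.BALANCED_TRANSLOCATION,
    "t(unbal)": AberrationSubtype.UNBALANCED_TRANSLOCATION,
    "ace": AberrationSubtype.TERMINAL_FRAGMENT,
}

_EXCHANGE_CATEGORIES = (
    AberrationCategory.STABLE_EXCHANGE,
    AberrationCategory.UNSTABLE_EXCHANGE,
)

_VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}

#: endpoint column order of the per-dose table
ENDPOINTS = (
    "breaks",
    "aberrant_cells",
    "stable_exchanges",
    "unstable_exchanges",
    "total_aberrations",
)


@dataclass(frozen=True)
class AberrationEvent:
    """A single structural aberration observed in one cell."""

    category: AberrationCategory
    subtype: AberrationSubtype | None = None
    chromosomes_involved: tuple[str, ...] | None = None
    breaks_override: int | None = None

    def __post_init__(self) -> None:
        if self.subtype is not None:
            expected = SUBTYPE_CATEGORY[self.subtype]
            if expected is not self.category:
                raise ValueError(
                    f"subtype {self.subtype.value} belongs to category "
                    f"{expected.value}, not {self.category.value}"
                )
        if self.chromosomes_involved is not None:
            chroms = tuple(str(c).upper() for c in self.chromosomes_involved)
            bad = [c for c in chroms if c not in _VALID_CHROMOSOMES]
            if bad:
                raise ValueError(f"unknown chromosome identifiers: {bad}")
            minimum = 2 if self.category in _EXCHANGE_CATEGORIES else 1
            if len(chroms) < minimum:
                raise ValueError(
                    f"{self.category.value} requires >= {minimum} chromosomes, "
                    f"got {len(chroms)}"
                )
            object.__setattr__(self, "chromosomes_involved", chroms)
        if self.breaks_override is not None and self.breaks_override < 1:
            raise ValueError("breaks_override must be a positive count")

    @property
    def breaks(self) -> int:
        """Minimal break count of this event (2 per exchange, 1 per fragment)."""
        if self.breaks_override is not None:
            return self.breaks_override
        return 2 if self.category in _EXCHANGE_CATEGORIES else 1


@dataclass(frozen=True)
class CellRecord:
    """All structural aberrations scored in one cell."""

    cell_id: str
    dose: float
    events: tuple[AberrationEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0 Gy, got {self.dose}")
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def is_aberrant(self) -> bool:
        return len(self.events) > 0


def classify_event(descriptor: str) -> AberrationEvent:
    """Build an :class:`AberrationEvent` from a coded aberration descriptor.

    Accepted codes (case-insensitive): ``dic`` (dicentric), ``r`` (centric
    ring), ``t(bal)`` (balanced translocation), ``t(unbal)`` (unbalanced
    translocation), ``ace`` (excess acentric fragment).
    """
    code = descriptor.strip().lower()
    if code not in EVENT_CODES:
        accepted = ", ".join(sorted(EVENT_CODES))
        raise ValueError(
            f"unrecognized aberration descriptor {descriptor!r}; "
            f"accepted codes: {accepted}"
        )
    subtype = EVENT_CODES[code]
    return AberrationEvent(category=SUBTYPE_CATEGORY[subtype], subtype=subtype)


def count_breaks(record: CellRecord) -> int:
    """Minimal number of chromosome breaks producing the cell's aberrations."""
    return sum(event.breaks for event in record.events)


class ScoringTable:
    """Per-dose aberration counts and frequencies (percent of cells scored).

    Wraps a dose-indexed DataFrame with integer columns ``cells_scored``,
    ``breaks``, ``aberrant_cells``, ``stable_exchanges``,
    ``unstable_exchanges``, ``excess_fragments``, ``total_aberrations``.
    """

    COUNT_COLUMNS = (
        "cells_scored",
        "breaks",
        "aberrant_cells",
        "stable_exchanges",
        "unstable_exchanges",
        "excess_fragments",
        "total_aberrations",
    )

    def __init__(self, counts: pd.DataFrame):
        df = counts.copy()
        if "dose_gy" in df.columns:
            df = df.set_index("dose_gy")
        df.index = df.index.astype(float)
        df.index.name = "dose_gy"
        df = df.sort_index()
        if "excess_fragments" not in df.columns:
            df["excess_fragments"] = (
                df["total_aberrations"]
                - df["stable_exchanges"]
                - df["unstable_exchanges"]
            )
        missing = [c for c in self.COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[list(self.COUNT_COLUMNS)].astype(int)
        self._validate(df)
        self.counts = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            raise ValueError("scoring table must contain at least one dose level")
        if (df < 0).any().any():
            raise ValueError("counts must be nonnegative")
        if (df["cells_scored"] < 1).any():
            raise ValueError("cells_scored must be >= 1 at every dose")
        total = (
            df["excess_fragments"]
            + df["stable_exchanges"]
            + df["unstable_exchanges"]
        )
        if not (df["total_aberrations"] == total).all():
            raise ValueError(
                "total_aberrations must equal excess_fragments + exchanges"
            )
        if (df["aberrant_cells"] > df["cells_scored"]).any():
            raise ValueError("aberrant_cells cannot exceed cells_scored")
        if (df["aberrant_cells"] > df["total_aberrations"]).any():
            raise ValueError("aberrant_cells cannot exceed total_aberrations")

    @property
    def doses(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def cells_scored(self) -> np.ndarray:
        return self.counts["cells_scored"].to_numpy()

    @property
    def frequencies(self) -> pd.DataFrame:
        """Counts expressed as percent of cells scored per dose."""
        freq = self.counts.drop(columns="cells_scored").div(
            self.counts["cells_scored"], axis=0
        )
        return 100.0 * freq

    def endpoint_counts(self, endpoint: str) -> np.ndarray:
        if endpoint not in self.counts.columns or endpoint == "cells_scored":
            raise KeyError(f"unknown endpoint {endpoint!r}")
        return self.counts[endpoint].to_numpy()

    def control_row(self, endpoint: str) -> tuple[int, int]:
        """(count, cells scored) of the endpoint at the lowest (control) dose."""
        dose0 = self.counts.index.min()
        row = self.counts.loc[dose0]
        return int(row[endpoint]), int(row["cells_scored"])

    def to_csv(self, path: str | Path) -> None:
        self.counts.reset_index().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScoringTable":
        return cls(pd.read_csv(path))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScoringTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"ScoringTable({len(self.counts)} dose levels)"


def tabulate(records: Iterable[CellRecord]) -> ScoringTable:
    """Aggregate per-cell records into a per-dose :class:`ScoringTable`."""
    records = list(records)
    if not records:
        raise ValueError("cannot tabulate an empty record list")
    rows: dict[float, dict[str, int]] = {}
    for rec in records:
        row = rows.setdefault(
            float(rec.dose), {c: 0 for c in ScoringTable.COUNT_COLUMNS}
        )
        row["cells_scored"] += 1
        row["breaks"] += count_breaks(rec)
        row["aberrant_cells"] += int(rec.is_aberrant)
        for ev in rec.events:
            if ev.category is AberrationCategory.STABLE_EXCHANGE:
                row["stable_exchanges"] += 1
            elif ev.category is AberrationCategory.UNSTABLE_EXCHANGE:
                row["unstable_exchanges"] += 1
            else:
                row["excess_fragments"] += 1
            row["total_aberrations"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "dose_gy"
    return ScoringTable(df)


# ---------------------------------------------------------------------------
# Exact and nonparametric tests
# ---------------------------------------------------------------------------

def fisher_exact(
    a: int, b: int, c: int, d: int, sided: str = "two"
) -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Rows are groups (e.g. dose, control), columns are (aberrant,
    non-aberrant).  The p-value is computed by exact integer enumeration of
    the hypergeometric distribution over all tables with the observed
    margins; the two-sided value sums the probabilities of all tables no more
    probable than the observed one, ``sided="greater"`` sums tables with a
    first-cell count at least as large (``"less"`` at most as large).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"counts must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")

    n1, k_total, n_total = a + b, a + c, a + b + c + d
    if n_total == 0:
        raise ValueError("table is empty")
    lo = max(0, n1 + k_total - n_total)
    hi = min(n1, k_total)
    if n_total <= 2000:
        # exact integer weights: P(X = x) ∝ C(K, x) * C(N-K, n1-x)
        weights = [
            math.comb(k_total, x) * math.comb(n_total - k_total, n1 - x)
            for x in range(lo, hi + 1)
        ]
        total = sum(weights)
        obs = weights[a - lo]
        if sided == "greater":
            num = sum(w for x, w in enumerate(weights, start=lo) if x >= a)
        elif sided == "less":
            num = sum(w for x, w in enumerate(weights, start=lo) if x <= a)
        else:
            num = sum(w for w in weights if w <= obs)
        return min(1.0, num / total)
    # large tables: hypergeometric through scipy, relative tolerance on the
    # two-sided probability comparison
    dist = stats.hypergeom(n_total, k_total, n1)
    if sided == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if sided == "less":
        return float(min(1.0, dist.cdf(a)))
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    obs_p = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= obs_p * (1 + 1e-11)].sum()))


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of the first sample, midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    sided: str = "two",
    exact_limit: int = 20,
) -> tuple[float, float]:
    """Mann–Whitney U test; returns ``(U, p)`` with U for ``sample_a``.

    For combined sample sizes up to ``exact_limit`` the p-value is exact, by
    enumeration of every assignment of the pooled values to the two groups;
    above the cutoff a normal approximation with midrank tie correction and
    continuity correction is used.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")
    n, m = x.size, y.size
    u_obs = _mwu_statistic(x, y)
    mu = n * m / 2.0

    if n + m <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        count = 0
        n_perm = math.comb(n + m, n)
        eps = 1e-9
        for idx in itertools.combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - offset
            if sided == "two":
                hit = abs(u - mu) >= abs(u_obs - mu) - eps
            elif sided == "greater":
                hit = u >= u_obs - eps
            else:
                hit = u <= u_obs + eps
            count += hit
        return u_obs, count / n_perm

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    nn = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if sigma2 <= 0:  # all values identical
        return u_obs, 1.0
    sigma = math.sqrt(sigma2)
    if sided == "two":
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif sided == "greater":
        z = (u_obs - mu - 0.5) / sigma
        p = stats.norm.sf(z)
    else:
        z = (u_obs - mu + 0.5) / sigma
        p = stats.norm.cdf(z)
    return u_obs, min(1.0, float(p))


# ---------------------------------------------------------------------------
# Tidy per-cell TSV I/O
# ---------------------------------------------------------------------------
# columns: cell_id, dose_gy, event_code; events semicolon-separated, "." = none

def write_cell_records(records: Iterable[CellRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        codes = []
        for ev in rec.events:
            code = _event_to_code(ev)
            codes.append(code)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "dose_gy": rec.dose,
                "event_code": ";".join(codes) if codes else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _event_to_code(event: AberrationEvent) -> str:
    for code, subtype in EVENT_CODES.items():
        if event.subtype is subtype:
            return code
    # category without subtype: fall back to a category-representative code
    fallback = {
        AberrationCategory.EXCESS_FRAGMENT: "ace",
        AberrationCategory.STABLE_EXCHANGE: "t(bal)",
        AberrationCategory.UNSTABLE_EXCHANGE: "t(unbal)",
    }
    return fallback[event.category]


def read_cell_records(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "event_code": str})
    required = {"cell_id", "dose_gy", "event_code"}
    if not required.issubset(df.columns):
        raise ValueError(f"per-cell TSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        code_field = str(row.event_code).strip()
        if code_field in (".", "", "nan"):
            events: tuple[AberrationEvent, ...] = ()
        else:
            events = tuple(classify_event(c) for c in code_field.split(";"))
        records.append(
            CellRecord(cell_id=str(row.cell_id), dose=float(row.dose_gy), events=events)
        )
    return records
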