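"""End-to-end orchestration: scoring table -> per-dose exact tests -> fits
(with the induced-repair alternative and F-test) -> threshold doses ->
telomere comparisons, written out as CSV/JSON plus a plain-text summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dose_response, scoring, telomere, threshold

log = logging.getLogger("cytodose")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, criterion settings and seeds for one pipeline run."""

    output_dir: Path
    cell_records: Path | None = None  # tidy per-cell TSV
    scoring_csv: Path | None = None  # pre-aggregated per-dose CSV
    telomere_tsv: Path | None = None
    family_map: dict[str, dose_response.ModelFamily] = field(
        default_factory=lambda: dict(dose_response.DEFAULT_FAMILY_MAP)
    )
    alpha: float = 0.05
    n_cells: int = 200
    sided: str = "one"
    n_draws: int = 100_000
    seed: int = threshold.DEFAULT_SEED
    fit_method: str = "ml"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.cell_records is None and self.scoring_csv is None:
            raise ValueError(
                "config must provide per-cell records or a per-dose scoring CSV"
            )
        for p in (self.cell_records, self.scoring_csv, self.telomere_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        missing = set(scoring.ENDPOINTS) - set(self.family_map)
        if missing:
            raise ValueError(f"family_map must cover all endpoints; missing {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "family_map" in raw:
            raw["family_map"] = {
                k: dose_response.ModelFamily(v) for k, v in raw["family_map"].items()
            }
        for key in ("cell_records", "scoring_csv", "telomere_tsv"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _significance_flags(table: scoring.ScoringTable, sided: str) -> pd.DataFrame:
    """Per dose and endpoint: exact-test p-value of the increase over control."""
    alternative = "greater" if sided == "one" else "two"
    rows = []
    dose0 = float(table.doses.min())
    for dose in table.doses:
        if dose == dose0:
            continue
        row = {"dose_gy": dose}
        n = int(table.counts.loc[dose, "cells_scored"])
        for ep in scoring.ENDPOINTS:
            c, n_c = table.control_row(ep)
            k = int(table.counts.loc[dose, ep])
            row[ep] = scoring.fisher_exact(
                k, max(n - k, 0), c, n_c - c, sided=alternative
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("dose_gy")


def _fit_reports(
    table: scoring.ScoringTable,
    family_map: dict[str, dose_response.ModelFamily],
    method: str,
) -> dict:
    """Primary fit per endpoint plus, where nested, the induced-repair
    (low-dose hypersensitivity) alternative and the F-test between them."""
    reports: dict = {}
    for ep in scoring.ENDPOINTS:
        family = family_map[ep]
        entry: dict = {}
        try:
            primary = dose_response.fit(table, ep, family, method=method)
            entry["primary"] = primary.report()
        except (ValueError, RuntimeError) as exc:
            entry["error"] = str(exc)
            reports[ep] = entry
            continue
        if family in (
            dose_response.ModelFamily.LINEAR,
            dose_response.ModelFamily.LQ,
        ):
            try:
                hrs = dose_response.fit(
                    table, ep, dose_response.ModelFamily.HRS_LQ, method=method
                )
                entry["hrs_alternative"] = hrs.report()
                f_stat, p = dose_response.compare_models(primary, hrs)
                entry["f_test"] = {"F": f_stat, "p": p}
            except (ValueError, RuntimeError) as exc:
                # saturated alternative: p is not calculated
                entry["f_test"] = {"error": str(exc)}
        reports[ep] = entry
    return reports


def _summary_text(
    table: scoring.ScoringTable,
    flags: pd.DataFrame,
    estimates: list[threshold.ThresholdEstimate],
    alpha: float,
) -> str:
    lines = ["mFISH scoring: counts (percent of cells scored)", ""]
    freq = table.frequencies
    header = f"{'dose [Gy]':>9} {'cells':>6}" + "".join(
        f"{ep:>22}" for ep in scoring.ENDPOINTS
    )
    lines.append(header)
    for dose in table.doses:
        row = table.counts.loc[dose]
        cells = int(row["cells_scored"])
        body = "".join(
            f"{int(row[ep]):>14} ({freq.loc[dose, ep]:>4.1f})"
            for ep in scoring.ENDPOINTS
        )
        lines.append(f"{dose:>9.2f} {cells:>6}" + body)
    lines.append("")
    lines.append(f"doses significantly above control (exact test, alpha={alpha}):")
    for ep in scoring.ENDPOINTS:
        sig = [f"{d:g} Gy (p={flags.loc[d, ep]:.3g})" for d in flags.index
               if flags.loc[d, ep] <= alpha]
        lines.append(f"  {ep}: " + (", ".join(sig) if sig else "none"))
    lines.append("")
    lines.append("calculated detection-threshold dose [Gy] (95% upper CL):")
    for est in estimates:
        if est.error is not None:
            lines.append(f"  {est.endpoint}: not attained ({est.error})")
            continue
        extra = "  [extrapolated beyond 1 Gy]" if est.extrapolated else ""
        emp = f", empirical {est.empirical:g} Gy" if est.empirical else ""
        lines.append(
            f"  {est.endpoint}: {est.d_star:.2f} ({est.upper_cl95:.2f})"
            f"{emp}{extra}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to the output dir.

    Returns a dict with the in-memory results and the paths written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cell_records is not None:
        records = scoring.read_cell_records(config.cell_records)
        table = scoring.tabulate(records)
        log.info("tabulated %d cell records", len(records))
    else:
        table = scoring.ScoringTable.read_csv(config.scoring_csv)
    log.info(
        "scoring table: %d dose levels, %d cells",
        len(table.doses),
        int(table.cells_scored.sum()),
    )
    table.to_csv(out / "scoring_table.csv")

    flags = _significance_flags(table, config.sided)
    flags.to_csv(out / "significance.csv")

    fits = _fit_reports(table, config.family_map, config.fit_method)
    (out / "fits.json").write_text(json.dumps(fits, indent=2))

    log.info("threshold Monte Carlo: n_draws=%d seed=%d", config.n_draws, config.seed)
    estimates = threshold.threshold_table(
        table,
        family_map=config.family_map,
        alpha=config.alpha,
        n_cells=config.n_cells,
        sided=config.sided,
        n_draws=config.n_draws,
        seed=config.seed,
        method=config.fit_method,
    )
    thr_rows = []
    for est in estimates:
        if est.extrapolated:
            log.warning("%s threshold extrapolated beyond 1 Gy", est.endpoint)
        thr_rows.append(
            {
                "endpoint": est.endpoint,
                "family": est.family.value,
                "threshold_gy": est.d_star,
                "upper_cl95_gy": est.upper_cl95,
                "empirical_threshold_gy": est.empirical,
                "y_detect": est.y_detect,
                "alpha": est.criterion.alpha,
                "n_cells": est.criterion.n_cells,
                "sided": est.criterion.sided,
                "n_draws": est.n_draws,
                "seed": est.seed,
                "error": est.error,
            }
        )
    pd.DataFrame(thr_rows).to_csv(out / "thresholds.csv", index=False)

    telomere_results = None
    if config.telomere_tsv is not None:
        measurements = telomere.read_telomere_tsv(config.telomere_tsv)
        summaries = telomere.summarize(measurements)
        telomere_results = pd.DataFrame(
            [
                {
                    "dose_gy": s.dose,
                    "time_h": s.harvest_time,
                    "n_telomeres": s.n_telomeres,
                    "mean_tc_percent": s.mean_tc,
                    "sem_tc_percent": s.sem_tc,
                    "U_vs_sham": s.u_vs_sham,
                    "p_vs_sham": s.p_vs_sham,
                }
                for s in summaries
            ]
        )
        telomere_results.to_csv(out / "telomere_summary.csv", index=False)

    summary = _summary_text(table, flags, estimates, config.alpha)
    (out / "summary.txt").write_text(summary)

    return {
        "table": table,
        "significance": flags,
        "fits": fits,
        "thresholds": estimates,
        "telomere": telomere_results,
        "output_dir": out,
    }
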