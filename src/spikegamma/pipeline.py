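"""Study-shaped orchestration.

One call runs the full analysis the way the study is shaped: simulate (or
ingest) a genotype x age cohort, compute per-cell gamma spectral metrics,
spike-gamma coupling, and synaptic event statistics, assemble cohort
tables (with power and frequency variance normalized to the age-matched
control group), and compare groups per metric. Every input cell appears
exactly once — either in the results or in the inclusion ledger with the
reason it was excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ParameterError
from .coupling import CouplingConfig, FilterConfig, SpikeDetectConfig, analyze_cell
from .events import build_template, detect_events, event_statistics
from .group_stats import CohortTable, ComparisonResult, compare_groups
from .spectral import SpectralConfig, gamma_metrics, normalize_to_control
from .synth import CellRecord, CohortDesign, psc_kernel, simulate_cohort

__all__ = ["RunConfig", "RunReport", "run", "analyze_records", "design_from_dict"]

METRICS = (
    "normalized_power",
    "normalized_freq_variance",
    "vector_length",
    "firing_rate",
    "event_amplitude",
    "event_frequency",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full study-shaped run."""

    design: CohortDesign
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    detect: SpikeDetectConfig = field(default_factory=SpikeDetectConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    event_threshold: float = 3.5
    control: str = "WT"
    alpha: float = 0.05
    q_outlier: float = 0.01

    def __post_init__(self) -> None:
        nyq = self.design.lfp.sampling_rate / 2.0
        if self.spectral.band_high > nyq:
            raise ParameterError(
                f"spectral band_high {self.spectral.band_high} Hz exceeds Nyquist {nyq} Hz"
            )
        if self.filter.high_cut >= nyq:
            raise ParameterError(
                f"filter high_cut {self.filter.high_cut} Hz must be below Nyquist {nyq} Hz"
            )


@dataclass
class RunReport:
    """Per-cell metrics, cohort tables, comparisons, and the inclusion ledger."""

    cells: pd.DataFrame
    tables: dict[str, CohortTable]
    comparisons: dict[str, ComparisonResult]
    ledger: pd.DataFrame
    provenance: dict

    def summary(self) -> str:
        lines = [
            f"spikegamma run ({self.provenance.get('mode', '?')} mode, "
            f"seed={self.provenance.get('master_seed')})",
            f"cells analyzed: {len(self.cells)}; excluded: {len(self.ledger)}",
        ]
        for metric, comp in self.comparisons.items():
            sig = comp.pairwise[comp.pairwise["significant"]]["age"].tolist()
            lines.append(f"  {metric}: genotype effect significant at ages {sig or 'none'}")
        return "\n".join(lines)


def _reference_template(design: CohortDesign):
    """Detection template from noiseless copies of the design's PSC kernel.

    Synthetic stand-in for the experimenter's hand-picked representative
    events: 20+ identical kernel snippets averaged exactly as real ones
    would be.
    """
    kernel = psc_kernel(design.synaptic)
    return build_template(
        [kernel] * 20,
        sampling_rate=design.synaptic.sampling_rate,
        polarity=design.synaptic.polarity,
    )


def analyze_records(records: list[CellRecord], config: RunConfig) -> RunReport:
    """Run the per-cell analyses and group comparisons on simulated cells."""
    template = _reference_template(config.design)
    rows, ledger_rows = [], []
    for rec in records:
        try:
            gm = gamma_metrics(rec.lfp, config.spectral)
            cr = analyze_cell(rec.lfp, rec.cell_trace, config.filter,
                              config.detect, config.coupling)
            ev = detect_events(rec.synaptic, template, config.event_threshold)
            es = event_statistics(ev, rec.synaptic.duration)
        except ParameterError as exc:
            ledger_rows.append({"cell_id": rec.cell_id, "genotype": rec.genotype,
                                "age": rec.age, "reason": f"stage error: {exc}"})
            continue
        if not cr.included:
            reason = cr.exclusion_reason or f"Rayleigh p={cr.rayleigh_p:.3g} >= alpha"
            ledger_rows.append({"cell_id": rec.cell_id, "genotype": rec.genotype,
                                "age": rec.age, "reason": reason})
            continue
        rows.append({
            "cell_id": rec.cell_id, "animal_id": rec.animal_id,
            "genotype": rec.genotype, "age": rec.age,
            "gamma_power": gm.band_power,
            "peak_frequency": gm.peak_frequency,
            "freq_variance": gm.frequency_variance,
            "vector_length": cr.vector_length,
            "phase_angle": cr.phase_angle,
            "rayleigh_p": cr.rayleigh_p,
            "firing_rate": cr.firing_rate,
            "n_spikes": cr.n_spikes,
            "event_amplitude": es["mean_amplitude"],
            "event_frequency": es["frequency"],
            "true_kappa": rec.true_params["kappa"],
            "true_vector_length": rec.true_params["vector_length"],
        })
    cells = pd.DataFrame(rows)
    if cells.empty:
        raise ParameterError("no cells survived inclusion; nothing to compare")

    # normalize spectral metrics to the age-matched control group
    for raw, norm in (("gamma_power", "normalized_power"),
                      ("freq_variance", "normalized_freq_variance")):
        cells[norm] = np.nan
        for age in cells["age"].unique():
            sel = cells["age"] == age
            ctrl = cells[sel & (cells["genotype"] == config.control)][raw]
            cells.loc[sel, norm] = normalize_to_control(cells.loc[sel, raw], ctrl)

    tables: dict[str, CohortTable] = {}
    comparisons: dict[str, ComparisonResult] = {}
    for metric in METRICS:
        tbl = CohortTable(cells[["genotype", "age", "animal_id", "cell_id"]]
                          .assign(value=cells[metric]))
        tables[metric] = tbl
        try:
            comparisons[metric] = compare_groups(
                tbl, control=config.control, q_outlier=config.q_outlier,
                alpha=config.alpha,
            )
        except ParameterError as exc:
            ledger_rows.append({"cell_id": f"<metric:{metric}>", "genotype": "",
                                "age": "", "reason": str(exc)})
    ledger = pd.DataFrame(ledger_rows, columns=["cell_id", "genotype", "age", "reason"])
    provenance = {
        "mode": "simulate",
        "master_seed": config.design.master_seed,
        "version": __version__,
        "n_cells_in": len(records),
        "n_cells_analyzed": len(cells),
        "n_cells_excluded": len(records) - len(cells),
        "alpha": config.alpha,
        "q_outlier": config.q_outlier,
        "spectral_band": [config.spectral.band_low, config.spectral.band_high],
        "coupling_band": [config.filter.low_cut, config.filter.high_cut],
        "segment_length": config.spectral.segment_length,
    }
    return RunReport(cells=cells, tables=tables, comparisons=comparisons,
                     ledger=ledger, provenance=provenance)


def run(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Simulate the configured cohort, analyze it, optionally write outputs.

    Deterministic under a fixed ``design.master_seed``: rerunning into a
    clean directory reproduces all numeric outputs bit-identically.
    """
    records = simulate_cohort(config.design)
    report = analyze_records(records, config)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cells.to_csv(out / "cells.csv", index=False)
    report.ledger.to_csv(out / "inclusion_ledger.csv", index=False)
    for metric, tbl in report.tables.items():
        tbl.data.to_csv(out / f"cohort_{metric}.csv", index=False)
        tbl.summary().to_csv(out / f"summary_{metric}.csv", index=False)
    comp = {m: c.to_dict() for m, c in report.comparisons.items()}
    (out / "comparisons.json").write_text(json.dumps(comp, indent=1, default=float))
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=1, default=float))
    return out


def design_from_dict(spec: dict) -> CohortDesign:
    """Build a :class:`CohortDesign` from a plain dict (YAML-friendly).

    Expected keys: ``groups`` (list of ``[genotype, age, n_cells]``),
    optional ``effects`` (list of ``{genotype, age, <param>: multiplier}``),
    optional ``lfp``/``coupling``/``synaptic`` parameter overrides, and
    ``master_seed``.
    """
    from .synth import CouplingParams, GammaLfpParams, SynapticTraceParams

    groups = [(str(g), str(a), int(n)) for g, a, n in spec["groups"]]
    effects = {}
    for eff in spec.get("effects", []):
        eff = dict(eff)
        key = (str(eff.pop("genotype")), str(eff.pop("age")))
        effects[key] = {k: float(v) for k, v in eff.items()}
    return CohortDesign(
        groups=groups,
        effects=effects,
        lfp=GammaLfpParams(**spec.get("lfp", {})),
        coupling=CouplingParams(**spec.get("coupling", {})),
        synaptic=SynapticTraceParams(**spec.get("synaptic", {})),
        master_seed=int(spec.get("master_seed", 0)),
    )
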