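"""End-to-end orchestration: read/simulate -> exclude -> average ->
classify -> prevalence and association tests -> report bundle.

A run is described by one :class:`PipelineConfig` (loadable from YAML).
Every stage's counts reconcile: parsed = analyzed + excluded, and the
mutually exclusive person categories partition the analyzed set.  A run
writes its full resolved configuration, package version and seed next to
its outputs, so a bundle is reproducible from its own directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .classify import RefractiveCriteria, classify_frame, CATEGORIES
from .cohort_io import (ExclusionReport, MeasurementLimits, ParseReport,
                        apply_exclusions, average_frame, characterize_sample,
                        read_cohort, records_to_frame, write_cohort)
from .simulate import CohortTable, SimulationConfig, simulate_cohort
from .stats import StratifiedResult, round_half_up, stratified_prevalence, prevalence

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("anisoprev")

STRATIFIERS = ("gender", "residence", "cycle")
OUTCOMES = {"is_ta": "TA", "has_sa": "SA", "has_ma": "MA"}


@dataclass
class PipelineConfig:
    """One structured configuration for a full run.

    Either ``input_csv`` names a cohort file, or ``simulate`` configures a
    synthetic cohort (then ``seed`` drives it).  ``criteria`` overrides
    threshold fields of the instrument-default profile; ``limits``
    overrides the instrument measurement range.
    """

    input_csv: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    seed: int = 0
    criteria: RefractiveCriteria = field(default_factory=RefractiveCriteria)
    limits: MeasurementLimits = field(default_factory=MeasurementLimits)
    ci_method: str = "wilson"
    min_replicates: int = 3
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file with the documented
    keys (``input_csv``, ``simulate``, ``seed``, ``criteria``, ``limits``,
    ``ci_method``, ``min_replicates``, ``out_dir``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    crit = RefractiveCriteria(**raw.pop("criteria", {}))
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim.pop("criteria", None)
        sim = SimulationConfig(criteria=crit, **sim)
    limits = MeasurementLimits(**raw.pop("limits", {}))
    return PipelineConfig(criteria=crit, simulate=sim, limits=limits, **raw)


@dataclass
class PipelineResult:
    """Everything one run produced, as tidy frames."""

    labeled: pd.DataFrame
    parse_report: Optional[ParseReport]
    exclusions: ExclusionReport
    sample: pd.DataFrame
    estimates: pd.DataFrame
    tests: pd.DataFrame
    category_counts: Dict[str, int]
    config: PipelineConfig
    truth: Optional[pd.DataFrame] = None

    @property
    def n_analyzed(self) -> int:
        return len(self.labeled)

    def summary_lines(self) -> List[str]:
        n = self.n_analyzed
        lines = [f"analyzed participants: {n}",
                 f"excluded: {self.exclusions.n_excluded} "
                 f"(missing_eye {len(self.exclusions.missing_eye)}, "
                 f"insufficient {len(self.exclusions.insufficient_replicates)}, "
                 f"out_of_range {len(self.exclusions.out_of_range)})"]
        if n == 0:
            return lines
        for cat in CATEGORIES:
            k = self.category_counts.get(cat, 0)
            lines.append(f"{cat}: {k} ({round_half_up(100 * k / n, 1)}%)")
        ta = int(self.labeled["is_ta"].sum())
        sa = int(self.labeled["has_sa"].sum())
        sma = int(self.labeled["is_sma"].sum())
        ma = int(self.labeled["has_ma"].sum())
        lines.append(f"total anisometropia: {ta} "
                     f"({round_half_up(100 * ta / n, 1)}%) = "
                     f"{sa} SA + {sma} sMA; MA: {ma}")
        if ta:
            for typ in ("myopic", "hyperopic", "sMA", "antimetropic"):
                k = int((self.labeled["aniso_type"] == typ).sum())
                lines.append(f"  type {typ}: {k} "
                             f"({round_half_up(100 * k / ta, 0):.0f}%)")
            for sev in ("low", "high", "very_high"):
                k = int((self.labeled["severity"] == sev).sum())
                lines.append(f"  severity {sev}: {k} "
                             f"({round_half_up(100 * k / ta, 1)}%)")
        lines.append("note: p-values are unadjusted for multiple testing")
        return lines


def _analysis_tables(labeled: pd.DataFrame, ci_method: str
                     ) -> (pd.DataFrame, pd.DataFrame):
    est_rows, test_rows = [], []
    n = len(labeled)
    for col, name in OUTCOMES.items():
        if n:
            overall = prevalence(int(labeled[col].sum()), n, ci_method=ci_method)
            est_rows.append({"outcome": name, "factor": "overall",
                             "stratum": "overall", "k": overall.numerator,
                             "n": n, "pct": overall.pct(1),
                             "ci_lo": overall.ci_low, "ci_hi": overall.ci_high})
        for factor in STRATIFIERS:
            if factor not in labeled.columns or n == 0:
                continue
            present = labeled[labeled[factor].astype(str) != "missing"]
            if present.empty or present[factor].nunique() < 2:
                continue
            res: StratifiedResult = stratified_prevalence(
                present, col, factor, ci_method=ci_method)
            for e in res.estimates:
                est_rows.append({"outcome": name, "factor": factor,
                                 "stratum": e.stratum, "k": e.numerator,
                                 "n": e.denominator, "pct": e.pct(1),
                                 "ci_lo": e.ci_low, "ci_hi": e.ci_high})
            if res.association is not None:
                a = res.association
                test_rows.append({"outcome": name, "factor": factor,
                                  "statistic": a.statistic, "df": a.df,
                                  "p": a.p_value,
                                  "significant": a.significant})
    estimates = pd.DataFrame(
        est_rows, columns=["outcome", "factor", "stratum", "k", "n", "pct",
                           "ci_lo", "ci_hi"])
    tests = pd.DataFrame(
        test_rows, columns=["outcome", "factor", "statistic", "df", "p",
                            "significant"])
    return estimates, tests


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute a full run and (optionally) write the output bundle.

    Outputs, when ``config.out_dir`` is set: ``cohort.csv`` (simulated runs
    only) with ``truth.csv`` sidecar, ``labeled.csv``, ``exclusions.csv``,
    ``sample.csv``, ``estimates.csv``, ``tests.csv``, ``summary.txt`` and
    ``run.json`` (config echo, seed, version, stage counts).
    """
    parse_report: Optional[ParseReport] = None
    truth = None
    if config.input_csv is not None:
        records, parse_report = read_cohort(config.input_csv)
    elif config.simulate is not None:
        cohort: CohortTable = simulate_cohort(config.simulate, config.seed)
        truth = cohort.truth
        frame = cohort.data
        records, parse_report = _frame_to_records(frame)
    else:
        raise ValueError("config must name input_csv or a simulate block")

    analyzed, exclusions = apply_exclusions(
        records, config.limits, config.min_replicates)
    frame = records_to_frame(analyzed)
    averaged = average_frame(frame, config.min_replicates)
    labeled = classify_frame(averaged, config.criteria) if len(averaged) else \
        averaged.assign(**{c: pd.Series(dtype=object) for c in
                           ("category", "aniso_type", "severity")},
                        **{c: pd.Series(dtype=bool) for c in
                           ("is_ta", "has_sa", "has_ma", "is_sma",
                            "compound_astigmat")})
    sample = characterize_sample(labeled)
    estimates, tests = _analysis_tables(labeled, config.ci_method)
    counts = ({cat: int((labeled["category"] == cat).sum())
               for cat in CATEGORIES} if len(labeled) else
              {cat: 0 for cat in CATEGORIES})

    result = PipelineResult(
        labeled=labeled, parse_report=parse_report, exclusions=exclusions,
        sample=sample, estimates=estimates, tests=tests,
        category_counts=counts, config=config, truth=truth)

    if config.out_dir:
        _write_bundle(result, records_frame=frame)
    return result


def _frame_to_records(frame: pd.DataFrame):
    import io as _io

    buf = _io.StringIO()
    write_cohort(frame, buf)
    buf.seek(0)
    return read_cohort(buf)


def _write_bundle(result: PipelineResult, records_frame: pd.DataFrame) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.truth is not None:
        write_cohort(records_frame, out / "cohort.csv")
        result.truth.to_csv(out / "truth.csv", index=False,
                            float_format="%.6g", lineterminator="\n")
    result.labeled.to_csv(out / "labeled.csv", index=False,
                          float_format="%.6g", lineterminator="\n")
    result.exclusions.to_frame().to_csv(out / "exclusions.csv", index=False,
                                        lineterminator="\n")
    result.sample.to_csv(out / "sample.csv", index=False, lineterminator="\n")
    result.estimates.to_csv(out / "estimates.csv", index=False,
                            float_format="%.6g", lineterminator="\n")
    result.tests.to_csv(out / "tests.csv", index=False, float_format="%.6g",
                        lineterminator="\n")
    (out / "summary.txt").write_text("\n".join(result.summary_lines()) + "\n")
    run_info = {
        "version": __version__,
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "n_analyzed": result.n_analyzed,
        "n_excluded": result.exclusions.n_excluded,
        "category_counts": result.category_counts,
    }
    (out / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True)
                                  + "\n")
    log.info("bundle written to %s", out)
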