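"""Pipeline execution and report writers.

``run_pipeline`` ties the three analyses together: it resolves a strict
run configuration into domain objects, obtains a participant-level cohort
(simulated or read from delimited text), and writes one delimited table
per analysis output plus a machine-readable ``results.json``.  Outputs
carry no timestamps, so a fixed configuration regenerates byte-identical
files; only the cohort-derived tables respond to the seed — the
break-even tables are cohort-independent.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .money import fmt_money, money, round_cents
from . import breakeven as be
from . import cba as cba_mod
from . import cea as cea_mod
from .config import (
    RunConfig,
    build_breakeven_scenario,
    build_cba_scenarios,
    build_cea_scenarios,
    build_cohort_spec,
    build_cost_structure,
    build_time_profile,
    build_wage_policy,
)
from .cost_model import FACE_TO_FACE, WEB, MODES
from .synthetic_cohort import (
    COLUMNS,
    generate_cohort,
    summarize_cohort,
    validate_schema,
)

log = logging.getLogger("eduecon")


class ParticipantTableError(ValueError):
    """Raised when participant-table rows fail to parse.

    ``errors`` maps 1-based file line numbers to messages; ``table``
    holds the rows that did parse.
    """

    def __init__(self, errors, table):
        self.errors = dict(errors)
        self.table = table
        lines = "; ".join(f"line {k}: {v}" for k, v in sorted(self.errors.items()))
        super().__init__(f"malformed participant rows — {lines}")


_MISSING_TOKENS = {"", "NA", "NaN", "nan", None}


def read_participant_table(path, on_error: str = "raise") -> pd.DataFrame:
    """Read a delimited participant table with typed columns.

    Expected header: ``id, arm, completed, grade, wtp_c1..wtp_c4,
    satisfaction``.  Empty strings and ``NA`` map to missing.  Malformed
    rows are reported with their 1-based file line numbers; with
    ``on_error="collect"`` the valid rows are returned and errors logged
    instead of raised.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValueError(f"participant table lacks columns: {sorted(missing_cols)}")

    def parse_float(token, field):
        if token in _MISSING_TOKENS:
            return np.nan
        return float(token)

    rows, errors = [], {}
    for idx, row in raw.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            arm = row["arm"]
            if arm not in MODES:
                raise ValueError(f"unknown arm label {arm!r}")
            completed_token = row["completed"].strip().lower()
            if completed_token in ("true", "1", "yes"):
                completed = True
            elif completed_token in ("false", "0", "no"):
                completed = False
            else:
                raise ValueError(f"bad completed flag {row['completed']!r}")
            parsed = {
                "id": row["id"],
                "arm": arm,
                "completed": completed,
                "grade": parse_float(row["grade"], "grade"),
            }
            for c in (1, 2, 3, 4):
                parsed[f"wtp_c{c}"] = parse_float(row[f"wtp_c{c}"], f"wtp_c{c}")
            parsed["satisfaction"] = parse_float(row["satisfaction"], "satisfaction")
            rows.append(parsed)
        except ValueError as exc:
            errors[line_no] = str(exc)
    table = pd.DataFrame(rows, columns=list(COLUMNS))
    if errors:
        if on_error == "raise":
            raise ParticipantTableError(errors, table)
        for line_no, msg in sorted(errors.items()):
            log.warning("skipping line %d: %s", line_no, msg)
    return table


def write_participant_table(table: pd.DataFrame, path) -> None:
    validate_schema(table)
    table.to_csv(path, index=False)


# Table writers --------------------------------------------------------------


def cost_structure_table(structures: dict) -> pd.DataFrame:
    rows = []
    for mode in MODES:
        s = structures[mode]
        for item in s.items:
            rows.append(
                {
                    "mode": mode,
                    "item": item.name,
                    "recurrence": item.recurrence,
                    "amount": fmt_money(item.amount),
                }
            )
        rows.append(
            {
                "mode": mode,
                "item": "total fixed",
                "recurrence": "per-class-fixed",
                "amount": fmt_money(s.fixed_total),
            }
        )
        rows.append(
            {
                "mode": mode,
                "item": "total variable",
                "recurrence": "per-participant-variable",
                "amount": fmt_money(s.variable_total),
            }
        )
    return pd.DataFrame(rows)


def breakeven_table(structure, cfg) -> pd.DataFrame:
    """Primary scenario plus every configured sweep, one row each.

    Segments are serialized in the "a–b; c–d" dialect; the rounded-ratio
    column carries the legacy single-class break-even number.
    """
    base = build_breakeven_scenario(structure, cfg)
    terms = be.FacilitatorTerms(
        hours=structure.facilitator_hours,
        rate=structure.facilitator_rate,
        other_fixed=structure.other_fixed,
    )
    rows = [
        {
            "scenario": "primary",
            "axis": "",
            "value": "",
            "segments": str(be.breakeven_segments(base)),
            "first_break_even": be.breakeven_segments(base).first_break_even,
            "rounded_ratio": be.breakeven_rounded_ratio(base),
        }
    ]
    for sweep in cfg.sweeps.get(structure.mode, []):
        for row in be.sensitivity_sweep(base, sweep.axis, sweep.values, terms):
            rows.append(
                {
                    "scenario": f"{row.axis}={row.value:g}",
                    "axis": row.axis,
                    "value": row.value,
                    "segments": str(row.segments),
                    "first_break_even": row.segments.first_break_even,
                    "rounded_ratio": row.rounded_ratio,
                }
            )
    return pd.DataFrame(rows)


def wtp_table(summary: dict) -> pd.DataFrame:
    rows = []
    for c in (1, 2, 3, 4):
        row = {"context": c}
        for arm, short in ((WEB, "web"), (FACE_TO_FACE, "f2f")):
            w = summary["arms"][arm]["wtp"][c]
            row[f"n_{short}"] = w["n"]
            row[f"mean_{short}"] = None if w["mean"] is None else round(w["mean"], 2)
            row[f"sd_{short}"] = None if w["sd"] is None else round(w["sd"], 2)
        rho = summary["wtp_satisfaction_rho"][c]
        row["spearman_rho"] = None if rho is None else round(rho["rho"], 2)
        row["rho_p_value"] = None if rho is None else round(rho["p_value"], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _class_qase_records(summary: dict, class_size: int) -> dict:
    """Scale cohort attrition and grades to one full class.

    Completers per class = round(class_size × completion rate); mean
    grade taken from the cohort summary (fraction).
    """
    records = {}
    for arm in MODES:
        s = summary["arms"][arm]
        n, completers = s["n_enrolled"], s["completers"]
        rate = completers / n if n else 0.0
        grade = (s["grade_mean"] or 0.0) / 100.0
        records[arm] = cea_mod.QASERecord(
            enrolled=class_size,
            completers=int(round(class_size * rate)),
            mean_grade=grade,
        )
    return records


def run_pipeline(config: RunConfig, out_dir=None, seed=None) -> dict:
    """Execute break-even → CEA → CBA and write the report bundle.

    Returns a dict with the output paths, the in-memory tables, and the
    machine-readable results document.  ``seed`` overrides the cohort
    seed (the break-even stage is cohort-independent and unaffected).
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    effective_seed = config.cohort.seed if (seed is None and config.cohort) else seed
    if effective_seed is None:
        effective_seed = config.seed
    log.info("run configuration resolved; seed=%s", effective_seed)

    policy = build_wage_policy(config.wage_policy)
    time_profile = build_time_profile(config.time_profile)
    structures = {
        mode: build_cost_structure(cfg)
        for mode, cfg in config.cost_structures.items()
    }

    tables = {}
    tables["cost_structures"] = cost_structure_table(structures)
    tables["breakeven_web"] = breakeven_table(structures[WEB], config.breakeven)
    tables["breakeven_f2f"] = breakeven_table(
        structures[FACE_TO_FACE], config.breakeven
    )

    # cohort: supplied or simulated
    if config.participant_table is not None:
        cohort = read_participant_table(config.participant_table)
    else:
        spec = build_cohort_spec(config.cohort, seed=effective_seed)
        cohort = generate_cohort(spec)
    summary = summarize_cohort(cohort)
    tables["cohort"] = cohort
    tables["wtp"] = wtp_table(summary)

    # CEA
    scenarios = build_cea_scenarios(config.cea, policy, time_profile)
    records = _class_qase_records(summary, config.cea.class_size)
    tables["cea"] = cea_mod.cea_sensitivity_table(
        records,
        scenarios,
        include_equal_attrition=config.cea.include_equal_attrition,
        alternative_fee_factor=config.cea.alternative_fee_factor,
    )

    # CBA
    context = config.cba.benefit_context
    benefits = {}
    for arm in MODES:
        w = summary["arms"][arm]["wtp"][context]
        benefits[arm] = money(w["mean"] if w["mean"] is not None else 0)
    cba_scenarios = build_cba_scenarios(config.cba)
    tables["cba"] = cba_mod.cba_sensitivity_table(
        cba_scenarios,
        fee=money(config.cba.fee),
        time_hours=time_profile.participant_hours(),
        policy=policy,
        benefits=benefits,
    )

    paths = {}
    file_map = {
        "cost_structures": "table_costs.csv",
        "breakeven_web": "table_breakeven_web.csv",
        "breakeven_f2f": "table_breakeven_f2f.csv",
        "cohort": "cohort.csv",
        "wtp": "table_wtp.csv",
        "cea": "table_cea.csv",
        "cba": "table_cba.csv",
    }
    for key, fname in file_map.items():
        path = out / fname
        tables[key].to_csv(path, index=False)
        paths[key] = path

    results = {
        "seed": effective_seed,
        "parameters": config.model_dump(),
        "breakeven": {
            mode: {
                "segments": str(
                    be.breakeven_segments(
                        build_breakeven_scenario(structures[mode], config.breakeven)
                    )
                ),
                "first_break_even": be.breakeven_segments(
                    build_breakeven_scenario(structures[mode], config.breakeven)
                ).first_break_even,
                "rounded_ratio": be.breakeven_rounded_ratio(
                    build_breakeven_scenario(structures[mode], config.breakeven)
                ),
            }
            for mode in MODES
        },
        "cohort_summary": summary,
        "cea": tables["cea"].to_dict(orient="records"),
        "cba": tables["cba"].to_dict(orient="records"),
    }
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=2, sort_keys=True, default=str))
    paths["results"] = results_path

    return {"paths": paths, "tables": tables, "results": results}
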