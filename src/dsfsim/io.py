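"""Readers and writers for run workbooks, plate maps and calibrations.

The instrument saves every run into a single workbook with one sheet of
(well, fluorescence) readings per temperature step, preceded by a
manifest sheet describing the schedule.  Two interchangeable dialects
are supported: an xlsx workbook (via openpyxl) and a plain-text
directory holding ``manifest.yaml`` plus one CSV per step, so analyses
can run without any spreadsheet tooling.  Plate maps and calibration
lines travel as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .analysis import CalibrationLine, ScreenReport
from .instrument import (
    DyeModel,
    PlateLayout,
    RawRun,
    Transition,
    UnfoldingModel,
    WellAssignment,
)
from .thermal import Schedule

__all__ = [
    "write_run_workbook",
    "read_run_workbook",
    "parse_plate_map",
    "expand_well_range",
    "write_calibration",
    "read_calibration",
    "write_report",
]

_MANIFEST_KEYS = ("start", "step", "ceiling", "dwell")


def _sheet_name(setpoint: float) -> str:
    return f"T_{setpoint:.1f}"


def write_run_workbook(run: RawRun, path: Union[str, Path]) -> Path:
    """Write a run in either dialect, chosen by the path suffix.

    ``.xlsx`` paths get a spreadsheet workbook (manifest sheet first,
    then one ``T_<setpoint>`` sheet per step); any other path becomes a
    directory with ``manifest.yaml`` and one CSV per step.
    """
    path = Path(path)
    wells = run.well_ids
    if len(wells) == 0:
        raise ValueError("run contains no wells")
    manifest = {
        "start": float(run.schedule.start),
        "step": float(run.schedule.step),
        "ceiling": float(run.schedule.ceiling),
        "dwell": float(run.schedule.dwell),
        "seed": run.metadata.get("seed"),
        "dyes": list(run.metadata.get("dyes", [])),
        "n_wells": len(wells),
    }
    tables = []
    for i_step, sp in enumerate(run.schedule.setpoints):
        sub = run.table[run.table["step"] == i_step].sort_values("well")
        tables.append((float(sp), sub[["well", "fluorescence"]].reset_index(drop=True)))

    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "manifest"
        for key, value in manifest.items():
            ws.append([key, ", ".join(map(str, value)) if isinstance(value, list) else value])
        for sp, table in tables:
            sheet = wb.create_sheet(_sheet_name(sp))
            sheet.append(["well", "fluorescence"])
            for _, row in table.iterrows():
                sheet.append([row["well"], float(row["fluorescence"])])
        wb.save(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        files = []
        for i_step, (sp, table) in enumerate(tables):
            fname = f"step_{i_step:02d}_{_sheet_name(sp)}.csv"
            table.to_csv(path / fname, index=False)
            files.append(fname)
        manifest["sheets"] = files
        with open(path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_run_workbook(path: Union[str, Path]) -> RawRun:
    """Read a run from either workbook dialect and validate it.

    Sheets must all carry the same well set; a mismatch is rejected with
    the offending sheet named.
    """
    path = Path(path)
    if path.is_dir():
        manifest_path = path / "manifest.yaml"
        if not manifest_path.exists():
            raise ValueError(f"missing manifest.yaml in {path}")
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        sheets = []
        for fname in manifest.get("sheets", []):
            table = pd.read_csv(path / fname)
            sheets.append((fname, table))
    elif path.suffix.lower() == ".xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        if "manifest" not in wb.sheetnames:
            raise ValueError(f"missing manifest sheet in {path}")
        manifest = {}
        for key, value in wb["manifest"].iter_rows(values_only=True):
            manifest[key] = value
        sheets = []
        for name in wb.sheetnames:
            if name == "manifest":
                continue
            rows = list(wb[name].iter_rows(values_only=True))
            table = pd.DataFrame(rows[1:], columns=list(rows[0]))
            sheets.append((name, table))
        wb.close()
    else:
        raise ValueError(f"unrecognised run path {path} (expected .xlsx or directory)")

    for key in _MANIFEST_KEYS:
        if key not in manifest or manifest[key] is None:
            raise ValueError(f"manifest missing schedule field {key!r}")
    schedule = Schedule(
        start=float(manifest["start"]),
        step=float(manifest["step"]),
        ceiling=float(manifest["ceiling"]),
        dwell=float(manifest["dwell"]),
    )
    setpoints = schedule.setpoints
    if len(sheets) != len(setpoints):
        raise ValueError(
            f"workbook has {len(sheets)} data sheets but the schedule has {len(setpoints)} steps"
        )

    records = []
    reference_wells: Optional[frozenset] = None
    for i_step, (name, table) in enumerate(sheets):
        if not {"well", "fluorescence"}.issubset(table.columns):
            raise ValueError(f"sheet {name!r} lacks well/fluorescence columns")
        if table["well"].isna().any() or table["fluorescence"].isna().any():
            raise ValueError(f"sheet {name!r} has ragged/missing rows")
        wells = frozenset(table["well"])
        if len(wells) != len(table):
            raise ValueError(f"sheet {name!r} repeats a well")
        if reference_wells is None:
            reference_wells = wells
        elif wells != reference_wells:
            raise ValueError(f"sheet {name!r} has a different well set from the first sheet")
        for _, row in table.iterrows():
            records.append(
                (i_step, float(setpoints[i_step]), str(row["well"]), float(row["fluorescence"]))
            )
    table = pd.DataFrame(records, columns=["step", "setpoint", "well", "fluorescence"])
    metadata = {
        "seed": manifest.get("seed"),
        "dyes": manifest.get("dyes"),
        "n_wells": len(reference_wells or ()),
    }
    return RawRun(schedule=schedule, table=table, metadata=metadata)


def expand_well_range(spec: Union[str, list]) -> list[str]:
    """Expand a wells entry: list, single id, or same-row range "A1-A3"."""
    if isinstance(spec, list):
        out = []
        for item in spec:
            out.extend(expand_well_range(item))
        return out
    text = str(spec).strip()
    if "-" in text:
        lo, hi = (part.strip() for part in text.split("-", 1))
        if lo[0] != hi[0]:
            raise ValueError(f"well range {text!r} must stay within one row")
        row = lo[0]
        c0, c1 = int(lo[1:]), int(hi[1:])
        if c1 < c0:
            raise ValueError(f"well range {text!r} is reversed")
        return [f"{row}{c}" for c in range(c0, c1 + 1)]
    return [text]


_DYE_FACTORIES = {"SYPRO": DyeModel.sypro, "CPM": DyeModel.cpm, "FAD": DyeModel.fad}


def _parse_dye(block) -> DyeModel:
    if isinstance(block, str):
        block = {"kind": block}
    kind = str(block.get("kind", "")).upper()
    if kind not in _DYE_FACTORIES:
        raise ValueError(f"unknown dye kind {block.get('kind')!r}")
    overrides = {k: v for k, v in block.items() if k != "kind"}
    return _DYE_FACTORIES[kind](**overrides)


def _parse_unfolding(block) -> UnfoldingModel:
    if "transitions" in block:
        transitions = tuple(
            Transition(
                tm=float(tr["tm"]),
                slope_factor=float(tr.get("slope_factor", 1.5)),
                weight=float(tr.get("weight", 1.0 / len(block["transitions"]))),
            )
            for tr in block["transitions"]
        )
        return UnfoldingModel(transitions)
    if "stepwise" in block:
        sw = block["stepwise"]
        return UnfoldingModel.stepwise(
            tm=float(sw["tm"]),
            n=int(sw.get("n", 3)),
            spread=float(sw.get("spread", 4.0)),
            slope_factor=float(sw.get("slope_factor", 2.5)),
        )
    if "tm" in block:
        return UnfoldingModel.single(
            tm=float(block["tm"]), slope_factor=float(block.get("slope_factor", 1.5))
        )
    raise ValueError("unfolding block needs 'tm', 'transitions' or 'stepwise'")


def parse_plate_map(path: Union[str, Path]) -> PlateLayout:
    """Load a plate layout from a YAML plate-map file.

    Format: a top-level ``groups`` list; each group gives ``condition``,
    ``wells`` (list or same-row range), optional ``blank: true``,
    ``dye`` (kind or parameter block) and, for samples, an ``unfolding``
    block.  ``replicate_group`` defaults to the condition label.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError("plate map must contain a top-level 'groups' list")
    wells: dict[str, WellAssignment] = {}
    for group in doc["groups"]:
        condition = str(group["condition"])
        rep_group = str(group.get("replicate_group", condition))
        blank = bool(group.get("blank", False))
        dye = _parse_dye(group.get("dye", "SYPRO"))
        unfolding = None
        if "unfolding" in group and group["unfolding"] is not None:
            if blank:
                raise ValueError(f"blank group {condition!r} must not define unfolding parameters")
            unfolding = _parse_unfolding(group["unfolding"])
        assignment = WellAssignment(
            condition=condition,
            replicate_group=rep_group,
            blank=blank,
            dye=dye,
            unfolding=unfolding,
        )
        for well in expand_well_range(group["wells"]):
            if well in wells:
                raise ValueError(f"well {well} assigned twice in the plate map")
            wells[well] = assignment
    return PlateLayout(wells=wells)


def write_calibration(cal: CalibrationLine, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "slope": cal.slope,
                "intercept": cal.intercept,
                "slope_se": cal.slope_se,
                "intercept_se": cal.intercept_se,
                "resid_sd": cal.resid_sd,
            },
            fh,
            sort_keys=False,
        )
    return path


def read_calibration(path: Union[str, Path]) -> CalibrationLine:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CalibrationLine(
        slope=float(doc["slope"]),
        intercept=float(doc["intercept"]),
        slope_se=float(doc.get("slope_se", np.nan)),
        intercept_se=float(doc.get("intercept_se", np.nan)),
        resid_sd=float(doc.get("resid_sd", np.nan)),
    )


def write_report(report: ScreenReport, path: Union[str, Path]) -> Path:
    """Write a screening report as CSV."""
    path = Path(path)
    report.table.to_csv(path, index=False)
    return path
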