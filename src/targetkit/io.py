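"""CSV formats, pipeline configuration and the batch pipeline.

Two dose-response CSV dialects are understood (UTF-8, comma-separated,
'.' decimal):

raw lengths (one row per dish)
    ``group,dose_gy,dish,mean_length_mm,n_beans``
pre-normalized rates (one row per group and dose)
    ``group,dose_gy,rate_percent``

Percentages live only at the file/CLI boundary; everything internal is a
fraction. Machine outputs keep full precision; 3-significant-figure
rounding is applied only in display columns.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .doseresponse import (
    DoseResponseTable,
    FitResult,
    ModelComparison,
    compare_models,
    estimate_d37,
    normalize,
)
from .hitmodel import d37_to_volume
from .physics import DEFAULT_PHYSICS, TargetPhysics, round_sig
from .synthetic import generate, mung_bean_design

logger = logging.getLogger("targetkit")

RAW_COLUMNS = ["group", "dose_gy", "dish", "mean_length_mm", "n_beans"]
RATE_COLUMNS = ["group", "dose_gy", "rate_percent"]


class CsvFormatError(ValueError):
    """A dose-response CSV violates the dialect contract."""


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CsvFormatError(f"{path}: no records (empty file)") from None
    if frame.empty:
        raise CsvFormatError(f"{path}: no records")
    return frame


def _check_numeric(frame: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    for col in columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise CsvFormatError(
                f"{path}: line {bad[0] + 2}: non-numeric value "
                f"{frame.loc[bad[0], col]!r} in column {col!r}"
            )
        if frame[col].isna().any():
            line = int(frame.index[frame[col].isna()][0]) + 2
            raise CsvFormatError(f"{path}: line {line}: missing value in column {col!r}")
        frame[col] = numeric


def read_dose_response_csv(path) -> List[DoseResponseTable]:
    """Parse either dose-response dialect into per-group tables.

    Raw-dialect dishes are averaged per (group, dose) — a plain mean of
    dish means, with bean counts summed. Duplicate (group, dose, dish)
    rows, missing dose-0 controls, missing columns and non-numeric cells
    are rejected with file/line-addressed messages.
    """
    path = Path(path)
    frame = _read_frame(path)
    cols = list(frame.columns)
    if cols == RAW_COLUMNS:
        _check_numeric(frame, ["dose_gy", "dish", "mean_length_mm", "n_beans"], path)
        dup = frame.duplicated(subset=["group", "dose_gy", "dish"])
        if dup.any():
            line = int(frame.index[dup][0]) + 2
            raise CsvFormatError(f"{path}: line {line}: duplicate (group, dose, dish) row")
        tables = []
        for gid, sub in frame.groupby("group", sort=False):
            per_dose = sub.groupby("dose_gy", sort=True).agg(
                mean_length_mm=("mean_length_mm", "mean"), n_beans=("n_beans", "sum")
            )
            if 0.0 not in per_dose.index:
                raise CsvFormatError(f"{path}: group {gid!r} has no dose-0 control row")
            tables.append(
                DoseResponseTable(
                    group_id=str(gid),
                    doses=per_dose.index.to_numpy(),
                    mean_lengths=per_dose["mean_length_mm"].to_numpy(),
                    n_beans=per_dose["n_beans"].to_numpy(),
                )
            )
        return tables
    if cols == RATE_COLUMNS:
        _check_numeric(frame, ["dose_gy", "rate_percent"], path)
        dup = frame.duplicated(subset=["group", "dose_gy"])
        if dup.any():
            line = int(frame.index[dup][0]) + 2
            raise CsvFormatError(f"{path}: line {line}: duplicate (group, dose) row")
        tables = []
        for gid, sub in frame.groupby("group", sort=False):
            sub = sub.sort_values("dose_gy")
            if 0.0 not in sub["dose_gy"].to_numpy():
                raise CsvFormatError(f"{path}: group {gid!r} has no dose-0 control row")
            tables.append(
                DoseResponseTable(
                    group_id=str(gid),
                    doses=sub["dose_gy"].to_numpy(),
                    rates=sub["rate_percent"].to_numpy() / 100.0,
                )
            )
        return tables
    raise CsvFormatError(
        f"{path}: unrecognised header {cols}; expected {RAW_COLUMNS} or {RATE_COLUMNS}"
    )


def write_dose_response_csv(tables, path, dialect: str = "rate") -> Path:
    """Write tables (or a raw-dialect DataFrame) to one of the dialects."""
    path = Path(path)
    if isinstance(tables, pd.DataFrame):
        frame = tables[RAW_COLUMNS] if dialect == "raw" else tables[RATE_COLUMNS]
        frame.to_csv(path, index=False)
        return path
    rows = []
    for table in tables:
        if dialect == "rate":
            t = table if table.is_normalized else normalize(table)
            for d, r in zip(t.doses, t.rates):
                rows.append({"group": t.group_id, "dose_gy": d, "rate_percent": r * 100.0})
        elif dialect == "raw":
            if table.mean_lengths is None:
                raise CsvFormatError(
                    f"group {table.group_id!r} has no raw lengths to write"
                )
            n = table.n_beans if table.n_beans is not None else np.full(table.doses.size, 0)
            for i, (d, L) in enumerate(zip(table.doses, table.mean_lengths)):
                rows.append(
                    {
                        "group": table.group_id,
                        "dose_gy": d,
                        "dish": 0,
                        "mean_length_mm": L,
                        "n_beans": int(n[i]),
                    }
                )
        else:
            raise CsvFormatError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class D37Row:
    label: str
    exposure: str
    d37_gy: float
    diameter_nm: float  # full precision

    @property
    def diameter_nm_display(self) -> float:
        return round_sig(self.diameter_nm, 3)


@dataclass(frozen=True)
class D37Table:
    """Labelled D37 doses with their derived target diameters."""

    rows: Tuple[D37Row, ...]
    physics: TargetPhysics = DEFAULT_PHYSICS

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.rows],
                "exposure": [r.exposure for r in self.rows],
                "d37_gy": [r.d37_gy for r in self.rows],
                "diameter_nm": [
                    r.diameter_nm_display if display else r.diameter_nm for r in self.rows
                ],
            }
        )


def compute_d37_table(
    d37_inputs: Iterable, physics: TargetPhysics = DEFAULT_PHYSICS
) -> D37Table:
    """Attach sphere-equivalent diameters to (label, d37) pairs.

    Each input is ``(label, d37)`` or ``(label, exposure, d37)``; full
    precision is kept, display rounding happens in :meth:`D37Table.to_frame`.
    """
    rows = []
    for item in d37_inputs:
        if len(item) == 2:
            label, d37 = item
            exposure = ""
        else:
            label, exposure, d37 = item
        geometry = d37_to_volume(physics, float(d37))
        rows.append(
            D37Row(
                label=str(label),
                exposure=str(exposure),
                d37_gy=float(d37),
                diameter_nm=geometry.diameter_nm,
            )
        )
    return D37Table(rows=tuple(rows), physics=physics)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [f.group_id for f in fits],
            "d37_gy": [f.d37_gy for f in fits],
            "diameter_nm": [f.geometry.diameter_nm for f in fits],
            "method": [f.method for f in fits],
            "hits_tolerated": [f.hits_tolerated for f in fits],
            "extrapolated": [f.extrapolated for f in fits],
            "residual_ss": [f.residual_ss for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )


def comparisons_to_frame(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for k, fit in sorted(c.fits.items()):
            rows.append(
                {
                    "group": c.group_id,
                    "hits_tolerated": k,
                    "d37_gy": fit.d37_gy,
                    "residual_ss": fit.residual_ss,
                    "preferred": k == c.preferred_k,
                    "shoulder": c.shoulder,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

PIPELINE_DEFAULTS: Dict[str, object] = {
    "input": None,            # dose-response CSV; when absent, simulate
    "d37_inputs": None,       # optional label,d37_gy CSV for the diameter table
    "method": "loglinear_origin",
    "epsilon_j": DEFAULT_PHYSICS.epsilon_j,
    "rho_kg_m3": DEFAULT_PHYSICS.rho_kg_m3,
    "hits_tolerated": 0,
    "seed": 0,
    "noise_cv": 0.10,
    "dishes_per_dose": 1,
    "bean_length_sd_mm": 5.0,
    "outdir": "targetkit_out",
}


def load_pipeline_config(path) -> Dict[str, object]:
    """Read a flat key: value config file, filling documented defaults."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CsvFormatError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(PIPELINE_DEFAULTS)
    if unknown:
        raise CsvFormatError(f"{path}: unknown config keys {sorted(unknown)}")
    config = dict(PIPELINE_DEFAULTS)
    config.update(raw)
    config["_defaulted"] = sorted(set(PIPELINE_DEFAULTS) - set(raw))
    return config


def read_d37_inputs_csv(path) -> List[Tuple[str, str, float]]:
    """Read label[,exposure],d37_gy rows for :func:`compute_d37_table`."""
    path = Path(path)
    frame = _read_frame(path)
    if "label" not in frame.columns or "d37_gy" not in frame.columns:
        raise CsvFormatError(f"{path}: need columns label,d37_gy (optional exposure)")
    _check_numeric(frame, ["d37_gy"], path)
    exposure = frame["exposure"] if "exposure" in frame.columns else [""] * len(frame)
    return [
        (str(l), str(e), float(d))
        for l, e, d in zip(frame["label"], exposure, frame["d37_gy"])
    ]


def _setup_logging(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(fmt)
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config_path) -> int:
    """simulate/load -> normalize -> fit -> compare -> diameter table.

    Returns 0 on success; on the first failure, logs it, removes partial
    outputs and returns 1. Every active parameter (including defaulted
    ones) is logged.
    """
    written: List[Path] = []
    handler = None
    try:
        config = load_pipeline_config(config_path)
        outdir = Path(config["outdir"])
        outdir.mkdir(parents=True, exist_ok=True)
        handler = _setup_logging(outdir / "pipeline.log")
        for key in sorted(PIPELINE_DEFAULTS):
            origin = "default" if key in config["_defaulted"] else "config"
            logger.info("parameter %s = %r (%s)", key, config[key], origin)
        physics = TargetPhysics(
            epsilon_j=float(config["epsilon_j"]), rho_kg_m3=float(config["rho_kg_m3"])
        )
        method = str(config["method"])
        k = int(config["hits_tolerated"])
        seed = int(config["seed"])

        if config["input"]:
            logger.info("reading dose-response tables from %s", config["input"])
            tables = read_dose_response_csv(config["input"])
        else:
            logger.info("no input given: simulating the ten-group design (seed=%d)", seed)
            design = mung_bean_design(
                seed=seed,
                noise_cv=float(config["noise_cv"]),
                dishes_per_dose=int(config["dishes_per_dose"]),
                bean_length_sd_mm=float(config["bean_length_sd_mm"]),
                hits_tolerated=k,
            )
            tables = generate(design).to_tables()
        tables = [t if t.is_normalized else normalize(t) for t in tables]
        written.append(write_dose_response_csv(tables, outdir / "normalized.csv"))
        logger.info("wrote %s", written[-1])

        fits = [
            estimate_d37(t, method=method, hits_tolerated=k, physics=physics)
            for t in tables
        ]
        fits_path = outdir / "fits.csv"
        fits_to_frame(fits).to_csv(fits_path, index=False)
        written.append(fits_path)
        logger.info("wrote %s (method=%s, k=%d)", fits_path, method, k)

        comparisons = [compare_models(t, method=method, physics=physics) for t in tables]
        cmp_path = outdir / "comparison.csv"
        comparisons_to_frame(comparisons).to_csv(cmp_path, index=False)
        written.append(cmp_path)
        logger.info("wrote %s", cmp_path)

        d37_inputs = [(f.group_id, "", f.d37_gy) for f in fits]
        if config["d37_inputs"]:
            d37_inputs = read_d37_inputs_csv(config["d37_inputs"]) + d37_inputs
        table = compute_d37_table(d37_inputs, physics=physics)
        d37_path = outdir / "d37_table.csv"
        table.to_frame().to_csv(d37_path, index=False)
        written.append(d37_path)
        logger.info("wrote %s", d37_path)
        logger.info(
            "pipeline complete: epsilon=%g J, rho=%g kg/m^3, method=%s, seed=%d",
            physics.epsilon_j, physics.rho_kg_m3, method, seed,
        )
        return 0
    except Exception as exc:  # first addressable failure ends the run
        logger.error("pipeline failed: %s", exc)
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        return 1
    finally:
        if handler is not None:
            handler.close()
            logger.removeHandler(handler)
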