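"""File I/O: study tables, re-analysis reports, calibration grids, configs.

Study tables are plain CSV with a header (``study_id, n0[, n1], d_obs[, s]
[, peer_reviewed]``); unknown columns ride along as per-record metadata and
survive a round trip.  Lines starting with ``#`` are treated as comments, so
every CSV this package writes can embed its resolved configuration and seed
without breaking re-reads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import SimilarityInterval, ValidationError
from .meta import MetaReanalysisReport, MetaStudyRecord
from .simulation import BIN_LABELS, ISimDistribution, SimulationConfig

__all__ = [
    "MetaTableError",
    "read_meta_csv",
    "write_meta_csv",
    "write_report",
    "grid_to_frame",
    "write_grid",
    "load_config",
]

logger = logging.getLogger(__name__)

_MANDATORY = ("study_id", "n0", "d_obs")
_KNOWN = ("study_id", "n0", "n1", "d_obs", "s", "peer_reviewed")
_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


class MetaTableError(ValidationError):
    """A study table failed to parse or violated an invariant."""


def _parse_bool(value, line: int):
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise MetaTableError(f"line {line}: unparseable peer_reviewed value {value!r}")


def read_meta_csv(path: str | Path) -> list[MetaStudyRecord]:
    """Read a study table, validating structure and invariants.

    Raises :class:`MetaTableError` naming the offending column and data line
    (1-based, counting the header as line 1) on missing mandatory columns,
    non-numeric values, non-positive ``s``, or duplicate study ids.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise MetaTableError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    # data line numbers: header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2

    def numeric(column: str, kind=float, required=True):
        raw = df[column].astype("string").str.strip()
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna() & (raw != "")
        if bad.any():
            first = int(lines[bad.to_numpy()][0])
            raise MetaTableError(
                f"{path.name} line {first}: non-numeric {column} value "
                f"{raw[bad].iloc[0]!r}"
            )
        if required and (values.isna()).any():
            first = int(lines[values.isna().to_numpy()][0])
            raise MetaTableError(f"{path.name} line {first}: missing {column} value")
        return values.astype(float) if kind is float else values

    ids = df["study_id"].astype("string").str.strip()
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise MetaTableError(
            f"{path.name}: duplicate study_id value(s): {', '.join(dup.unique())}"
        )
    n0 = numeric("n0")
    d_obs = numeric("d_obs")
    n1 = numeric("n1", required=False) if "n1" in df.columns else None
    s = numeric("s", required=False) if "s" in df.columns else None
    extra_cols = [c for c in df.columns if c not in _KNOWN]

    records = []
    for i in range(len(df)):
        line = int(lines[i])
        s_i = 1.0 if s is None or pd.isna(s.iloc[i]) else float(s.iloc[i])
        pr = (
            _parse_bool(df["peer_reviewed"].iloc[i], line)
            if "peer_reviewed" in df.columns and pd.notna(df["peer_reviewed"].iloc[i])
            else True
        )
        try:
            records.append(
                MetaStudyRecord(
                    study_id=str(ids.iloc[i]),
                    n0=int(n0.iloc[i]),
                    n1=None if n1 is None or pd.isna(n1.iloc[i]) else int(n1.iloc[i]),
                    d_obs=float(d_obs.iloc[i]),
                    s=s_i,
                    peer_reviewed=pr,
                    extra={
                        c: df[c].iloc[i]
                        for c in extra_cols
                        if pd.notna(df[c].iloc[i])
                    },
                )
            )
        except ValidationError as err:
            raise MetaTableError(f"{path.name} line {line}: {err}") from err
    logger.info("read %d study records from %s", len(records), path)
    return records


def _records_frame(records: Sequence[MetaStudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "study_id": r.study_id,
            "n0": r.n0,
            "n1": r.n1,
            "d_obs": r.d_obs,
            "s": r.s,
            "peer_reviewed": r.peer_reviewed,
        }
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_meta_csv(
    records: Sequence[MetaStudyRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a study table; lossless under :func:`read_meta_csv`."""
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        _records_frame(records).to_csv(fh, index=False)


def _report_dict(report: MetaReanalysisReport) -> dict:
    return {
        "es_theo": report.es_theo,
        "si": {"lower": report.si.lower, "upper": report.si.upper},
        "n_studies": report.n_studies,
        "counts": report.counts,
        "percent": report.percent,
        "studies": [
            {
                "study_id": ev.record.study_id,
                "n0": ev.record.n0,
                "n1": ev.record.n1,
                "es_obs": ev.es_obs,
                "isim": ev.verdict.isim,
                "category": ev.verdict.category.value,
                "expected_coverage_percent": ev.expected_coverage_percent,
            }
            for ev in report.studies
        ],
    }


def write_report(
    report: MetaReanalysisReport,
    path: str | Path,
    fmt: str = "csv",
    config: SimulationConfig | None = None,
) -> None:
    """Write a re-analysis report as CSV (per-study rows + summary block) or JSON."""
    path = Path(path)
    payload = _report_dict(report)
    if config is not None:
        payload["config"] = _config_dict(config)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if fmt != "csv":
        raise ValidationError(f"unknown report format {fmt!r}")
    with path.open("w") as fh:
        fh.write(f"# es_theo={report.es_theo} si=[{report.si.lower},{report.si.upper}]\n")
        if config is not None:
            fh.write(f"# config={json.dumps(_config_dict(config))}\n")
        pd.DataFrame(payload["studies"]).to_csv(fh, index=False)
        fh.write("# summary\n")
        for key in ("opposite", "undefined", "outside_si", "inside_si"):
            fh.write(
                f"# {key},{report.counts[key]},{report.percent[key]}%\n"
            )


def grid_to_frame(distributions: Sequence[ISimDistribution]) -> pd.DataFrame:
    """Calibration grid as a table: one row per setting, the ten bins, coverage."""
    rows = []
    for dist in distributions:
        if dist.setting is None:
            raise ValidationError("grid rows must carry their StudySetting")
        row = {
            "m_theo": dist.setting.m_theo,
            "m_pop": dist.setting.m1_pop,
            "n": dist.setting.n0,
            "n1": dist.setting.n1,
        }
        row.update({label: round(dist.bin_percent[label], 2) for label in BIN_LABELS})
        row["si_coverage"] = round(dist.si_coverage_percent, 2)
        row["n_opposite"] = dist.n_opposite
        row["n_undefined"] = dist.n_undefined
        rows.append(row)
    return pd.DataFrame(rows)


def write_grid(
    distributions: Sequence[ISimDistribution],
    path: str | Path,
    fmt: str = "csv",
    config: SimulationConfig | None = None,
) -> None:
    """Write a calibration grid as CSV or JSON, embedding the run config."""
    path = Path(path)
    frame = grid_to_frame(distributions)
    if fmt == "json":
        payload = {"rows": frame.to_dict(orient="records")}
        if config is not None:
            payload["config"] = _config_dict(config)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        with path.open("w") as fh:
            if config is not None:
                fh.write(f"# config={json.dumps(_config_dict(config))}\n")
            frame.to_csv(fh, index=False)
    else:
        raise ValidationError(f"unknown grid format {fmt!r}")


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["si"] = {"lower": config.si.lower, "upper": config.si.upper}
    return d


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from YAML or JSON.

    Recognised keys: ``reps``, ``seed``, ``df_mode`` and ``si`` (either a
    two-element list or a ``{lower, upper}`` mapping).
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path.name}: config must be a mapping")
    kwargs = {}
    for key in ("reps", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "df_mode" in data:
        kwargs["df_mode"] = str(data["df_mode"])
    if "si" in data:
        si = data["si"]
        if isinstance(si, dict):
            kwargs["si"] = SimilarityInterval(float(si["lower"]), float(si["upper"]))
        else:
            lower, upper = si
            kwargs["si"] = SimilarityInterval(float(lower), float(upper))
    unknown = set(data) - {"reps", "seed", "df_mode", "si"}
    if unknown:
        raise ValidationError(f"{path.name}: unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)
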