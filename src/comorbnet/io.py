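"""File formats: discharge CSVs, code lists, and GraphML export.

Discharge dialects:

* wide — ``patient_id,sex,age_years,year,dx1..dx16`` (one row per admission);
* long — ``patient_id,sex,age_years,year,admission_id,code`` (one row per
  diagnosis, grouped into admissions by ``admission_id``).

Chronic list: one code per line, ``#`` comments.  Sex-specific list: CSV
with ``code,sex`` columns.  Malformed codes are logged (via the returned
counter), never silently dropped.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .cohort import DischargeRecord, is_valid_code, normalize_code

MAX_DX = 16
WIDE_COLUMNS = ["patient_id", "sex", "age_years", "year"] + [
    f"dx{i}" for i in range(1, MAX_DX + 1)
]
LONG_COLUMNS = ["patient_id", "sex", "age_years", "year", "admission_id", "code"]


def detect_dialect(path: str | Path) -> str:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if "admission_id" in header:
        return "long"
    if "dx1" in header:
        return "wide"
    raise ValueError(f"{path}: header matches neither the wide nor the long dialect")


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_records(
    path: str | Path, dialect: str | None = None
) -> tuple[list[DischargeRecord], int]:
    """Read a discharge CSV; returns (records, n_malformed_codes_dropped)."""
    dialect = dialect or detect_dialect(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    dropped = 0
    records: list[DischargeRecord] = []

    if dialect == "wide":
        _require_columns(df, ["patient_id", "sex", "age_years", "year", "dx1"], path)
        dx_cols = [c for c in df.columns if c.startswith("dx")]
        for row in df.itertuples(index=False):
            raw = [getattr(row, c) for c in dx_cols if getattr(row, c)]
            codes = []
            for c in raw:
                c = normalize_code(c)
                if is_valid_code(c):
                    codes.append(c)
                else:
                    dropped += 1
            if not codes:
                continue
            records.append(
                DischargeRecord(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    age_years=int(row.age_years),
                    year=int(row.year),
                    codes=tuple(codes),
                )
            )
    elif dialect == "long":
        _require_columns(df, LONG_COLUMNS, path)
        for (_, _), group in df.groupby(["patient_id", "admission_id"], sort=True):
            first = group.iloc[0]
            codes = []
            for c in group["code"]:
                c = normalize_code(c)
                if is_valid_code(c):
                    codes.append(c)
                else:
                    dropped += 1
            if not codes:
                continue
            records.append(
                DischargeRecord(
                    patient_id=first["patient_id"],
                    sex=first["sex"],
                    age_years=int(first["age_years"]),
                    year=int(first["year"]),
                    codes=tuple(codes),
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return records, dropped


def write_records(
    records: Iterable[DischargeRecord], path: str | Path, dialect: str = "wide"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "wide":
            writer.writerow(WIDE_COLUMNS)
            for r in records:
                dx = list(r.codes[:MAX_DX]) + [""] * (MAX_DX - min(len(r.codes), MAX_DX))
                writer.writerow([r.patient_id, r.sex, r.age_years, r.year] + dx)
        elif dialect == "long":
            writer.writerow(LONG_COLUMNS)
            for i, r in enumerate(records):
                for code in r.codes:
                    writer.writerow(
                        [r.patient_id, r.sex, r.age_years, r.year, f"A{i:08d}", code]
                    )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_chronic_list(path: str | Path) -> frozenset[str]:
    """One code per line; '#' starts a comment; blank lines ignored."""
    codes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        code = normalize_code(line)
        if not is_valid_code(code):
            raise ValueError(f"{path}: malformed code {line!r}")
        codes.add(code)
    return frozenset(codes)


def write_chronic_list(codes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(codes)) + "\n")


def read_sex_specific(path: str | Path) -> dict[str, str]:
    """CSV with columns code,sex (sex in {M, F})."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["code", "sex"], path)
    out = {}
    for row in df.itertuples(index=False):
        code = normalize_code(row.code)
        if not is_valid_code(code) or row.sex not in ("M", "F"):
            raise ValueError(f"{path}: malformed row {row!r}")
        out[code] = row.sex
    return out


def write_sex_specific(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "sex"])
        for code in sorted(mapping):
            writer.writerow([code, mapping[code]])


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export; list/dict edge metadata is serialized to strings."""
    g = nx.Graph(**{k: v for k, v in net.graph.items() if v is not None})
    for node, data in net.nodes(data=True):
        g.add_node(node, **{k: v for k, v in data.items()})
    for u, v, data in net.edges(data=True):
        clean = {}
        for k, val in data.items():
            if isinstance(val, (list, tuple)):
                clean[k] = "|".join(str(x) for x in val)
            elif isinstance(val, dict):
                clean[k] = "|".join(f"{a}:{b:.6g}" for a, b in sorted(val.items()))
            else:
                clean[k] = val
        g.add_edge(u, v, **clean)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, str(path))


__all__ = [
    "read_records",
    "write_records",
    "read_chronic_list",
    "write_chronic_list",
    "read_sex_specific",
    "write_sex_specific",
    "write_graphml",
    "detect_dialect",
    "WIDE_COLUMNS",
    "LONG_COLUMNS",
]
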