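"""Readers and writers for clone tables, configs, and result files.

The on-disk clone table is delimited text (CSV or TSV, autodetected by
extension) with header columns ``clone_id, timepoint_days, composition,
n_total, m_prog``.  A clone's syncytial composition is serialized as
``"k:count"`` pairs joined by ``";"`` with ascending k (e.g. ``"1:3;2:1"``
for three singles and one pair); an extinct clone has an empty composition
and ``n_total = 0``.  ``m_prog`` may be empty when unknown.  Lines starting
with ``#`` before the header carry JSON provenance (resolved config and
seed) and are ignored by the reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .observables import CloneObservation

__all__ = [
    "CloneTableError",
    "composition_to_str",
    "str_to_composition",
    "read_clone_table",
    "write_clone_table",
    "table_to_observations",
    "observations_to_table",
    "load_config",
]

_COLUMNS = ["clone_id", "timepoint_days", "composition", "n_total", "m_prog"]


class CloneTableError(ValueError):
    """A clone table failed validation; the message carries row numbers."""


def composition_to_str(composition: dict[int, int]) -> str:
    """Serialize a composition map to ``"k:count"`` pairs with ascending k."""
    return ";".join(f"{k}:{c}" for k, c in sorted(composition.items()) if c > 0)


def str_to_composition(text) -> dict[int, int]:
    """Parse the ``"k:count;..."`` composition dialect; empty means extinct."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return {}
    comp: dict[int, int] = {}
    for pair in str(text).split(";"):
        k_str, _, c_str = pair.partition(":")
        try:
            k, c = int(k_str), int(c_str)
        except ValueError as exc:
            raise CloneTableError(f"malformed composition entry {pair!r}") from exc
        if k < 1 or c < 0:
            raise CloneTableError(f"invalid composition entry {pair!r}")
        if k in comp:
            raise CloneTableError(f"duplicate length {k} in composition {text!r}")
        comp[k] = c
    return comp


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_clone_table(path) -> pd.DataFrame:
    """Read and validate a clone table; raise ``CloneTableError`` on bad rows."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype={
        "clone_id": str, "composition": str,
    })
    missing = [c for c in _COLUMNS if c not in df.columns and c != "m_prog"]
    if missing:
        raise CloneTableError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    if "m_prog" not in df.columns:
        df["m_prog"] = pd.NA
    errors = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            comp = str_to_composition(row.composition)
            n = sum(k * c for k, c in comp.items())
            if int(row.n_total) != n:
                errors.append(
                    f"row {row_no}: n_total={row.n_total} does not match "
                    f"composition sum {n}"
                )
            if float(row.timepoint_days) < 0:
                errors.append(f"row {row_no}: negative timepoint_days")
            if not pd.isna(row.m_prog) and int(row.m_prog) < 0:
                errors.append(f"row {row_no}: negative m_prog")
        except CloneTableError as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise CloneTableError(f"{path}: validation failed\n" + "\n".join(errors))
    df["timepoint_days"] = df["timepoint_days"].astype(float)
    df["n_total"] = df["n_total"].astype(int)
    df["m_prog"] = df["m_prog"].astype("Int64")
    df["composition"] = df["composition"].fillna("")
    return df[_COLUMNS]


def write_clone_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a clone table; optional provenance goes into ``#`` header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance is not None:
            fh.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def table_to_observations(df: pd.DataFrame) -> list[CloneObservation]:
    """Convert a validated clone table into ``CloneObservation`` records."""
    out = []
    for row in df.itertuples(index=False):
        out.append(CloneObservation(
            clone_id=str(row.clone_id),
            timepoint=float(row.timepoint_days),
            composition=str_to_composition(row.composition),
            n_total=int(row.n_total),
            m_prog=None if pd.isna(row.m_prog) else int(row.m_prog),
        ))
    return out


def observations_to_table(observations) -> pd.DataFrame:
    rows = [{
        "clone_id": o.clone_id,
        "timepoint_days": o.timepoint,
        "composition": composition_to_str(o.composition),
        "n_total": o.n_total,
        "m_prog": pd.NA if o.m_prog is None else o.m_prog,
    } for o in observations]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["m_prog"] = df["m_prog"].astype("Int64")
    return df


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a dict."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
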