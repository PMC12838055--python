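"""Readers and writers for term records, score matrices and lexicons.

File dialects: UTF-8, comma-separated, "." decimal, missing as empty
string. Term records travel as JSONL (one ``{"pid","term","category"}``
object per line) or long CSV; score matrices as wide CSV with a ``pid``
column plus one column per facet.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scoring import PERSONAL, AnchorLexicon, TermRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def write_term_records(records: Sequence[TermRecord], path: PathLike) -> None:
    """Write term records as JSONL (.jsonl) or long CSV (.csv) by extension."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {"pid": r.pid, "term": r.raw_term, "category": r.category},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pid", "term", "category"])
            for r in records:
                w.writerow([r.pid, r.raw_term, r.category])


def read_term_records(
    path: PathLike,
    fmt: Optional[str] = None,
    malformed_tolerance: int = 0,
) -> List[TermRecord]:
    """Read term records from JSONL or long CSV.

    ``category`` defaults to "personal" when absent. Malformed rows are
    counted and logged; exceeding ``malformed_tolerance`` is an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix == ".jsonl" else "csv"
    records: List[TermRecord] = []
    bad: List[int] = []

    if fmt == "jsonl":
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                records.append(
                    TermRecord(
                        pid=str(obj["pid"]),
                        raw_term=str(obj["term"]),
                        category=str(obj.get("category", PERSONAL)),
                    )
                )
            except (json.JSONDecodeError, KeyError):
                bad.append(lineno)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "pid" not in reader.fieldnames:
                raise ValueError("missing required column: pid")
            if "term" not in reader.fieldnames:
                raise ValueError("missing required column: term")
            for lineno, row in enumerate(reader, 2):
                pid, term = row.get("pid"), row.get("term")
                if not pid or term is None:
                    bad.append(lineno)
                    continue
                records.append(
                    TermRecord(
                        pid=pid,
                        raw_term=term,
                        category=row.get("category") or PERSONAL,
                    )
                )
    if bad:
        logger.warning("%d malformed rows at lines %s", len(bad), bad[:10])
        if len(bad) > malformed_tolerance:
            raise ValueError(
                f"{len(bad)} malformed rows (first at line {bad[0]}) exceed tolerance "
                f"{malformed_tolerance}"
            )
    return records


def write_scores_wide(
    scores: Union[pd.DataFrame, np.ndarray],
    path: PathLike,
    pids: Optional[Sequence[str]] = None,
    columns: Optional[Sequence[str]] = None,
) -> None:
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(np.asarray(scores), index=list(pids), columns=list(columns))
    scores.index.name = "pid"
    scores.to_csv(path, float_format="%.12g", na_rep="")


def read_scores_wide(path: PathLike) -> pd.DataFrame:
    """Wide person x facet score matrix; duplicate pids are an error."""
    df = pd.read_csv(path, dtype={0: str})
    pid_col = df.columns[0]
    if df[pid_col].duplicated().any():
        dups = df[pid_col][df[pid_col].duplicated()].tolist()
        raise ValueError(f"duplicate pids: {dups}")
    df = df.set_index(pid_col)
    df.index.name = "pid"
    out = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int((out.isna() & df.notna()).sum().sum())
    if n_bad:
        logger.warning("%d non-numeric cells coerced to missing", n_bad)
    return out


def write_scores_long(scores: pd.DataFrame, path: PathLike) -> None:
    long = scores.reset_index().melt(id_vars="pid", var_name="facet", value_name="value")
    long.to_csv(path, index=False, float_format="%.12g", na_rep="")


def write_lexicon(lexicon: AnchorLexicon, path: PathLike) -> None:
    obj = {
        "facets": lexicon.facets,
        "anchors": lexicon.anchors,
        "domain_map": lexicon.domain_map,
    }
    Path(path).write_text(json.dumps(obj, indent=2, ensure_ascii=False), encoding="utf-8")


def read_lexicon(path: PathLike) -> AnchorLexicon:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnchorLexicon(
        facets=list(obj["facets"]),
        anchors={k: list(v) for k, v in obj["anchors"].items()},
        domain_map=dict(obj["domain_map"]),
    )


def write_json(obj: Dict, path: PathLike) -> None:
    """Serialize a report dict to stable, rerun-identical JSON."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return {"index": list(o.index), "columns": list(o.columns), "data": o.values.tolist()}
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=default, ensure_ascii=False),
        encoding="utf-8",
    )
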