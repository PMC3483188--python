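"""Readers and writers for record, output, gold and bundle files.

Records come in as TSV/CSV rows of (record_id, associated term code,
free text); structured output, gold annotations and patient bundles are
JSON-lines.  Writing then reading any of these reproduces the in-memory
structures exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .cause_of_death import PatientBundle
from .pipeline import OutputItem, RecordOutput

__all__ = [
    "read_records",
    "write_outputs",
    "read_outputs",
    "read_gold",
    "write_gold",
    "read_bundles",
    "write_bundles_dicts",
]

PathLike = Union[str, Path]


def read_records(path: PathLike) -> list[tuple[str, Optional[str], str]]:
    """Read (record_id, associated_code, text) rows from TSV or CSV.

    The delimiter is taken from the file extension (.tsv → tab).  A header
    row with a ``record_id`` column is optional.
    """
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    rows: list[tuple[str, Optional[str], str]] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for i, row in enumerate(reader):
            if not row or all(not cell.strip() for cell in row):
                continue
            if i == 0 and row[0].strip().lower() == "record_id":
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: row {i + 1} has {len(row)} fields, need 3")
            rid, code, text = row[0].strip(), row[1].strip(), row[2]
            rows.append((rid, code or None, text))
    return rows


def _write_jsonl(path: PathLike, dicts: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for d in dicts:
            handle.write(json.dumps(d, sort_keys=True) + "\n")


def _read_jsonl(path: PathLike) -> Iterator[dict]:
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                yield json.loads(line)


def write_outputs(
    path: PathLike, outputs: Sequence[RecordOutput], fmt: str = "jsonl"
) -> None:
    if fmt == "jsonl":
        _write_jsonl(path, (o.to_dict() for o in outputs))
        return
    if fmt != "csv":
        raise ValueError(f"unknown output format {fmt!r}")
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["record_id", "mode", "kind", "value", "attribute", "negated",
             "dictionary", "term_text"]
        )
        for output in outputs:
            for item in output.items:
                value = item.value
                if isinstance(value, dict):
                    value = json.dumps(value, sort_keys=True)
                writer.writerow(
                    [output.record_id, output.mode, item.kind, value,
                     item.attribute or "", int(item.negated),
                     item.dictionary or "", item.term_text or ""]
                )


def read_outputs(path: PathLike) -> list[RecordOutput]:
    return [RecordOutput.from_dict(d) for d in _read_jsonl(path)]


def write_gold(path: PathLike, gold: dict[str, Sequence[OutputItem]]) -> None:
    _write_jsonl(
        path,
        (
            {"record_id": rid, "items": [item.to_dict() for item in items]}
            for rid, items in gold.items()
        ),
    )


def read_gold(path: PathLike) -> dict[str, list[OutputItem]]:
    return {
        d["record_id"]: [OutputItem.from_dict(i) for i in d.get("items", [])]
        for d in _read_jsonl(path)
    }


def read_bundles(path: PathLike) -> list[PatientBundle]:
    return [PatientBundle.from_dict(d) for d in _read_jsonl(path)]


def write_bundles_dicts(path: PathLike, bundles: Iterable[dict]) -> None:
    _write_jsonl(path, bundles)
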