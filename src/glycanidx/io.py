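"""Reading and writing glycoform distribution tables.

The on-disk long format is a UTF-8 comma-separated file with a header row
``condition_id,glycan,relative_abundance_percent``; the JSON form is a
document keyed by condition id.  Raw abundances round-trip bit-exactly:
floats are written with :func:`repr`, which Python's float parser inverts
losslessly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping

from .nomenclature import parse_species

__all__ = [
    "DISTRIBUTION_COLUMNS",
    "read_distributions_csv",
    "write_distributions_csv",
    "read_distributions_json",
    "write_distributions_json",
]

DISTRIBUTION_COLUMNS = ("condition_id", "glycan", "relative_abundance_percent")

RawDistributions = dict[str, dict[str, float]]


class TableFormatError(ValueError):
    """Raised on malformed distribution tables, with a row locator."""


def read_distributions_csv(path: str | Path) -> RawDistributions:
    """Read a long-format distribution CSV into {condition_id: {glycan: %}}.

    Glycan names are validated through the shorthand parser; duplicate
    (condition, glycan) rows and malformed values are rejected with the
    offending row number.
    """
    out: RawDistributions = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(DISTRIBUTION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            cid = row["condition_id"].strip()
            glycan = row["glycan"].strip()
            try:
                glycan = parse_species(glycan).name
            except ValueError as exc:
                raise TableFormatError(f"{path} row {i}: {exc}") from exc
            try:
                value = float(row["relative_abundance_percent"])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path} row {i}: bad abundance {row['relative_abundance_percent']!r}"
                ) from exc
            cond = out.setdefault(cid, {})
            if glycan in cond:
                raise TableFormatError(f"{path} row {i}: duplicate ({cid}, {glycan})")
            cond[glycan] = value
    return out


def write_distributions_csv(
    distributions: Mapping[str, Mapping[str, float]], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DISTRIBUTION_COLUMNS)
        for cid, table in distributions.items():
            for glycan, value in table.items():
                writer.writerow([cid, glycan, repr(float(value))])


def read_distributions_json(path: str | Path) -> RawDistributions:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return {
        str(cid): {parse_species(g).name: float(v) for g, v in table.items()}
        for cid, table in doc.items()
    }


def write_distributions_json(
    distributions: Mapping[str, Mapping[str, float]], path: str | Path
) -> None:
    doc = {cid: dict(table) for cid, table in distributions.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
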