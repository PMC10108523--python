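"""Generic sortable/filterable feature table backing the tabular view and
the SV inspector's list panel.

Display coordinates are 1-based inclusive (the field's table convention);
the conversion from internal 0-based half-open happens here and only here.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import FilterExpressionError, FormatError
from .features import Feature, VariantFeature
from .sv import SVEvent


@dataclass
class FeatureTable:
    header: list[str]
    rows: list[list]
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [None] * len(self.rows)
        for row in self.rows:
            if len(row) != len(self.header):
                raise FormatError("table row arity does not match header")

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        try:
            i = self.header.index(name)
        except ValueError:
            raise FilterExpressionError(f"unknown column {name!r}")
        return [row[i] for row in self.rows]


def _flatten_info(info: dict) -> dict[str, object]:
    out = {}
    for key, value in sorted(info.items()):
        if isinstance(value, (list, tuple)):
            value = ",".join(str(v) for v in value)
        out[f"info.{key}"] = value
    return out


def to_table(items: Sequence) -> FeatureTable:
    """Canonical table over a homogeneous list of features, variants, or
    SV events.  Start columns are 1-based for display."""
    if not items:
        return FeatureTable(
            header=["id", "refName", "start", "end", "type", "name"], rows=[]
        )
    kinds = {type(x) for x in items}
    if len(kinds) > 1:
        raise FormatError(f"to_table needs a homogeneous list, got {kinds}")
    item = items[0]
    info_keys: list[str] = []
    seen = set()
    if isinstance(item, (VariantFeature, SVEvent)):
        for x in items:
            for k in _flatten_info(x.info):
                if k not in seen:
                    seen.add(k)
                    info_keys.append(k)
        info_keys.sort()

    if isinstance(item, SVEvent):
        header = ["id", "refName", "start", "end", "mateRef", "matePos",
                  "type"] + info_keys
        rows = []
        for ev in items:
            info = _flatten_info(ev.info)
            mate_ref, mate_pos = (ev.end2 if ev.end2 else (None, None))
            rows.append([
                ev.id, ev.end1[0], ev.end1[1] + 1, ev.end1[1] + 1,
                mate_ref, mate_pos + 1 if mate_pos is not None else None,
                ev.kind,
            ] + [info.get(k) for k in info_keys])
        return FeatureTable(header=header, rows=rows, provenance=list(items))

    if isinstance(item, VariantFeature):
        header = ["id", "refName", "start", "end", "type", "name", "ref",
                  "alt", "qual", "filter"] + info_keys
        rows = []
        for v in items:
            info = _flatten_info(v.info)
            rows.append([
                v.uniqueId, v.refName, v.start + 1, v.end, v.type, v.name,
                v.ref, ",".join(v.alts), v.qual, v.filter,
            ] + [info.get(k) for k in info_keys])
        return FeatureTable(header=header, rows=rows, provenance=list(items))

    if isinstance(item, Feature):
        header = ["id", "refName", "start", "end", "type", "name", "strand"]
        rows = [
            [f.uniqueId, f.refName, f.start + 1, f.end, f.type, f.name, f.strand]
            for f in items
        ]
        return FeatureTable(header=header, rows=rows, provenance=list(items))

    raise FormatError(f"to_table cannot tabulate {type(item).__name__}")


def sort_table(table: FeatureTable, column: str, descending: bool = False
               ) -> FeatureTable:
    """Stable sort; numbers numeric, text lexicographic, missing always last."""
    try:
        ci = table.header.index(column)
    except ValueError:
        raise FilterExpressionError(f"unknown column {column!r}")
    indexed = list(enumerate(table.rows))
    present = [(i, r) for i, r in indexed if r[ci] is not None]
    missing = [(i, r) for i, r in indexed if r[ci] is None]
    numeric = all(isinstance(r[ci], (int, float)) for _, r in present)

    def key(pair):
        v = pair[1][ci]
        return v if numeric else str(v)

    ordered = sorted(present, key=key, reverse=descending) + missing
    return FeatureTable(
        header=list(table.header),
        rows=[r for _, r in ordered],
        provenance=[table.provenance[i] for i, _ in ordered],
    )


def to_delimited(table: FeatureTable, delimiter: str = "\t") -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(table.header)
    for row in table.rows:
        writer.writerow(["" if v is None else v for v in row])
    return buf.getvalue()


def write_table(table: FeatureTable, path: str) -> None:
    delimiter = "," if path.endswith(".csv") else "\t"
    with open(path, "w") as fh:
        fh.write(to_delimited(table, delimiter))
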