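"""Declarative config and session model plus locstring parsing.

The JSON config dialect is deliberately minimal and versioned through its
``formatVersion`` field: assemblies (FASTA + optional alias/cytoband files)
and tracks (id, type, source path, the assemblies they draw on).  A session
is an ordered list of views over those tracks.  Schema errors carry a
JSON-pointer-style location so a typo in track 3 says so.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError, LocstringError
from .genome import Assembly, Region

TRACK_TYPES = {"feature", "quantitative", "alignments", "variant", "synteny",
               "reference"}
VIEW_TYPES = {"linear", "dotplot", "circular", "synteny", "breakpoint",
              "sv-inspector"}
FORMAT_VERSION = 1


@dataclass
class AssemblySource:
    name: str
    fasta: str
    aliases: Optional[str] = None
    cytobands: Optional[str] = None

    def load(self) -> Assembly:
        return Assembly.from_fasta(self.fasta, name=self.name,
                                   aliases_path=self.aliases,
                                   cytoband_path=self.cytobands)


@dataclass
class TrackConfig:
    trackId: str
    type: str
    assemblyNames: list[str]
    path: str
    options: dict = field(default_factory=dict)


@dataclass
class View:
    viewType: str
    regions: list[str] = field(default_factory=list)  # locstrings per axis/panel
    tracks: list[str] = field(default_factory=list)
    options: dict = field(default_factory=dict)


@dataclass
class Session:
    views: list[View] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"views": [
            {"viewType": v.viewType, "regions": list(v.regions),
             "tracks": list(v.tracks), "options": dict(v.options)}
            for v in self.views
        ]}

    @classmethod
    def from_dict(cls, data: dict, where: str = "/defaultSession") -> "Session":
        views = []
        for i, raw in enumerate(_expect(data, "views", list, where)):
            loc = f"{where}/views/{i}"
            vtype = _expect(raw, "viewType", str, loc)
            if vtype not in VIEW_TYPES:
                raise ConfigError(f"{loc}/viewType: unknown view {vtype!r}")
            views.append(View(
                viewType=vtype,
                regions=list(raw.get("regions", [])),
                tracks=list(raw.get("tracks", [])),
                options=dict(raw.get("options", {})),
            ))
        return cls(views=views)


@dataclass
class Config:
    assemblies: list[AssemblySource]
    tracks: list[TrackConfig]
    defaultSession: Optional[Session] = None

    def assembly(self, name: str) -> AssemblySource:
        for a in self.assemblies:
            if a.name == name:
                return a
        raise ConfigError(f"unknown assembly {name!r}")

    def track(self, track_id: str) -> TrackConfig:
        for t in self.tracks:
            if t.trackId == track_id:
                return t
        raise ConfigError(f"unknown track {track_id!r}")


def _expect(obj: dict, key: str, kind, where: str):
    if key not in obj:
        raise ConfigError(f"{where}: missing required key {key!r}")
    value = obj[key]
    if not isinstance(value, kind):
        raise ConfigError(f"{where}/{key}: expected {kind.__name__}")
    return value


def load_config(path: str) -> Config:
    """Read and schema-validate a config JSON file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigError("/: config must be a JSON object")
    version = data.get("formatVersion", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise ConfigError(f"/formatVersion: unsupported version {version}")
    assemblies = []
    for i, raw in enumerate(_expect(data, "assemblies", list, "/")):
        where = f"/assemblies/{i}"
        assemblies.append(AssemblySource(
            name=_expect(raw, "name", str, where),
            fasta=_expect(raw, "fasta", str, where),
            aliases=raw.get("aliases"),
            cytobands=raw.get("cytobands"),
        ))
    names = [a.name for a in assemblies]
    for name in names:
        if names.count(name) > 1:
            raise ConfigError(f"/assemblies: duplicate assembly name {name!r}")
    tracks = []
    seen_ids: dict[str, int] = {}
    for i, raw in enumerate(data.get("tracks", [])):
        where = f"/tracks/{i}"
        tid = _expect(raw, "trackId", str, where)
        if tid in seen_ids:
            raise ConfigError(
                f"{where}/trackId: duplicate trackId {tid!r} "
                f"(also /tracks/{seen_ids[tid]})"
            )
        seen_ids[tid] = i
        ttype = _expect(raw, "type", str, where)
        if ttype not in TRACK_TYPES:
            raise ConfigError(f"{where}/type: unknown track type {ttype!r}")
        asm_names = _expect(raw, "assemblyNames", list, where)
        for name in asm_names:
            if name not in names:
                raise ConfigError(
                    f"{where}/assemblyNames: unknown assembly {name!r}")
        if ttype == "synteny" and len(asm_names) != 2:
            raise ConfigError(
                f"{where}/assemblyNames: synteny tracks name exactly two "
                f"assemblies, got {len(asm_names)}")
        if ttype != "synteny" and len(asm_names) != 1:
            raise ConfigError(
                f"{where}/assemblyNames: expected one assembly, got "
                f"{len(asm_names)}")
        tracks.append(TrackConfig(
            trackId=tid, type=ttype, assemblyNames=list(asm_names),
            path=_expect(raw, "path", str, where),
            options=dict(raw.get("options", {})),
        ))
    session = None
    if "defaultSession" in data:
        session = Session.from_dict(data["defaultSession"])
        known = set(seen_ids)
        for i, view in enumerate(session.views):
            for tid in view.tracks:
                if tid not in known:
                    raise ConfigError(
                        f"/defaultSession/views/{i}/tracks: unknown track "
                        f"{tid!r}")
    return Config(assemblies=assemblies, tracks=tracks, defaultSession=session)


def save_session(session: Session, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(session.to_dict(), fh, indent=2, sort_keys=True)


def load_session(path: str) -> Session:
    with open(path) as fh:
        return Session.from_dict(json.load(fh), where="/")


# ---------------------------------------------------------------------------
# locstrings

_LOC = re.compile(
    r"^(?P<ref>[^:\s]+)"
    r"(?::(?P<start>[\d,]+)(?:-|\.\.)(?P<end>[\d,]+))?"
    r"(?:\s*\[(?P<rev>rev)\])?$"
)


def parse_locstring(text: str, assembly: Assembly) -> Region:
    """Human location ('chr1:1,000-2,000', 'chr1:1000..2000', 'chr1', with
    optional '[rev]' suffix) to an internal 0-based half-open Region.

    Input coordinates are 1-based inclusive; commas are ignored; a bare
    refName means the whole sequence; aliases are resolved.
    """
    m = _LOC.match(text.strip())
    if m is None:
        raise LocstringError(f"cannot parse location {text!r}")
    refName = assembly.canonical(m.group("ref"))
    reverse = m.group("rev") is not None
    length = assembly.seq_length(refName)
    if m.group("start") is None:
        return Region(refName, 0, length, reversed=reverse)
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1 or start > end:
        raise LocstringError(
            f"{text!r}: start must satisfy 1 <= start <= end")
    if end > length:
        raise LocstringError(
            f"{text!r}: end {end} beyond {refName} length {length}")
    return Region(refName, start - 1, end, reversed=reverse)
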