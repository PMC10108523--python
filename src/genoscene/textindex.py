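"""Trix-style prefix index over feature names and descriptions.

The two-file layout follows the trix idea: ``.ix`` holds one sorted line per
term (``term docId,wordPos docId,wordPos ...``) and ``.ixx`` holds a sparse
offset table (the first 5 characters of every 64th term, right-padded, plus
the 10-digit lowercase-hex byte offset of that line) so a prefix search can
seek instead of scanning.  The dialect is self-defined and versioned via the
``# genoscene-trix 1`` comment heading the .ixx file; byte-compatibility
with other trix writers is not asserted.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import FormatError

log = logging.getLogger("genoscene.textindex")

IXX_STRIDE = 64
IXX_PREFIX_WIDTH = 5
IXX_HEADER = "# genoscene-trix 1\n"

_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass
class TrixIndex:
    """In-memory form: sorted unique lowercased terms with (docId, wordPos)
    hit lists, plus the sparse prefix/offset table of the serialized .ix."""

    ixLines: list[tuple[str, list[tuple[str, int]]]] = field(default_factory=list)
    ixxEntries: list[tuple[str, int]] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.ixLines]


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on any non-alphanumeric run."""
    return _TOKEN.findall(text.lower())


def serialize_ix(ixLines: Sequence[tuple[str, list[tuple[str, int]]]]) -> str:
    lines = []
    for term, hits in ixLines:
        lines.append(term + " " + " ".join(f"{d},{p}" for d, p in hits))
    return "\n".join(lines) + ("\n" if lines else "")


def _ixx_entries(ixLines) -> list[tuple[str, int]]:
    entries = []
    offset = 0
    for lineno, (term, hits) in enumerate(ixLines):
        if lineno % IXX_STRIDE == 0:
            entries.append((term[:IXX_PREFIX_WIDTH].ljust(IXX_PREFIX_WIDTH), offset))
        offset += len((term + " " + " ".join(f"{d},{p}" for d, p in hits) + "\n")
                      .encode())
    return entries


def build_index(docs: Iterable[tuple[str, str]]) -> TrixIndex:
    """Index (docId, text) pairs; docIds must contain no whitespace."""
    postings: dict[str, list[tuple[str, int]]] = {}
    for doc_id, text in docs:
        if re.search(r"\s", doc_id):
            raise FormatError(f"docId {doc_id!r} contains whitespace")
        for pos, token in enumerate(tokenize(text)):
            postings.setdefault(token, []).append((doc_id, pos))
    ix_lines = [
        (term, sorted(postings[term])) for term in sorted(postings)
    ]
    return TrixIndex(ixLines=ix_lines, ixxEntries=_ixx_entries(ix_lines))


def write_index(index: TrixIndex, prefix_path: str) -> tuple[str, str]:
    """Write ``<prefix>.ix`` and ``<prefix>.ixx``; returns both paths."""
    ix_path, ixx_path = prefix_path + ".ix", prefix_path + ".ixx"
    with open(ix_path, "w") as fh:
        fh.write(serialize_ix(index.ixLines))
    with open(ixx_path, "w") as fh:
        fh.write(IXX_HEADER)
        for pfx, offset in index.ixxEntries:
            fh.write(f"{pfx}{offset:010x}\n")
    return ix_path, ixx_path


def read_ixx(ixx_path: str) -> list[tuple[str, int]]:
    entries = []
    with open(ixx_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            entries.append((line[:IXX_PREFIX_WIDTH], int(line[IXX_PREFIX_WIDTH:], 16)))
    return entries


def search(index: TrixIndex, prefix: str, limit: Optional[int] = None
           ) -> list[str]:
    """docIds whose indexed text contains a term starting with ``prefix``.

    Exact-term matches come first, then proper prefix matches; each group is
    sorted by docId and de-duplicated.
    """
    if not prefix:
        raise FormatError("search prefix must be non-empty")
    needle = prefix.lower()
    terms = index.terms
    lo = bisect.bisect_left(terms, needle)
    exact: list[str] = []
    rest: list[str] = []
    for term, hits in index.ixLines[lo:]:
        if not term.startswith(needle):
            break
        bucket = exact if term == needle else rest
        bucket.extend(d for d, _ in hits)
    seen: set[str] = set()
    out: list[str] = []
    for doc in sorted(set(exact)) + sorted(set(rest)):
        if doc not in seen:
            seen.add(doc)
            out.append(doc)
    return out[:limit] if limit is not None else out


def search_files(ix_path: str, ixx_path: str, prefix: str,
                 limit: Optional[int] = None) -> list[str]:
    """File-backed search: binary-search the .ixx, seek into the .ix, scan."""
    if not prefix:
        raise FormatError("search prefix must be non-empty")
    needle = prefix.lower()
    entries = read_ixx(ixx_path)
    offset = 0
    key = needle[:IXX_PREFIX_WIDTH].ljust(IXX_PREFIX_WIDTH)
    prefixes = [p for p, _ in entries]
    # the first term with this prefix may precede the first stride entry
    # bearing it, so start from the last entry strictly before the key
    i = bisect.bisect_left(prefixes, key) - 1
    if i >= 0:
        offset = entries[i][1]
    exact: list[str] = []
    rest: list[str] = []
    with open(ix_path, "rb") as fh:
        fh.seek(offset)
        for raw in fh:
            line = raw.decode().rstrip("\n")
            if not line:
                continue
            term, _, hits = line.partition(" ")
            if term.startswith(needle):
                docs = [h.split(",")[0] for h in hits.split()]
                (exact if term == needle else rest).extend(docs)
            elif term > needle:
                break
    seen: set[str] = set()
    out: list[str] = []
    for doc in sorted(set(exact)) + sorted(set(rest)):
        if doc not in seen:
            seen.add(doc)
            out.append(doc)
    return out[:limit] if limit is not None else out


# ---------------------------------------------------------------------------
# track indexing

DEFAULT_FIELDS = ("Name", "ID", "description", "Note", "Alias", "gene_name")


def _docs_from_gff3(path: str, track_id: str, fields: Sequence[str]):
    from .features import read_features

    for feat in read_features(path, format="gff3"):
        for node in feat.walk():
            texts = []
            for key in fields:
                if key == "Name" and node.name:
                    texts.append(node.name)
                elif key == "ID":
                    texts.append(node.uniqueId)
                else:
                    texts.extend(node.attributes.get(key, []))
            if not texts:
                continue
            display = node.name or node.uniqueId
            doc_id = (f"{node.refName}:{node.start + 1}-{node.end}"
                      f"|{track_id}|{display}").replace(" ", "_")
            yield doc_id, " ".join(texts)


def _docs_from_vcf(path: str, track_id: str, fields: Sequence[str]):
    from .features import read_variants

    for v in read_variants(path):
        texts = []
        if v.name:
            texts.append(v.name)
        for key in fields:
            value = v.info.get(key)
            if value is not None:
                texts.append(str(value))
        if not texts:
            continue
        display = v.name or v.uniqueId
        doc_id = (f"{v.refName}:{v.start + 1}-{v.end}"
                  f"|{track_id}|{display}").replace(" ", "_")
        yield doc_id, " ".join(texts)


def index_tracks(
    trackFiles: Sequence[tuple[str, str]],
    fields: Sequence[str] = DEFAULT_FIELDS,
    aggregate: bool = False,
):
    """Index (trackId, path) GFF3/VCF pairs.

    docIds encode ``refName:start-end|trackId|displayName`` (1-based display
    coordinates) so a hit decodes straight back to a location.  Returns one
    aggregate TrixIndex, or a dict of per-track indexes.
    """
    per_track: dict[str, list[tuple[str, str]]] = {}
    for track_id, path in trackFiles:
        lowered = path.lower()
        if lowered.endswith((".vcf", ".vcf.gz")):
            docs = list(_docs_from_vcf(path, track_id, fields))
        elif lowered.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
            docs = list(_docs_from_gff3(path, track_id, fields))
        else:
            raise FormatError(f"cannot index {path!r}: not GFF3 or VCF")
        per_track[track_id] = docs
    if aggregate:
        merged: list[tuple[str, str]] = []
        for track_id in per_track:
            merged.extend(per_track[track_id])
        return build_index(merged)
    return {tid: build_index(docs) for tid, docs in per_track.items()}


def decode_doc_id(doc_id: str) -> dict:
    """Split a docId back into location, trackId, and display name."""
    loc, track_id, display = doc_id.split("|", 2)
    ref, _, span = loc.partition(":")
    start, _, end = span.partition("-")
    return {
        "refName": ref,
        "start": int(start) - 1,
        "end": int(end),
        "trackId": track_id,
        "name": display,
    }
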