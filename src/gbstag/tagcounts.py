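"""Collapse FASTQ files into tag-count tables and build the master tag list.

Rather than aligning every read, the pipeline first collapses all reads
into unique (sequence, length) tags with occurrence counts — one table per
FASTQ file — then merges the tables into a single master list keeping only
tags seen at least ``min_count`` times across the whole experiment.  Tag
recurrence substitutes for base-quality filtering: a tag observed many
times is unlikely to be pure sequencing error.  The master list is exported
as FASTQ (with uniform fake qualities) for alignment by an external aligner.
"""

from __future__ import annotations

import heapq
import struct
import zlib
from dataclasses import dataclass, field

from .seqcore import (
    DEFAULT_MIN_TAG_LENGTH,
    MAX_TAG_LENGTH,
    BarcodeKey,
    EnzymeModel,
    LaneClassifier,
    ReadStatus,
    Tag,
    encode_sequence,
    iter_fastq,
    write_fastq,
    _open_text,
)

_MAGIC = b"GBTC"
_VERSION = 1
_REC = struct.Struct(">16sBQ")  # packed bases, length, count


@dataclass
class ReadReport:
    """Accounting of one classification pass over a FASTQ file."""

    total: int = 0
    good: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    chimera_trimmed: int = 0
    per_taxon_good: dict[str, int] = field(default_factory=dict)

    def record(self, status: ReadStatus, taxon: str | None, chimera: bool) -> None:
        self.total += 1
        if status is ReadStatus.GOOD:
            self.good += 1
            self.per_taxon_good[taxon] = self.per_taxon_good.get(taxon, 0) + 1
        else:
            self.rejected[status.value] = self.rejected.get(status.value, 0) + 1
        if chimera:
            self.chimera_trimmed += 1


class TagCountTable:
    """Sorted map Tag -> count, with provenance.

    Iteration is always in the Tag total order, so tables can be merged as
    sorted streams.
    """

    def __init__(self, counts: dict[Tag, int] | None = None, source: str = ""):
        self.source = source
        self._counts: dict[Tag, int] = {}
        if counts:
            for tag, c in counts.items():
                if c < 1:
                    raise ValueError("tag counts must be >= 1")
                self._counts[tag] = int(c)

    def add(self, tag: Tag, n: int = 1) -> None:
        self._counts[tag] = self._counts.get(tag, 0) + n

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, tag: Tag) -> bool:
        return tag in self._counts

    def __getitem__(self, tag: Tag) -> int:
        return self._counts[tag]

    def get(self, tag: Tag, default: int = 0) -> int:
        return self._counts.get(tag, default)

    def items(self) -> list[tuple[Tag, int]]:
        return sorted(self._counts.items())

    def tags(self) -> list[Tag]:
        return sorted(self._counts)

    def total_count(self) -> int:
        return sum(self._counts.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, TagCountTable) and self._counts == other._counts


class MasterTagList(TagCountTable):
    """Experiment-wide tag list: merged counts filtered at ``min_count``."""

    def __init__(self, counts: dict[Tag, int], min_count: int, source: str = "merged"):
        super().__init__(counts, source=source)
        if any(c < min_count for c in counts.values()):
            raise ValueError("master list contains counts below min_count")
        self.min_count = min_count
        self._order: list[Tag] | None = None

    def index(self) -> dict[Tag, int]:
        """Tag -> rank in sorted order (the canonical tag index)."""
        return {t: i for i, t in enumerate(self.tags())}


def count_tags(
    fastq,
    key: BarcodeKey,
    enzyme: EnzymeModel,
    flowcell: str,
    lane: str,
    trim_length: int = MAX_TAG_LENGTH,
    min_tag_length: int = DEFAULT_MIN_TAG_LENGTH,
    require_remnant: bool = True,
) -> tuple[TagCountTable, ReadReport]:
    """Tally GOOD-read tags from one FASTQ file."""
    clf = LaneClassifier(
        key.lane_entries(flowcell, lane), enzyme,
        trim_length=trim_length, min_tag_length=min_tag_length,
        require_remnant=require_remnant,
    )
    table = TagCountTable(source=str(fastq))
    report = ReadReport()
    for _rid, seq in iter_fastq(fastq):
        c = clf.classify(seq)
        report.record(c.status, c.taxon, c.chimera_trimmed)
        if c.status is ReadStatus.GOOD:
            table.add(c.tag)
    return table, report


def merge_tag_counts(tables: list[TagCountTable], min_count: int = 5) -> MasterTagList:
    """k-way merge of sorted tables; drop tags below the experiment minimum."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    merged: dict[Tag, int] = {}
    current: Tag | None = None
    acc = 0
    for tag, c in heapq.merge(*(t.items() for t in tables)):
        if tag == current:
            acc += c
        else:
            if current is not None and acc >= min_count:
                merged[current] = acc
            current, acc = tag, c
    if current is not None and acc >= min_count:
        merged[current] = acc
    return MasterTagList(merged, min_count=min_count)


def export_master_fastq(master: MasterTagList, path, quality_char: str = "I") -> None:
    """Write the master list as FASTQ for an external aligner.

    Record IDs encode the tag's index in the sorted master order and its
    count; sequences are the decoded tags at their true length, with a
    uniform high quality string.
    """
    if len(master) == 0:
        raise ValueError("refusing to export an empty master tag list")
    def records():
        for i, (tag, count) in enumerate(master.items()):
            seq = tag.sequence
            yield f"tag{i}|count={count}", seq, quality_char * len(seq)
    write_fastq(records(), path)


def master_from_fastq(path, min_count: int = 1) -> MasterTagList:
    """Re-read an exported master FASTQ back into a MasterTagList."""
    counts: dict[Tag, int] = {}
    for rid, seq in iter_fastq(path):
        count = 1
        if "count=" in rid:
            count = int(rid.split("count=")[1].split("|")[0])
        counts[encode_sequence(seq)] = count
    return MasterTagList(counts, min_count=min_count, source=str(path))


# ---------------------------------------------------------------------------
# Persistence: documented little-ish binary (big-endian records) + TSV


def write_tagcounts(table: TagCountTable, path) -> None:
    items = table.items()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack(">HI", _VERSION, len(items)))
        payload = bytearray()
        for tag, count in items:
            payload += _REC.pack(tag.packed_bytes, tag.length, count)
        fh.write(struct.pack(">I", zlib.crc32(bytes(payload))))
        fh.write(payload)


def read_tagcounts(path) -> TagCountTable:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path}: not a tag-count file")
        version, n = struct.unpack(">HI", fh.read(6))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported version {version}")
        (crc,) = struct.unpack(">I", fh.read(4))
        payload = fh.read(n * _REC.size)
        if zlib.crc32(payload) != crc:
            raise ValueError(f"{path}: checksum mismatch")
        counts: dict[Tag, int] = {}
        for off in range(0, len(payload), _REC.size):
            packed, length, count = _REC.unpack_from(payload, off)
            counts[Tag(int.from_bytes(packed, "big"), length)] = count
    return TagCountTable(counts, source=str(path))


def write_tagcounts_tsv(table: TagCountTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("tag\tlength\tcount\n")
        for tag, count in table.items():
            fh.write(f"{tag.sequence}\t{tag.length}\t{count}\n")


def read_tagcounts_tsv(path) -> TagCountTable:
    counts: dict[Tag, int] = {}
    with _open_text(path) as fh:
        fh.readline()
        for line in fh:
            seq, _length, count = line.rstrip("\n").split("\t")
            counts[encode_sequence(seq)] = int(count)
    return TagCountTable(counts, source=str(path))
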