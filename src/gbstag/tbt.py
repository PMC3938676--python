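"""TagsByTaxa: the sparse tags x taxa read-depth matrix.

One row per master tag (in master order), one column per taxon (a sample
from a particular library prep), depths stored as single bytes saturating
at 127.  At the low per-sample depths GBS targets (0.5-3x) the matrix is
overwhelmingly zero, so persistence uses a zero-run/literal run-length
encoding with per-row checksums.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .seqcore import (
    DEFAULT_MIN_TAG_LENGTH,
    MAX_TAG_LENGTH,
    BarcodeKey,
    EnzymeModel,
    LaneClassifier,
    ReadStatus,
    Tag,
)
from .seqcore import iter_fastq
from .tagcounts import MasterTagList

DEPTH_CAP = 127


@dataclass
class TBTReport:
    """Accounting of a TBT build: GOOD reads matched/unmatched per taxon."""

    total_reads: int = 0
    good_reads: int = 0
    matched: dict[str, int] = field(default_factory=dict)
    unmatched_good: int = 0
    rejected: dict[str, int] = field(default_factory=dict)


class TBT:
    """Dense-backed tags x taxa depth matrix with a 127 depth cap."""

    def __init__(self, tags: list[Tag], taxa: list[str], depths: np.ndarray | None = None):
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxa names must be unique")
        self.tags = list(tags)
        self.taxa = list(taxa)
        if depths is None:
            depths = np.zeros((len(tags), len(taxa)), dtype=np.uint8)
        depths = np.asarray(depths, dtype=np.uint8)
        if depths.shape != (len(tags), len(taxa)):
            raise ValueError("depth matrix shape does not match tags x taxa")
        if depths.size and depths.max() > DEPTH_CAP:
            raise ValueError(f"depths exceed cap of {DEPTH_CAP}")
        self.depths = depths
        self._taxon_idx = {t: i for i, t in enumerate(taxa)}

    def taxon_index(self, taxon: str) -> int:
        return self._taxon_idx[taxon]

    def row(self, i: int) -> np.ndarray:
        return self.depths[i]

    def increment(self, tag_row: int, taxon_col: int) -> None:
        d = self.depths[tag_row, taxon_col]
        if d < DEPTH_CAP:
            self.depths[tag_row, taxon_col] = d + 1

    def column_sums(self) -> dict[str, int]:
        sums = self.depths.sum(axis=0, dtype=np.int64)
        return {t: int(s) for t, s in zip(self.taxa, sums)}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TBT)
            and self.tags == other.tags
            and self.taxa == other.taxa
            and np.array_equal(self.depths, other.depths)
        )


def build_tbt(
    fastqs: list[tuple[object, str, str]],
    key: BarcodeKey,
    master: MasterTagList,
    enzyme: EnzymeModel,
    trim_length: int = MAX_TAG_LENGTH,
    min_tag_length: int = DEFAULT_MIN_TAG_LENGTH,
    require_remnant: bool = True,
    taxa: list[str] | None = None,
) -> tuple[TBT, TBTReport]:
    """Tally per-taxon depth of each master tag over (fastq, flowcell, lane)
    inputs.  GOOD reads whose tag is not in the master list are reported but
    not stored.  File order never changes the result (saturating tallies
    commute)."""
    tag_order = master.tags()
    tag_idx = master.index()
    if taxa is None:
        taxa = key.taxa
    tbt = TBT(tag_order, taxa)
    report = TBTReport()
    for fastq, flowcell, lane in sorted(fastqs, key=lambda x: str(x[0])):
        clf = LaneClassifier(
            key.lane_entries(flowcell, lane), enzyme,
            trim_length=trim_length, min_tag_length=min_tag_length,
            require_remnant=require_remnant,
        )
        for _rid, seq in iter_fastq(fastq):
            c = clf.classify(seq)
            report.total_reads += 1
            if c.status is not ReadStatus.GOOD:
                report.rejected[c.status.value] = report.rejected.get(c.status.value, 0) + 1
                continue
            report.good_reads += 1
            row = tag_idx.get(c.tag)
            if row is None:
                report.unmatched_good += 1
                continue
            if c.taxon not in tbt._taxon_idx:
                raise KeyError(f"taxon {c.taxon!r} not in requested taxa list")
            tbt.increment(row, tbt._taxon_idx[c.taxon])
            report.matched[c.taxon] = report.matched.get(c.taxon, 0) + 1
    return tbt, report


def merge_taxa(tbt: TBT, groups: dict[str, str]) -> TBT:
    """Merge replicate taxa: depth of a merged taxon is the capped sum of
    its members.  ``groups`` maps member taxon -> merged name; taxa not in
    ``groups`` pass through unchanged."""
    for t in groups:
        if t not in tbt._taxon_idx:
            raise KeyError(f"unknown taxon {t!r} in groups")
    new_names: list[str] = []
    members: dict[str, list[int]] = {}
    for i, t in enumerate(tbt.taxa):
        name = groups.get(t, t)
        if name not in members:
            members[name] = []
            new_names.append(name)
        members[name].append(i)
    if len(set(new_names)) != len(new_names):  # defensive; dict keys unique
        raise ValueError("merged taxa names collide")
    out = np.zeros((len(tbt.tags), len(new_names)), dtype=np.uint8)
    for j, name in enumerate(new_names):
        s = tbt.depths[:, members[name]].astype(np.int32).sum(axis=1)
        out[:, j] = np.minimum(s, DEPTH_CAP).astype(np.uint8)
    return TBT(tbt.tags, new_names, out)


def blank_qc(tbt: TBT, blank_taxa: list[str], max_expected: int = 10) -> dict[str, int]:
    """Flag blank negative controls whose matched depth exceeds expectation."""
    sums = tbt.column_sums()
    return {t: sums[t] for t in blank_taxa if sums.get(t, 0) > max_expected}


# ---------------------------------------------------------------------------
# RLE persistence
#
# Row payload tokens (1-byte headers): bit 7 set = literal of (header & 0x7F)
# depth bytes following; bit 7 clear = that many zero bytes.  Runs longer
# than 127 split into several tokens.  Isolated single zeros are folded into
# the surrounding literal (a dedicated run token would cost more than the
# byte it encodes).  Each row is followed by the crc32 of its raw bytes.

_MAGIC = b"GBT1"


def _rle_encode_row(row: np.ndarray) -> bytes:
    raw = row.tobytes()
    n = len(raw)
    out = bytearray()
    lit_start = 0
    i = 0
    while i < n:
        if raw[i] == 0:
            j = i
            while j < n and raw[j] == 0:
                j += 1
            # encode as a zero run only if it pays for its header
            if j - i >= 2 or j == n:
                _emit_literal(out, raw, lit_start, i)
                r = j - i
                while r > 0:
                    k = min(r, 127)
                    out.append(k)
                    r -= k
                lit_start = j
            i = j
        else:
            i += 1
    _emit_literal(out, raw, lit_start, n)
    return bytes(out)


def _emit_literal(out: bytearray, raw: bytes, start: int, end: int) -> None:
    while start < end:
        k = min(end - start, 127)
        out.append(0x80 | k)
        out += raw[start : start + k]
        start += k


def rle_write(tbt: TBT, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack(">II", len(tbt.tags), len(tbt.taxa)))
        for name in tbt.taxa:
            b = name.encode()
            fh.write(struct.pack(">H", len(b)) + b)
        for tag in tbt.tags:
            fh.write(struct.pack(">16sB", tag.packed_bytes, tag.length))
        for i in range(len(tbt.tags)):
            row = tbt.depths[i]
            enc = _rle_encode_row(row)
            fh.write(struct.pack(">I", len(enc)))
            fh.write(enc)
            fh.write(struct.pack(">I", zlib.crc32(row.tobytes())))


def rle_read(path) -> TBT:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path}: not a TBT RLE file")
        ntags, ntaxa = struct.unpack(">II", fh.read(8))
        taxa = []
        for _ in range(ntaxa):
            (ln,) = struct.unpack(">H", fh.read(2))
            taxa.append(fh.read(ln).decode())
        tags = []
        for _ in range(ntags):
            packed, length = struct.unpack(">16sB", fh.read(17))
            tags.append(Tag(int.from_bytes(packed, "big"), length))
        depths = np.zeros((ntags, ntaxa), dtype=np.uint8)
        for i in range(ntags):
            (enc_len,) = struct.unpack(">I", fh.read(4))
            enc = fh.read(enc_len)
            (crc,) = struct.unpack(">I", fh.read(4))
            row = bytearray()
            off = 0
            while off < len(enc):
                head = enc[off]
                off += 1
                n = head & 0x7F
                if head & 0x80:
                    row += enc[off : off + n]
                    off += n
                else:
                    row += b"\x00" * n
            if len(row) != ntaxa:
                raise ValueError(f"{path}: row {i} decodes to wrong width")
            if zlib.crc32(bytes(row)) != crc:
                raise ValueError(f"{path}: checksum mismatch on row {i}")
            depths[i] = np.frombuffer(bytes(row), dtype=np.uint8)
    return TBT(tags, taxa, depths)


def rle_compressed_size(tbt: TBT) -> int:
    """Payload bytes the RLE rows occupy (excluding headers), for QC."""
    return sum(len(_rle_encode_row(tbt.depths[i])) for i in range(len(tbt.tags)))
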