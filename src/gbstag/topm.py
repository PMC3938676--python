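"""TagsOnPhysicalMap: every master tag, its unique-best genomic position,
and (after Discovery) the variants it carries.

Alignment of the master tags to the reference is done by an external
aligner (bwa, bowtie2, minimap2, ...); this module imports the resulting
SAM.  Every master tag gets exactly one entry — UNIQUE (one best
alignment), MULTIPLE (ties) or UNALIGNED — so the TOPM always partitions
the master list.  Keeping the unplaced tags around lets later evidence
(a better aligner, genetic mapping) place them without rebuilding.

Coordinates are 1-based SAM coordinates.  ``cut_pos`` anchors the cut-site
end of the tag: the leftmost aligned base for + strand alignments and the
rightmost for − strand, so tags from the two sides of one cut site map to
stable, strand-consistent reference coordinates.
"""

from __future__ import annotations

import re
import struct
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional

import h5py
import numpy as np
import pysam

from .seqcore import Tag, encode_sequence, _open_text
from .tagcounts import MasterTagList

GAP = "-"
DEFAULT_MAX_VARIANTS = 8

_ALLELES = "ACGT" + GAP
_ALLELE_CODE = {a: i for i, a in enumerate(_ALLELES)}


class AlignStatus(Enum):
    UNIQUE = "UNIQUE"
    MULTIPLE = "MULTIPLE"
    UNALIGNED = "UNALIGNED"


@dataclass(frozen=True)
class Variant:
    """One allele carried by a tag: 0-based offset within the TagLocus
    alignment, and the allele character (A/C/G/T or '-' for a gap)."""

    offset: int
    allele: str

    def __post_init__(self):
        if self.allele not in _ALLELE_CODE:
            raise ValueError(f"invalid variant allele {self.allele!r}")
        if self.offset < 0:
            raise ValueError("variant offset must be >= 0")


@dataclass
class TOPMEntry:
    tag: Tag
    status: AlignStatus
    chrom: Optional[str] = None
    strand: Optional[str] = None
    cut_pos: Optional[int] = None
    variants: tuple[Variant, ...] = ()


class TOPMError(ValueError):
    pass


class TOPM:
    """Key-value map over tags plus a position-ordered view of UNIQUE entries."""

    def __init__(self, entries: list[TOPMEntry], max_variants: int = DEFAULT_MAX_VARIANTS):
        self.max_variants = max_variants
        self._entries: dict[Tag, TOPMEntry] = {}
        for e in entries:
            if e.tag in self._entries:
                raise TOPMError(f"duplicate tag in TOPM: {e.tag.sequence}")
            if e.status is AlignStatus.UNIQUE:
                if e.chrom is None or e.strand not in "+-" or not e.cut_pos or e.cut_pos < 1:
                    raise TOPMError("UNIQUE entry needs chrom, strand and cut_pos >= 1")
            self._entries[e.tag] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, tag: Tag) -> bool:
        return tag in self._entries

    def lookup(self, tag: Tag) -> Optional[TOPMEntry]:
        """Exact (sequence, length) lookup; a miss returns None."""
        return self._entries.get(tag)

    def entries(self) -> list[TOPMEntry]:
        return [self._entries[t] for t in sorted(self._entries)]

    def iter_by_position(self) -> Iterator[TOPMEntry]:
        """UNIQUE entries sorted by (chrom, cut_pos, strand)."""
        uniq = [e for e in self._entries.values() if e.status is AlignStatus.UNIQUE]
        uniq.sort(key=lambda e: (e.chrom, e.cut_pos, e.strand, e.tag))
        return iter(uniq)

    def status_counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in AlignStatus}
        for e in self._entries.values():
            out[e.status.value] += 1
        return out

    def annotate_variants(self, tag: Tag, variants: list[Variant | tuple[int, str]]) -> None:
        """Replace a UNIQUE tag's recorded variants (persisted with the TOPM)."""
        entry = self._entries.get(tag)
        if entry is None:
            raise TOPMError("cannot annotate a tag absent from the TOPM")
        if entry.status is not AlignStatus.UNIQUE:
            raise TOPMError(f"cannot annotate a {entry.status.value} tag")
        vs = tuple(v if isinstance(v, Variant) else Variant(*v) for v in variants)
        if len(vs) > self.max_variants:
            raise TOPMError(f"{len(vs)} variants exceed max_variants={self.max_variants}")
        offsets = [v.offset for v in vs]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise TOPMError("variant offsets must be strictly increasing")
        self._entries[tag] = replace(entry, variants=vs)

    def annotated_entries(self) -> list[TOPMEntry]:
        return [e for e in self.entries() if e.variants]

    def copy(self) -> "TOPM":
        return TOPM([replace(e) for e in self.entries()], max_variants=self.max_variants)

    def __eq__(self, other) -> bool:
        return isinstance(other, TOPM) and self.entries() == other.entries()


# ---------------------------------------------------------------------------
# SAM import

_TAGID = re.compile(r"tag(\d+)")


def import_sam(sam_path, master: MasterTagList, mapq_min: int = 0) -> TOPM:
    """Convert external-aligner SAM output over the exported master FASTQ
    into a TOPM.

    A tag is UNIQUE iff its primary alignment is mapped, has no reported
    equal-score alternative (XS == AS, or an equal-score secondary record),
    and MAPQ >= mapq_min.  MAPQ 0 without an alignment score tag is treated
    as MULTIPLE (aligners emit MAPQ 0 for repetitive placements).
    """
    order = master.tags()
    by_index: dict[int, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_supplementary:
                continue
            # Exported IDs look like "tag12|count=34"; resolve on the index.
            m = _TAGID.match(rec.query_name or "")
            if m is None:
                raise TOPMError(f"SAM read ID {rec.query_name!r} is not a master tag ID")
            idx = int(m.group(1))
            if idx >= len(order):
                raise TOPMError(f"SAM read ID {rec.query_name!r} beyond master list")
            by_index.setdefault(idx, []).append(
                (
                    rec.is_unmapped,
                    rec.is_secondary,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    rec.is_reverse,
                    rec.mapping_quality,
                    rec.get_tag("AS") if rec.has_tag("AS") else None,
                    rec.get_tag("XS") if rec.has_tag("XS") else None,
                )
            )
    entries = [
        _classify_alignment(tag, by_index.get(i), mapq_min)
        for i, tag in enumerate(order)
    ]
    return TOPM(entries)


def _classify_alignment(tag: Tag, recs, mapq_min: int) -> TOPMEntry:
    if not recs:
        return TOPMEntry(tag, AlignStatus.UNALIGNED)
    primaries = [r for r in recs if not r[1]]
    if not primaries:
        raise TOPMError(f"no primary SAM record for tag {tag.sequence}")
    unmapped, _sec, chrom, start0, end0, is_rev, mapq, as_score, xs_score = primaries[0]
    if unmapped:
        return TOPMEntry(tag, AlignStatus.UNALIGNED)
    secondaries = [r for r in recs if r[1] and not r[0]]
    if as_score is not None:
        if xs_score is not None and xs_score >= as_score:
            return TOPMEntry(tag, AlignStatus.MULTIPLE)
        if any(r[7] is not None and r[7] >= as_score for r in secondaries):
            return TOPMEntry(tag, AlignStatus.MULTIPLE)
    else:
        if secondaries or mapq == 0:
            return TOPMEntry(tag, AlignStatus.MULTIPLE)
    if mapq < mapq_min:
        return TOPMEntry(tag, AlignStatus.UNALIGNED)
    strand = "-" if is_rev else "+"
    # 1-based: leftmost aligned base for +, rightmost for - (cut-site end).
    cut_pos = end0 if is_rev else start0 + 1
    return TOPMEntry(tag, AlignStatus.UNIQUE, chrom=chrom, strand=strand, cut_pos=cut_pos)


# ---------------------------------------------------------------------------
# Persistence: TSV, binary, HDF5


def write_topm_tsv(topm: TOPM, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("tag\tlength\tstatus\tchrom\tstrand\tcut_pos\tvariants\n")
        for e in topm.entries():
            var = ";".join(f"{v.offset}:{v.allele}" for v in e.variants)
            fh.write(
                f"{e.tag.sequence}\t{e.tag.length}\t{e.status.value}\t"
                f"{e.chrom or '.'}\t{e.strand or '.'}\t{e.cut_pos or 0}\t{var or '.'}\n"
            )


def read_topm_tsv(path, max_variants: int = DEFAULT_MAX_VARIANTS) -> TOPM:
    entries = []
    with _open_text(path) as fh:
        fh.readline()
        for line in fh:
            seq, _ln, status, chrom, strand, cut_pos, var = line.rstrip("\n").split("\t")
            variants = ()
            if var != ".":
                variants = tuple(
                    Variant(int(p.split(":")[0]), p.split(":")[1]) for p in var.split(";")
                )
            entries.append(
                TOPMEntry(
                    encode_sequence(seq),
                    AlignStatus(status),
                    chrom=None if chrom == "." else chrom,
                    strand=None if strand == "." else strand,
                    cut_pos=int(cut_pos) or None,
                    variants=variants,
                )
            )
    return TOPM(entries, max_variants=max_variants)


_STATUS_CODE = {AlignStatus.UNIQUE: 0, AlignStatus.MULTIPLE: 1, AlignStatus.UNALIGNED: 2}
_STATUS_FROM = {v: k for k, v in _STATUS_CODE.items()}
_BIN_MAGIC = b"GBPM"


def write_topm_binary(topm: TOPM, path) -> None:
    entries = topm.entries()
    chroms = sorted({e.chrom for e in entries if e.chrom})
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    with open(path, "wb") as fh:
        fh.write(_BIN_MAGIC)
        fh.write(struct.pack(">HIB", 1, len(entries), topm.max_variants))
        fh.write(struct.pack(">H", len(chroms)))
        for c in chroms:
            b = c.encode()
            fh.write(struct.pack(">H", len(b)) + b)
        payload = bytearray()
        for e in entries:
            payload += struct.pack(
                ">16sBBhBq",
                e.tag.packed_bytes,
                e.tag.length,
                _STATUS_CODE[e.status],
                chrom_idx.get(e.chrom, -1),
                0 if e.strand != "-" else 1,
                e.cut_pos or 0,
            )
            payload += struct.pack(">B", len(e.variants))
            for v in e.variants:
                payload += struct.pack(">HB", v.offset, _ALLELE_CODE[v.allele])
        fh.write(struct.pack(">I", zlib.crc32(bytes(payload))))
        fh.write(payload)


def read_topm_binary(path) -> TOPM:
    with open(path, "rb") as fh:
        if fh.read(4) != _BIN_MAGIC:
            raise ValueError(f"{path}: not a TOPM binary")
        _ver, n, max_variants = struct.unpack(">HIB", fh.read(7))
        (nchrom,) = struct.unpack(">H", fh.read(2))
        chroms = []
        for _ in range(nchrom):
            (ln,) = struct.unpack(">H", fh.read(2))
            chroms.append(fh.read(ln).decode())
        (crc,) = struct.unpack(">I", fh.read(4))
        payload = fh.read()
        if zlib.crc32(payload) != crc:
            raise ValueError(f"{path}: checksum mismatch")
    entries = []
    off = 0
    head = struct.Struct(">16sBBhBq")
    for _ in range(n):
        packed, length, scode, cidx, sflag, cut_pos = head.unpack_from(payload, off)
        off += head.size
        (nvar,) = struct.unpack_from(">B", payload, off)
        off += 1
        variants = []
        for _ in range(nvar):
            voff, acode = struct.unpack_from(">HB", payload, off)
            off += 3
            variants.append(Variant(voff, _ALLELES[acode]))
        status = _STATUS_FROM[scode]
        entries.append(
            TOPMEntry(
                Tag(int.from_bytes(packed, "big"), length),
                status,
                chrom=chroms[cidx] if cidx >= 0 and status is AlignStatus.UNIQUE else None,
                strand=("-" if sflag else "+") if status is AlignStatus.UNIQUE else None,
                cut_pos=cut_pos or None,
                variants=tuple(variants),
            )
        )
    return TOPM(entries, max_variants=max_variants)


def write_topm_hdf5(topm: TOPM, path) -> None:
    entries = topm.entries()
    n = len(entries)
    bits = np.zeros((n, 2), dtype=np.uint64)
    for i, e in enumerate(entries):
        bits[i, 0] = e.tag.bits >> 64
        bits[i, 1] = e.tag.bits & ((1 << 64) - 1)
    var_counts = np.array([len(e.variants) for e in entries], dtype=np.int32)
    flat = [(v.offset, _ALLELE_CODE[v.allele]) for e in entries for v in e.variants]
    with h5py.File(path, "w") as f:
        f.attrs["max_variants"] = topm.max_variants
        f.create_dataset("tag_bits", data=bits)
        f.create_dataset("tag_length", data=np.array([e.tag.length for e in entries], dtype=np.uint8))
        f.create_dataset("status", data=np.array([_STATUS_CODE[e.status] for e in entries], dtype=np.uint8))
        f.create_dataset(
            "chrom",
            data=np.array([(e.chrom or "").encode() for e in entries], dtype="S64"),
        )
        f.create_dataset(
            "strand",
            data=np.array([1 if e.strand == "-" else 0 for e in entries], dtype=np.uint8),
        )
        f.create_dataset("cut_pos", data=np.array([e.cut_pos or 0 for e in entries], dtype=np.int64))
        f.create_dataset("variant_counts", data=var_counts)
        f.create_dataset(
            "variants",
            data=np.array(flat, dtype=np.int32).reshape(-1, 2) if flat else np.zeros((0, 2), np.int32),
        )


def read_topm_hdf5(path) -> TOPM:
    with h5py.File(path, "r") as f:
        max_variants = int(f.attrs["max_variants"])
        bits = f["tag_bits"][:]
        lengths = f["tag_length"][:]
        status = f["status"][:]
        chrom = f["chrom"][:]
        strand = f["strand"][:]
        cut_pos = f["cut_pos"][:]
        var_counts = f["variant_counts"][:]
        flat = f["variants"][:]
    entries = []
    vi = 0
    for i in range(len(lengths)):
        st = _STATUS_FROM[int(status[i])]
        variants = tuple(
            Variant(int(flat[j, 0]), _ALLELES[int(flat[j, 1])])
            for j in range(vi, vi + int(var_counts[i]))
        )
        vi += int(var_counts[i])
        entries.append(
            TOPMEntry(
                Tag((int(bits[i, 0]) << 64) | int(bits[i, 1]), int(lengths[i])),
                st,
                chrom=chrom[i].decode() or None if st is AlignStatus.UNIQUE else None,
                strand=("-" if strand[i] else "+") if st is AlignStatus.UNIQUE else None,
                cut_pos=int(cut_pos[i]) or None,
                variants=variants,
            )
        )
    return TOPM(entries, max_variants=max_variants)
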