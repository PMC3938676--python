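"""Sequence encoding, enzyme model, barcode keys, and read classification.

GBS reads have a rigid anatomy: a sample barcode, immediately followed by
the remnant of the restriction-enzyme cut site, followed by genomic
sequence.  Everything downstream of the barcode (remnant included) is the
*tag*: a unique sequence of up to 64 bases that, together with its length,
is the unit of all counting, alignment and SNP calling in this package.

Tags are packed two bits per base (A=00, C=01, G=10, T=11), so a 64-base
tag occupies exactly 16 bytes of payload.  Ambiguous bases are never
allowed inside a tag; reads containing an N in the tag region are rejected
wholesale rather than trimmed or corrected.  Base quality scores are
ignored throughout: tag recurrence across the experiment, not the
sequencer's confidence, is the evidence of sequence quality.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator, Optional

MAX_TAG_LENGTH = 64
DEFAULT_MIN_TAG_LENGTH = 20

_BASES = "ACGT"
_ENC = str.maketrans("ACGT", "0123")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class SequenceError(ValueError):
    """Raised when a sequence violates the tag alphabet or length bounds."""


@dataclass(frozen=True, order=True)
class Tag:
    """A packed tag: 2-bit encoded bases plus an explicit length.

    ``bits`` holds the bases as a base-4 integer, first base most
    significant; positions above ``length`` are zero.  Equality and the
    (total, deterministic) ordering are over ``(bits, length)``.
    """

    bits: int
    length: int

    @property
    def sequence(self) -> str:
        return decode_bits(self.bits, self.length)

    @property
    def packed_bytes(self) -> bytes:
        """16-byte big-endian payload (128 bits, zero-padded high bits)."""
        return self.bits.to_bytes(16, "big")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sequence


def encode_sequence(seq: str) -> Tag:
    """Pack an A/C/G/T string of 1..64 bases into a :class:`Tag`.

    Injective over (sequence, length); N or IUPAC codes are rejected.
    """
    n = len(seq)
    if n < 1 or n > MAX_TAG_LENGTH:
        raise SequenceError(f"tag length {n} outside [1, {MAX_TAG_LENGTH}]")
    try:
        bits = int(seq.translate(_ENC), 4) if seq else 0
    except ValueError as exc:
        raise SequenceError(f"non-ACGT base in tag: {seq!r}") from exc
    # int(x, 4) accepts signs/whitespace that translate() left untouched;
    # any character outside ACGT must have failed above, but a lone "+"
    # would not, so double-check the alphabet cheaply on suspicion.
    if not _is_acgt(seq):
        raise SequenceError(f"non-ACGT base in tag: {seq!r}")
    return Tag(bits=bits, length=n)


def _is_acgt(seq: str) -> bool:
    return not seq.strip("ACGT")


def decode_bits(bits: int, length: int) -> str:
    out = []
    for shift in range(2 * (length - 1), -1, -2):
        out.append(_BASES[(bits >> shift) & 3])
    return "".join(out)


def decode_tag(tag: Tag) -> str:
    return decode_bits(tag.bits, tag.length)


_COMPL = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


# ---------------------------------------------------------------------------
# Enzyme model


@dataclass(frozen=True)
class EnzymeModel:
    """Cut-site model for one enzyme (or enzyme pair).

    ``remnants`` are the sequences expected immediately after the barcode
    (one per possible cut overhang); ``internal_patterns`` are full
    recognition sites whose occurrence *inside* a read marks a chimeric
    fragment and triggers trimming.  Internal patterns may use IUPAC
    degeneracy codes (e.g. GCWGC); remnants may not.
    """

    name: str
    remnants: tuple[str, ...]
    internal_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.remnants:
            raise ValueError("enzyme needs at least one cut-site remnant")
        for r in self.remnants:
            if not r or not _is_acgt(r):
                raise ValueError(f"invalid remnant {r!r}: must be non-empty A/C/G/T")
        for p in self.internal_patterns:
            if not p or any(c not in _IUPAC for c in p):
                raise ValueError(f"invalid internal cut pattern {p!r}")

    @property
    def internal_regex(self) -> Optional[re.Pattern]:
        if not self.internal_patterns:
            return None
        alts = ["".join(_IUPAC[c] for c in p) for p in self.internal_patterns]
        return re.compile("|".join(alts))

    def leading_remnant(self, seq: str) -> Optional[str]:
        """The remnant that ``seq`` starts with, or None."""
        for r in sorted(self.remnants, key=len, reverse=True):
            if seq.startswith(r):
                return r
        return None


def load_enzyme(name: str) -> EnzymeModel:
    """Load an enzyme from the packaged config table (user-extensible data)."""
    table = json.loads(
        resources.files("gbstag.data").joinpath("enzymes.json").read_text()
    )
    if name not in table:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(table)}")
    spec = table[name]
    return EnzymeModel(
        name=name,
        remnants=tuple(spec["remnants"]),
        internal_patterns=tuple(spec.get("internal_patterns", ())),
    )


# ---------------------------------------------------------------------------
# Barcode key


class BarcodeKeyError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeEntry:
    flowcell: str
    lane: str
    barcode: str
    taxon: str
    prep_id: str = ""

    @property
    def taxon_name(self) -> str:
        """Taxon identity is sample x library prep."""
        return f"{self.taxon}:{self.prep_id}" if self.prep_id else self.taxon


@dataclass
class BarcodeKey:
    """Validated (flowcell, lane, barcode) -> sample map.

    Within one lane, barcodes must be unique and prefix-free (no barcode a
    prefix of another), which makes exact-prefix matching unambiguous and
    order-independent.  Barcode lengths are restricted to 4..16 bases.
    """

    entries: list[BarcodeEntry] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[tuple[str, str], list[str]] = {}
        for e in self.entries:
            if not (4 <= len(e.barcode) <= 16):
                raise BarcodeKeyError(
                    f"barcode {e.barcode!r} length outside [4, 16]"
                )
            if not _is_acgt(e.barcode):
                raise BarcodeKeyError(f"non-ACGT barcode {e.barcode!r}")
            seen.setdefault((e.flowcell, e.lane), []).append(e.barcode)
        for (fc, lane), bcs in seen.items():
            if len(set(bcs)) != len(bcs):
                raise BarcodeKeyError(f"duplicate barcode in {fc}/{lane}")
            srt = sorted(bcs)
            for a, b in zip(srt, srt[1:]):
                if b.startswith(a):
                    raise BarcodeKeyError(
                        f"barcode {a!r} is a prefix of {b!r} in {fc}/{lane}"
                    )

    def lane_entries(self, flowcell: str, lane: str) -> dict[str, BarcodeEntry]:
        return {
            e.barcode: e
            for e in self.entries
            if e.flowcell == flowcell and e.lane == str(lane)
        }

    @property
    def taxa(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.taxon_name not in out:
                out.append(e.taxon_name)
        return out


_REQUIRED_COLUMNS = ("Flowcell", "Lane", "Barcode", "Sample")


def parse_barcode_key(path) -> BarcodeKey:
    """Parse a tab-delimited barcode key file.

    Header row must name Flowcell, Lane, Barcode and Sample (LibraryPrepID
    optional; extra columns ignored).
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in _REQUIRED_COLUMNS:
            if col not in idx:
                raise BarcodeKeyError(f"key file missing required column {col!r}")
        prep_col = idx.get("LibraryPrepID")
        entries = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                entries.append(
                    BarcodeEntry(
                        flowcell=parts[idx["Flowcell"]],
                        lane=parts[idx["Lane"]],
                        barcode=parts[idx["Barcode"]].upper(),
                        taxon=parts[idx["Sample"]],
                        prep_id=parts[prep_col] if prep_col is not None and prep_col < len(parts) else "",
                    )
                )
            except IndexError as exc:
                raise BarcodeKeyError(f"malformed key row at line {lineno}") from exc
    return BarcodeKey(entries=entries)


# ---------------------------------------------------------------------------
# Read classification


class ReadStatus(Enum):
    GOOD = "GOOD"
    NO_BARCODE = "NO_BARCODE"
    CONTAINS_N = "CONTAINS_N"
    TOO_SHORT = "TOO_SHORT"


@dataclass(frozen=True)
class ReadClassification:
    status: ReadStatus
    taxon: Optional[str] = None
    tag: Optional[Tag] = None
    chimera_trimmed: bool = False


class LaneClassifier:
    """Classifies raw reads for one flowcell/lane against one enzyme.

    Bundles the per-lane barcode map and precompiled patterns so that the
    per-read hot path stays cheap.
    """

    def __init__(
        self,
        barcodes: dict[str, BarcodeEntry],
        enzyme: EnzymeModel,
        trim_length: int = MAX_TAG_LENGTH,
        min_tag_length: int = DEFAULT_MIN_TAG_LENGTH,
        require_remnant: bool = True,
    ):
        if trim_length > MAX_TAG_LENGTH:
            raise ValueError(f"trim_length {trim_length} exceeds {MAX_TAG_LENGTH}")
        if not barcodes:
            raise BarcodeKeyError("no barcode entries for this flowcell/lane")
        self.barcodes = barcodes
        self.enzyme = enzyme
        self.trim_length = trim_length
        self.min_tag_length = min_tag_length
        self.require_remnant = require_remnant
        self._bc_lengths = sorted({len(b) for b in barcodes})
        self._internal = enzyme.internal_regex
        self._remnants = tuple(sorted(enzyme.remnants, key=len, reverse=True))

    def classify(self, raw: str) -> ReadClassification:
        entry = None
        for blen in self._bc_lengths:
            e = self.barcodes.get(raw[:blen])
            if e is not None:
                entry = e
                break
        if entry is None:
            return ReadClassification(ReadStatus.NO_BARCODE)
        rest = raw[len(entry.barcode):]

        remnant = None
        for r in self._remnants:
            if rest.startswith(r):
                remnant = r
                break
        if remnant is None and self.require_remnant:
            # Structurally not a barcoded GBS read: the assay guarantees the
            # cut-site remnant directly after the barcode.
            return ReadClassification(ReadStatus.NO_BARCODE)

        seq = rest[: self.trim_length]
        if not _is_acgt(seq):
            return ReadClassification(ReadStatus.CONTAINS_N)

        chimera = False
        if self._internal is not None:
            start = len(remnant) if remnant else 1
            m = self._internal.search(seq, start)
            if m is not None:
                seq = seq[: m.start()]
                chimera = True

        if len(seq) < self.min_tag_length:
            return ReadClassification(ReadStatus.TOO_SHORT, chimera_trimmed=chimera)
        return ReadClassification(
            ReadStatus.GOOD,
            taxon=entry.taxon_name,
            tag=encode_sequence(seq),
            chimera_trimmed=chimera,
        )


def classify_read(
    raw: str,
    key: BarcodeKey | dict[str, BarcodeEntry],
    enzyme: EnzymeModel,
    flowcell: str | None = None,
    lane: str | None = None,
    trim_length: int = MAX_TAG_LENGTH,
    min_tag_length: int = DEFAULT_MIN_TAG_LENGTH,
    require_remnant: bool = True,
) -> ReadClassification:
    """Classify a single raw read (convenience wrapper over LaneClassifier)."""
    if isinstance(key, BarcodeKey):
        if flowcell is None or lane is None:
            raise ValueError("flowcell and lane required with a full BarcodeKey")
        barcodes = key.lane_entries(flowcell, lane)
    else:
        barcodes = key
    clf = LaneClassifier(
        barcodes, enzyme, trim_length=trim_length,
        min_tag_length=min_tag_length, require_remnant=require_remnant,
    )
    return clf.classify(raw)


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-transparent)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file, transparently gunzipping."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title, seq.upper()


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, seq, qual) triples as 4-line FASTQ records."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
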