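"""Read demultiplexing, barcode calling and quality filtering.

A merged amplicon read has the layout::

    fwd_tag + fwd_primer + template + revcomp(rev_primer) + revcomp(rev_tag)

and may arrive in either orientation. A read is assigned to a specimen iff
both tags match exactly (no mismatch) and both primers match with at most
``max_primer_mismatches`` mismatches under IUPAC semantics. The dominant
unique sequence per specimen is then called as the barcode when it clears
the read-count thresholds, after which stop-codon and length filters are
applied per sequence, and a minimum-barcode floor per trap/sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import ConfigError, DataError

__all__ = [
    "TaggedRead",
    "DemuxSheet",
    "SpecimenAmplicon",
    "BarcodeRecord",
    "DemuxResult",
    "demultiplex",
    "call_barcode",
    "filter_barcodes",
    "filter_samples",
    "iupac_mismatches",
]

# Calling thresholds: >=50 assigned reads per amplicon; dominant read count
# strictly >10 and at least 5x the runner-up.
MIN_TOTAL_READS = 50
MIN_SUPPORT = 10
DOMINANCE_RATIO = 5.0

# Length floors keyed by nominal amplicon length.
LENGTH_CUTOFFS = {313: 300, 658: 500}

INVERTEBRATE_MITO_TABLE = 5

_IUPAC_SETS = {
    code: frozenset(bases) | ({"N"} if code == "N" else frozenset())
    for code, bases in ambiguous_dna_values.items()
}


@dataclass(frozen=True)
class TaggedRead:
    """One merged amplicon read awaiting specimen assignment."""

    read_id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise DataError(f"read {self.read_id}: invalid symbols {sorted(bad)}")


@dataclass(frozen=True)
class SpecimenAmplicon:
    """Per-specimen tally of unique trimmed sequences."""

    specimen_id: str
    tally: Mapping[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.tally.values())


@dataclass(frozen=True)
class BarcodeRecord:
    """A called DNA barcode with specimen metadata."""

    specimen_id: str
    sequence: str
    support: int
    trap: str = "unassigned"
    family: str = "unassigned"

    @property
    def length(self) -> int:
        return len(self.sequence)


def iupac_mismatches(observed: str, pattern: str, stop_after: int | None = None) -> int:
    """Count mismatches of an observed ACGTN string against an IUPAC pattern.

    A position matches when the observed base is in the pattern code's base
    set; an observed N only matches a pattern N. Counting stops early once
    ``stop_after`` is exceeded (the exact count is then a lower bound).
    """
    if len(observed) != len(pattern):
        raise DataError("observed and pattern lengths differ")
    mismatches = 0
    for obs, pat in zip(observed, pattern):
        allowed = _IUPAC_SETS.get(pat)
        if allowed is None:
            raise DataError(f"invalid IUPAC code {pat!r} in pattern")
        if obs not in allowed:
            mismatches += 1
            if stop_after is not None and mismatches > stop_after:
                return mismatches
    return mismatches


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _validate_iupac(primer: str, name: str) -> None:
    bad = [c for c in primer.upper() if c not in _IUPAC_SETS]
    if bad:
        raise ConfigError(f"{name} contains non-IUPAC symbols {sorted(set(bad))}")


@dataclass(frozen=True)
class DemuxSheet:
    """Per-specimen tag pairs plus shared primers and mismatch limits."""

    entries: Mapping[str, tuple[str, str]]  # specimen -> (fwd_tag, rev_tag)
    primer_fwd: str
    primer_rev: str
    traps: Mapping[str, str] = field(default_factory=dict)  # specimen -> trap
    max_primer_mismatches: int = 2
    max_tag_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigError("demux sheet has no specimens")
        _validate_iupac(self.primer_fwd, "forward primer")
        _validate_iupac(self.primer_rev, "reverse primer")
        pairs = Counter(self.entries.values())
        dupes = [pair for pair, k in pairs.items() if k > 1]
        if dupes:
            raise ConfigError(f"duplicate tag pairs in sheet: {dupes}")
        tag_lengths = {len(t) for pair in self.entries.values() for t in pair}
        if len(tag_lengths) != 1:
            raise ConfigError(f"tags must share one length, got {sorted(tag_lengths)}")
        if self.max_primer_mismatches < 0 or self.max_tag_mismatches < 0:
            raise ConfigError("mismatch limits must be non-negative")

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.entries.values()))[0])


@dataclass
class DemuxResult:
    amplicons: dict[str, SpecimenAmplicon]
    n_assigned: int
    n_unassigned: int
    n_ambiguous: int  # subset of unassigned: matched in both orientations

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned


def _match_one_orientation(seq: str, sheet: DemuxSheet, lookup) -> tuple[str, str] | None:
    """Return (specimen, trimmed template) if this orientation matches."""
    tl = sheet.tag_length
    fp, rp = sheet.primer_fwd, sheet.primer_rev
    inner = len(seq) - 2 * tl - len(fp) - len(rp)
    if inner <= 0:
        return None
    fwd_tag = seq[:tl]
    rev_tag = _revcomp(seq[-tl:])
    specimen = lookup(fwd_tag, rev_tag)
    if specimen is None:
        return None
    if iupac_mismatches(seq[tl : tl + len(fp)], fp, sheet.max_primer_mismatches) > sheet.max_primer_mismatches:
        return None
    rev_region = _revcomp(seq[-(tl + len(rp)) : -tl])
    if iupac_mismatches(rev_region, rp, sheet.max_primer_mismatches) > sheet.max_primer_mismatches:
        return None
    template = seq[tl + len(fp) : len(seq) - tl - len(rp)]
    return specimen, template


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads: Iterable[TaggedRead], sheet: DemuxSheet) -> DemuxResult:
    """Assign reads to specimens and tally trimmed unique sequences.

    Both orientations of each read are tested; a read matching in both is
    ambiguous and left unassigned. Each read is assigned to at most one
    specimen, so assigned + unassigned = total.
    """
    by_pair = {pair: specimen for specimen, pair in sheet.entries.items()}

    if sheet.max_tag_mismatches == 0:
        def lookup(ft: str, rt: str) -> str | None:
            return by_pair.get((ft, rt))
    else:
        def lookup(ft: str, rt: str) -> str | None:
            hits = [
                specimen
                for (sft, srt), specimen in by_pair.items()
                if _hamming(ft, sft) <= sheet.max_tag_mismatches
                and _hamming(rt, srt) <= sheet.max_tag_mismatches
            ]
            return hits[0] if len(hits) == 1 else None

    tallies: dict[str, Counter] = {s: Counter() for s in sheet.entries}
    n_assigned = n_unassigned = n_ambiguous = 0
    for read in reads:
        seq = read.sequence.upper()
        fwd = _match_one_orientation(seq, sheet, lookup)
        rev = _match_one_orientation(_revcomp(seq), sheet, lookup)
        if fwd and rev:
            n_ambiguous += 1
            n_unassigned += 1
        elif fwd or rev:
            specimen, template = fwd or rev
            tallies[specimen][template] += 1
            n_assigned += 1
        else:
            n_unassigned += 1
    amplicons = {
        s: SpecimenAmplicon(specimen_id=s, tally=dict(t))
        for s, t in tallies.items()
        if t
    }
    return DemuxResult(amplicons, n_assigned, n_unassigned, n_ambiguous)


def call_barcode(
    amplicon: SpecimenAmplicon,
    min_total: int = MIN_TOTAL_READS,
    min_support: int = MIN_SUPPORT,
    dominance: float = DOMINANCE_RATIO,
) -> BarcodeRecord | None:
    """Call the dominant sequence as the specimen barcode, or None.

    Amplicons with fewer than ``min_total`` reads are dropped. The dominant
    count c1 must strictly exceed ``min_support`` and satisfy
    c1 >= dominance * c2 where c2 is the runner-up count (0 for a single
    unique sequence). A tie for the top count yields no barcode.
    """
    if not amplicon.tally:
        raise DataError(f"{amplicon.specimen_id}: empty tally")
    if amplicon.total_reads < min_total:
        return None
    ranked = sorted(amplicon.tally.items(), key=lambda kv: (-kv[1], kv[0]))
    seq1, c1 = ranked[0]
    c2 = ranked[1][1] if len(ranked) > 1 else 0
    if c1 == c2:
        return None
    if c1 <= min_support or c1 < dominance * c2:
        return None
    return BarcodeRecord(specimen_id=amplicon.specimen_id, sequence=seq1, support=c1)


def has_internal_stop(
    sequence: str,
    reading_frame: int = 2,
    table: int = INVERTEBRATE_MITO_TABLE,
) -> bool:
    """True if the translation in the given frame contains a stop codon.

    ``reading_frame`` is 1-based on the forward strand; trailing partial
    codons are ignored. Gaps are stripped before translation.
    """
    if reading_frame not in (1, 2, 3):
        raise ConfigError(f"reading_frame must be 1, 2 or 3, got {reading_frame}")
    seq = sequence.upper().replace("-", "")
    offset = reading_frame - 1
    coding = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
    if not coding:
        return False
    protein = str(Seq(coding).translate(table=table))
    return "*" in protein


def filter_barcodes(
    records: Sequence[BarcodeRecord],
    expected_length: int,
    reading_frame: int = 2,
    table: int = INVERTEBRATE_MITO_TABLE,
) -> tuple[list[BarcodeRecord], list[tuple[str, str]]]:
    """Apply length and stop-codon filters.

    Returns (retained records, rejection log of (specimen_id, reason)).
    Reasons are ``"length"`` and ``"stop_codon"``.
    """
    if expected_length not in LENGTH_CUTOFFS:
        raise ConfigError(
            f"expected_length must be one of {sorted(LENGTH_CUTOFFS)}, got {expected_length}"
        )
    min_len = LENGTH_CUTOFFS[expected_length]
    kept: list[BarcodeRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        if rec.length < min_len:
            rejected.append((rec.specimen_id, "length"))
        elif has_internal_stop(rec.sequence, reading_frame=reading_frame, table=table):
            rejected.append((rec.specimen_id, "stop_codon"))
        else:
            kept.append(rec)
    return kept, rejected


def filter_samples(
    records: Sequence[BarcodeRecord],
    min_barcodes: int = 100,
    key: str = "trap",
) -> tuple[list[BarcodeRecord], list[tuple[str, int]]]:
    """Drop trap/sample groups holding fewer than ``min_barcodes`` barcodes.

    Returns (retained records, log of (group, size) for dropped groups).
    """
    if key not in ("trap", "family"):
        raise ConfigError(f"unsupported grouping key {key!r}")
    sizes: Counter = Counter(getattr(rec, key) for rec in records)
    dropped = sorted((g, n) for g, n in sizes.items() if n < min_barcodes)
    bad = {g for g, _ in dropped}
    kept = [rec for rec in records if getattr(rec, key) not in bad]
    return kept, dropped
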