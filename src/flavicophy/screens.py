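"""Sequence-level screens: motif conservation and frameshift rescue.

Three observations about insect-specific flavivirus genomes are turned into
reusable operations:

* the 14-residue fusion-peptide motif of the E protein is highly conserved
  within the group (:func:`scan_motif`);
* cysteine positions in the E region are completely conserved across the
  group (:func:`check_conserved_columns`);
* NS5-like sequences interrupted by a premature stop codon can often be
  "rescued" by resuming translation in the +1 reading frame, and overlapping
  reading frames of substantial length (tens of codons) exist in these
  genomes (:func:`frameshift_rescue`, :func:`find_overlapping_orfs`).

Coordinates are 0-based, half-open, forward strand only (the flavivirus
genome is a single positive-sense ORF).  Ambiguous IUPAC bases translate to
'X' and never count as stop codons, which is conservative for rescue
detection.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "MotifProfile",
    "FrameshiftReport",
    "STOP_CODONS",
    "scan_motif",
    "check_conserved_columns",
    "frameshift_rescue",
    "find_overlapping_orfs",
    "translate",
]

# The standard genetic code; flaviviruses are translated by the host cytosol.
_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {"TAA", "TAG", "TGA"}
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)


@dataclass(frozen=True)
class MotifProfile:
    """An exact amino-acid motif with optional wildcard positions.

    'X' matches any residue; a bracketed group like ``[GH]`` matches any of
    the listed residues at that single position.
    """

    name: str
    pattern: str
    source_group: str = ""

    def __post_init__(self):
        if not re.fullmatch(r"(?:[A-WYZ]|X|\[[A-Z]+\])+", self.pattern):
            raise ValueError(f"invalid motif pattern {self.pattern!r}")

    def __len__(self) -> int:
        """Number of residue positions (a bracket group is one position)."""
        return len(re.findall(r"\[[A-Z]+\]|.", self.pattern))

    def regex(self) -> re.Pattern:
        parts = []
        for tok in re.findall(r"\[[A-Z]+\]|.", self.pattern):
            parts.append("." if tok == "X" else tok)
        return re.compile("".join(parts))


def _as_records(sequences) -> list[tuple[str, str]]:
    """Accept a FASTA path, file-like, mapping, or iterable of SeqRecords."""
    if isinstance(sequences, Mapping):
        return [(str(k), str(v).upper()) for k, v in sequences.items()]
    if isinstance(sequences, (str, Path)):
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(sequences), "fasta")]
    if hasattr(sequences, "read"):
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(sequences, "fasta")]
    return [(r.id, str(r.seq).upper()) for r in sequences]


def _looks_nucleotide(seq: str) -> bool:
    letters = set(seq) - set("-.*")
    return bool(letters) and letters <= set("ACGTUN")


def scan_motif(
    sequences, motif: MotifProfile, on_nucleotide: str = "warn"
) -> list[tuple[str, int, str]]:
    """All (overlapping) matches of ``motif`` in each amino-acid sequence.

    Returns ``(sequence id, 0-based start, matched substring)`` triples.
    Sequences that look like nucleotide data (ACGTUN-only) trigger a warning
    or, with ``on_nucleotide='error'``, a ValueError.
    """
    rx = motif.regex()
    hits = []
    for sid, seq in _as_records(sequences):
        if _looks_nucleotide(seq):
            msg = f"sequence {sid!r} looks like nucleotide data in a protein scan"
            if on_nucleotide == "error":
                raise ValueError(msg)
            warnings.warn(msg)
        pos = 0
        while True:
            m = rx.search(seq, pos)
            if m is None:
                break
            hits.append((sid, m.start(), m.group(0)))
            pos = m.start() + 1
    return hits


def check_conserved_columns(alignment, residue: str) -> list[int]:
    """Columns of an amino-acid alignment where ``residue`` is present in
    every sequence (a gap anywhere disqualifies the column)."""
    if len(residue) != 1:
        raise ValueError("residue must be a single amino acid")
    residue = residue.upper()
    records = _as_records(alignment)
    if len(records) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    (ncol,) = lengths
    out = []
    for j in range(ncol):
        if all(seq[j] == residue for _, seq in records):
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# translation and frames
# ---------------------------------------------------------------------------

def translate(seq: str) -> str:
    """Translate frame 0 with the standard code; ambiguous codons become 'X'
    (never a stop), trailing partial codons are dropped."""
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _stop_positions(seq: str, frame_start: int) -> list[int]:
    """Nucleotide start positions of stop codons read from ``frame_start``."""
    return [
        i
        for i in range(frame_start, len(seq) - 2, 3)
        if seq[i : i + 3] in STOP_CODONS
    ]


@dataclass(frozen=True)
class FrameshiftReport:
    """Outcome of a +1 frameshift rescue scan.

    ``stop_position`` is the codon index of the first in-frame stop (None if
    the frame-0 ORF is already stop-free, in which case no rescue is
    attempted).  ``rescue_start`` is the nucleotide coordinate at which
    translation resumes in the shifted frame.
    """

    stop_position: int | None
    rescue_found: bool
    shift_offset: int
    rescue_start: int | None
    rescued_length: int


def frameshift_rescue(
    seq: str, min_codons: int = 52, shift: int = 1
) -> FrameshiftReport:
    """Can a premature frame-0 stop be bypassed by a frameshift?

    Locates the first in-frame stop codon, then asks whether resuming
    translation in the shifted frame (default +1) at some position at or
    before the stop yields at least ``min_codons`` stop-free codons.  The
    default ``min_codons`` of 52 is the size of the smallest documented
    flavivirus overlapping ORF (the *foo* ORF).
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if shift not in (1, -1):
        raise ValueError("shift must be +1 or -1")
    frame0_stops = _stop_positions(seq, 0)
    if not frame0_stops:
        return FrameshiftReport(
            stop_position=None,
            rescue_found=False,
            shift_offset=shift,
            rescue_start=None,
            rescued_length=0,
        )
    stop_nt = frame0_stops[0]
    frame_start = shift % 3  # +1 -> 1, -1 -> 2
    shifted_stops = set(_stop_positions(seq, frame_start))
    best_len, best_start = 0, None
    # candidate resumption points: every shifted-frame codon boundary at or
    # before the stop codon
    for q in range(frame_start, stop_nt + 3, 3):
        length = 0
        i = q
        while i + 3 <= len(seq) and i not in shifted_stops:
            length += 1
            i += 3
        if length > best_len:
            best_len, best_start = length, q
    return FrameshiftReport(
        stop_position=stop_nt // 3,
        rescue_found=best_len >= min_codons,
        shift_offset=shift,
        rescue_start=best_start,
        rescued_length=best_len,
    )


def find_overlapping_orfs(
    seq: str, offsets: Iterable[int] = (1,), min_codons: int = 52
) -> list[tuple[int, int, int]]:
    """Maximal stop-free codon runs in shifted reading frames.

    Returns ``(offset, start_nt, length_codons)`` for every maximal run of
    at least ``min_codons`` stop-free codons in each requested frame shift
    (coordinates relative to the input, 0-based).
    """
    seq = seq.upper().replace("U", "T")
    offsets = list(offsets)
    if not offsets:
        raise ValueError("offsets must be non-empty")
    out = []
    for off in offsets:
        frame_start = off % 3
        stops = set(_stop_positions(seq, frame_start))
        run_start, run_len = None, 0
        positions = list(range(frame_start, len(seq) - 2, 3))
        for i in positions:
            if i in stops:
                if run_len >= min_codons:
                    out.append((off, run_start, run_len))
                run_start, run_len = None, 0
            else:
                if run_start is None:
                    run_start = i
                run_len += 1
        if run_len >= min_codons:
            out.append((off, run_start, run_len))
    return out
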