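"""Per-read editing state: alignment, exclusion, classification, junctions.

Each amplicon read is reduced to its observed per-ES U-count vector by
exact non-T backbone matching between the primer anchors.  Reads whose
non-T residue string differs from the reference backbone in any way
(a non-T SNP, or an insertion/deletion of a non-T residue) are excluded —
editing only adds or removes U's, so any other difference is a sequencing
artefact or off-target molecule.  Exclusions are encoded as reasons rather
than raised, so per-sample exclusion tallies stay auditable.

A non-excluded read is then classified against the two references over the
amplicon window and, if partially edited, assigned junction boundaries:

* JSS (junction start site): the first ES, moving 3'->5', whose U count
  fails to match the canonical fully edited sequence.
* JES (junction end site): the 5'-most ES with any editing action — a U
  count differing from the pre-edited sequence, canonical or not.

``jes == jss - 1`` encodes an *empty* junction: canonical editing up to
``jes`` with pre-edited sequence 5' of it, i.e. a clean pause with no zone
of non-canonical editing.  Sites where the pre-edited and canonical U
counts coincide are consistent with both references and can never be a JSS
or JES.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .scaffold import AmpliconWindow, EditingScaffold, UindelError, clean_sequence

__all__ = [
    "ExcludedRead",
    "ReadClass",
    "ExclusionReason",
    "AlignedRead",
    "JunctionCall",
    "ReadCall",
    "align_read",
    "classify_read",
    "call_junction",
    "process_read",
    "process_reads",
]


class ExcludedRead(UindelError):
    """Classification/junction calling was attempted on an excluded read."""


class ReadClass(str, enum.Enum):
    EXCLUDED = "EXCLUDED"
    PRE_EDITED = "PRE_EDITED"
    PARTIALLY_EDITED = "PARTIALLY_EDITED"
    FULLY_EDITED = "FULLY_EDITED"

    def __str__(self) -> str:  # clean TSV rendering
        return self.value


class ExclusionReason(str, enum.Enum):
    BACKBONE_MISMATCH = "backbone-mismatch"
    PRIMER_MISSING = "primer-missing"
    TOO_SHORT = "too-short"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AlignedRead:
    """A read reduced to its U-count vector over the amplicon ES window.

    ``u_obs[0]`` corresponds to ``window.es_lo``.  ``u_obs`` is None iff
    the read is excluded.
    """

    read_id: str
    u_obs: tuple[int, ...] | None
    exclusion: ExclusionReason | None = None

    @property
    def excluded(self) -> bool:
        return self.exclusion is not None


@dataclass(frozen=True)
class JunctionCall:
    jss: int | None
    jes: int | None


@dataclass(frozen=True)
class ReadCall:
    """Bundle of everything downstream statistics need about one read."""

    read_id: str
    read_class: ReadClass
    jss: int | None
    jes: int | None
    u_obs: tuple[int, ...] | None
    exclusion: ExclusionReason | None


def _hamming_le(a: str, b: str, k: int) -> bool:
    """True if strings of equal length differ at <= k positions."""
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def align_read(
    s: EditingScaffold,
    w: AmpliconWindow,
    read: str,
    read_id: str = "read",
    *,
    min_length: int = 0,
    primer_mismatches: int = 0,
) -> AlignedRead:
    """Extract a read's per-ES U counts by exact backbone matching.

    Amplicons are primer-delimited by construction, so the forward primer
    is required as a prefix of the read and the reverse primer as a suffix
    (each within ``primer_mismatches`` Hamming mismatches; default exact).
    Between the primers, the read's non-T residue string must equal the
    reference backbone over the window exactly; the T-run lengths at each
    gap then give the observed U counts.  All failure modes return an
    excluded read rather than raising.
    """
    seq = read.strip().upper().replace("U", "T")
    if len(seq) < max(min_length, len(w.fwd_primer) + len(w.rev_primer)):
        return AlignedRead(read_id, None, ExclusionReason.TOO_SHORT)
    if not _hamming_le(seq[: len(w.fwd_primer)], w.fwd_primer, primer_mismatches):
        return AlignedRead(read_id, None, ExclusionReason.PRIMER_MISSING)
    if not _hamming_le(seq[len(seq) - len(w.rev_primer):], w.rev_primer, primer_mismatches):
        return AlignedRead(read_id, None, ExclusionReason.PRIMER_MISSING)
    insert = seq[len(w.fwd_primer): len(seq) - len(w.rev_primer)]

    # expected backbone residues strictly between the primer footprints
    expected = s.backbone[w.fwd_end + 1 : w.rev_start]
    runs: list[int] = []
    residues: list[str] = []
    run = 0
    for ch in insert:
        if ch == "T":
            run += 1
        else:
            runs.append(run)
            residues.append(ch)
            run = 0
    runs.append(run)  # run before the reverse primer's first residue
    if "".join(residues) != expected:
        return AlignedRead(read_id, None, ExclusionReason.BACKBONE_MISMATCH)
    # runs are 5'->3' over gaps fwd_end+1 .. rev_start  ->  ES es_hi..es_lo
    u_obs = tuple(reversed(runs))
    return AlignedRead(read_id, u_obs)


def classify_read(a: AlignedRead, s: EditingScaffold, w: AmpliconWindow) -> ReadClass:
    """Classify a read against the two references over the window.

    FULLY_EDITED iff the read matches the canonical U counts at every
    window ES; PRE_EDITED iff it matches the pre-edited counts; otherwise
    PARTIALLY_EDITED.  A read consistent with both (possible only when the
    window is never-edited) is reported FULLY_EDITED.
    """
    if a.excluded:
        raise ExcludedRead(f"{a.read_id}: {a.exclusion}")
    can = s.window_u(s.can_u, w.es_lo, w.es_hi)
    pre = s.window_u(s.pre_u, w.es_lo, w.es_hi)
    if a.u_obs == can:
        return ReadClass.FULLY_EDITED
    if a.u_obs == pre:
        return ReadClass.PRE_EDITED
    return ReadClass.PARTIALLY_EDITED


def call_junction(a: AlignedRead, s: EditingScaffold, w: AmpliconWindow) -> JunctionCall:
    """Call the junction boundaries of a read.

    jss: smallest window ES whose U count differs from the canonical
    sequence.  jes: largest window ES whose U count differs from the
    pre-edited sequence.  Pre-edited and fully edited reads have no
    junction (both None).
    """
    if a.excluded:
        raise ExcludedRead(f"{a.read_id}: {a.exclusion}")
    cls = classify_read(a, s, w)
    if cls is not ReadClass.PARTIALLY_EDITED:
        return JunctionCall(None, None)
    assert a.u_obs is not None
    can = s.window_u(s.can_u, w.es_lo, w.es_hi)
    pre = s.window_u(s.pre_u, w.es_lo, w.es_hi)
    jss = next(
        w.es_lo + i for i, (u, c) in enumerate(zip(a.u_obs, can)) if u != c
    )
    jes = next(
        w.es_hi - i
        for i, (u, p) in enumerate(zip(reversed(a.u_obs), reversed(pre)))
        if u != p
    )
    return JunctionCall(jss, jes)


def process_read(
    s: EditingScaffold,
    w: AmpliconWindow,
    read: str,
    read_id: str = "read",
    *,
    min_length: int = 0,
    primer_mismatches: int = 0,
) -> ReadCall:
    """Align, classify and junction-call one read; never raises."""
    a = align_read(
        s, w, read, read_id,
        min_length=min_length, primer_mismatches=primer_mismatches,
    )
    if a.excluded:
        return ReadCall(read_id, ReadClass.EXCLUDED, None, None, None, a.exclusion)
    cls = classify_read(a, s, w)
    jc = call_junction(a, s, w)
    return ReadCall(read_id, cls, jc.jss, jc.jes, a.u_obs, None)


def process_reads(
    s: EditingScaffold,
    w: AmpliconWindow,
    reads: Iterable[tuple[str, str]],
    *,
    min_length: int = 0,
    primer_mismatches: int = 0,
) -> list[ReadCall]:
    """Process an iterable of (read_id, sequence) pairs."""
    return [
        process_read(
            s, w, seq, rid,
            min_length=min_length, primer_mismatches=primer_mismatches,
        )
        for rid, seq in reads
    ]
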