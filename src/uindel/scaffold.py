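"""Editing-site coordinate system for U-indel edited transcripts.

Kinetoplastid mitochondrial mRNAs are edited by insertion and deletion of
uridines at *editing sites* (ES): the gaps between consecutive non-U
residues of the transcript "backbone".  Because the pre-edited and fully
edited versions of a transcript differ only in their U content, both share
the same backbone, and any editing intermediate is fully described by one
integer per ES — the number of U's it carries there.

This module builds that coordinate system from a pre-edited / fully-edited
sequence pair and restricts it to the ES window covered by an amplicon's
primer pair.  ES indices are 1-based and numbered from the 3' end (ES1 is
the gap between the two 3'-most backbone residues), matching the 3'->5'
direction in which editing progresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

__all__ = [
    "UindelError",
    "BackboneMismatch",
    "EmptyInput",
    "LengthMismatch",
    "InvalidAlphabet",
    "PrimerNotFound",
    "AmbiguousPrimer",
    "InvalidPrimer",
    "EditingScaffold",
    "AmpliconWindow",
    "build_scaffold",
    "reconstruct_sequence",
    "restrict_to_amplicon",
    "full_window",
    "load_reference_pair",
    "write_scaffold_tsv",
]


class UindelError(Exception):
    """Base class for all errors raised by this package."""


class BackboneMismatch(UindelError):
    """The two reference sequences do not share a non-T backbone."""


class EmptyInput(UindelError):
    """A reference sequence has fewer than two non-T residues."""


class LengthMismatch(UindelError):
    """A U-count vector does not match the scaffold's ES count."""


class InvalidAlphabet(UindelError):
    """A reference contains characters outside A/C/G/T/U."""


class PrimerNotFound(UindelError):
    pass


class AmbiguousPrimer(UindelError):
    """A primer matches more than one location on the reference."""


class InvalidPrimer(UindelError):
    """A primer is empty or not anchored on a backbone residue."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def clean_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate the DNA alphabet.

    Degenerate IUPAC codes (N, R, Y, ...) are rejected rather than guessed.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise InvalidAlphabet(
            f"{context} contains non-ACGT characters: {sorted(bad)!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _decompose(seq: str) -> tuple[str, list[int]]:
    """Split a T-containing sequence into (backbone, per-gap T-run lengths).

    Terminal T's (before the first / after the last non-T residue) are
    trimmed: editing sites are defined *between* backbone residues, and
    real amplicons are delimited by primers in never-edited sequence.
    Runs are returned 5'->3' (run[k] sits between backbone[k] and
    backbone[k+1]).
    """
    core = seq.strip("T")
    backbone = []
    runs: list[int] = []
    run = 0
    for ch in core:
        if ch == "T":
            run += 1
        else:
            if backbone:
                runs.append(run)
            backbone.append(ch)
            run = 0
    return "".join(backbone), runs


@dataclass(frozen=True)
class EditingScaffold:
    """Shared backbone plus per-ES U counts of an editing reference pair.

    ``pre_u`` and ``can_u`` are indexed by ES: element 0 is ES1 (3'-most
    gap), element ``n_es - 1`` is the 5'-most gap.
    """

    name: str
    backbone: str
    pre_u: tuple[int, ...]
    can_u: tuple[int, ...]

    @property
    def n_es(self) -> int:
        return len(self.backbone) - 1

    def es_to_gap(self, es: int) -> int:
        """Map ES index (1-based, from 3') to 5'->3' gap index (0-based)."""
        if not 1 <= es <= self.n_es:
            raise IndexError(f"ES{es} outside 1..{self.n_es}")
        return self.n_es - es

    def window_u(self, u: Sequence[int], es_lo: int, es_hi: int) -> tuple[int, ...]:
        """Slice a full-length ES-indexed vector down to an inclusive window."""
        return tuple(u[es_lo - 1 : es_hi])


def build_scaffold(pre_seq: str, edited_seq: str, name: str = "transcript") -> EditingScaffold:
    """Derive the ES coordinate system from a pre-edited/fully-edited pair.

    Both sequences are reduced to their non-T residue strings; these must
    be identical (a true editing pair), and the T-run lengths at each gap
    become the pre-edited and canonical U counts.

    Raises
    ------
    BackboneMismatch
        If the non-T residue strings differ.
    EmptyInput
        If either sequence has fewer than two non-T residues.
    """
    pre = clean_sequence(pre_seq, context="pre-edited reference")
    edt = clean_sequence(edited_seq, context="fully edited reference")
    bb_pre, runs_pre = _decompose(pre)
    bb_edt, runs_edt = _decompose(edt)
    if len(bb_pre) < 2 or len(bb_edt) < 2:
        raise EmptyInput("reference has fewer than 2 non-T residues")
    if bb_pre != bb_edt:
        raise BackboneMismatch(
            f"non-T backbones differ ({bb_pre[:30]}... vs {bb_edt[:30]}...): "
            "references are not a pre-edited/fully-edited pair"
        )
    # gap runs are 5'->3'; ES vectors are numbered from the 3' end
    return EditingScaffold(
        name=name,
        backbone=bb_pre,
        pre_u=tuple(reversed(runs_pre)),
        can_u=tuple(reversed(runs_edt)),
    )


def reconstruct_sequence(s: EditingScaffold, u: Sequence[int]) -> str:
    """Interleave the backbone with T-runs of length ``u[es]`` at each gap.

    Inverse of :func:`build_scaffold` for either reference vector, and the
    renderer for arbitrary editing intermediates.
    """
    if len(u) != s.n_es:
        raise LengthMismatch(f"u has length {len(u)}, scaffold has {s.n_es} ES")
    if any(x < 0 for x in u):
        raise LengthMismatch("u counts must be non-negative")
    parts = [s.backbone[0]]
    for gap in range(s.n_es):
        es = s.n_es - gap  # gap index 5'->3' -> ES from 3' end
        parts.append("T" * u[es - 1])
        parts.append(s.backbone[gap + 1])
    return "".join(parts)


@dataclass(frozen=True)
class AmpliconWindow:
    """ES range delimited by an amplicon primer pair.

    ``fwd_end`` / ``rev_start`` are 0-based backbone residue indices of the
    last residue covered by the forward primer footprint and the first
    residue covered by the reverse footprint; the ES in ``[es_lo, es_hi]``
    are exactly the gaps strictly between those anchors.
    """

    fwd_primer: str
    rev_primer: str
    es_lo: int
    es_hi: int
    fwd_end: int
    rev_start: int

    @property
    def n_es(self) -> int:
        return self.es_hi - self.es_lo + 1

    def es_range(self) -> range:
        return range(self.es_lo, self.es_hi + 1)


def _primer_footprint(
    s: EditingScaffold, primer: str, pre_seq: str, res_pos: list[int], label: str
) -> tuple[int, int]:
    """Locate a primer on the pre-edited rendering; return the backbone
    residue span (0-based, inclusive) it covers."""
    if not primer:
        raise InvalidPrimer(f"{label} primer is empty")
    first = pre_seq.find(primer)
    if first < 0:
        raise PrimerNotFound(f"{label} primer {primer!r} not found on reference")
    if pre_seq.find(primer, first + 1) >= 0:
        raise AmbiguousPrimer(f"{label} primer {primer!r} matches more than once")
    lo, hi = first, first + len(primer) - 1
    covered = [i for i, p in enumerate(res_pos) if lo <= p <= hi]
    if not covered:
        raise InvalidPrimer(f"{label} primer {primer!r} covers no backbone residue")
    return covered[0], covered[-1]


def restrict_to_amplicon(s: EditingScaffold, fwd: str, rev: str) -> AmpliconWindow:
    """Build the amplicon ES window delimited by a primer pair.

    Primers are given as sense-strand sequences.  The forward primer is
    located on the pre-edited rendering of the transcript (it targets
    pre-edited or never-edited sequence); the reverse primer likewise.
    The window is the maximal inclusive ES range strictly between the two
    primer footprints; read classification ("fully edited up to the
    forward primer") is evaluated only over this range.  Each primer must
    end (forward) / begin (reverse) on a backbone residue so the window
    boundary is well defined.
    """
    fwd = clean_sequence(fwd, context="forward primer")
    rev = clean_sequence(rev, context="reverse primer")
    pre_seq = reconstruct_sequence(s, s.pre_u)
    # nucleotide position of each backbone residue in the pre-edited rendering
    res_pos = [i for i, ch in enumerate(pre_seq) if ch != "T"]
    if fwd[-1] == "T":
        raise InvalidPrimer("forward primer must end on a non-T residue")
    if rev[0] == "T":
        raise InvalidPrimer("reverse primer must start on a non-T residue")
    _, b = _primer_footprint(s, fwd, pre_seq, res_pos, "forward")
    c, _ = _primer_footprint(s, rev, pre_seq, res_pos, "reverse")
    if c <= b:
        raise InvalidPrimer("reverse primer footprint does not lie 3' of forward primer")
    m = s.n_es
    es_lo = m + 1 - c  # gap index c (between residues c-1 and c)
    es_hi = m - b  # gap index b+1
    if es_lo > es_hi:
        raise InvalidPrimer("primer footprints are adjacent: no ES between them")
    return AmpliconWindow(
        fwd_primer=fwd, rev_primer=rev, es_lo=es_lo, es_hi=es_hi, fwd_end=b, rev_start=c
    )


def full_window(s: EditingScaffold) -> AmpliconWindow:
    """Window spanning every ES, with single-residue terminal 'primers'.

    Convenience for toy scaffolds and simulations that cover the whole
    molecule: the first and last backbone residues act as minimal primer
    anchors, so all ES fall strictly between the footprints.
    """
    return AmpliconWindow(
        fwd_primer=s.backbone[0],
        rev_primer=s.backbone[-1],
        es_lo=1,
        es_hi=s.n_es,
        fwd_end=0,
        rev_start=s.n_es,
    )


def render_amplicon(s: EditingScaffold, w: AmpliconWindow, u_window: Sequence[int]) -> str:
    """Render a full amplicon read: fwd primer + edited insert + rev primer.

    ``u_window`` is ES-indexed over ``w.es_lo..w.es_hi`` (element 0 =
    ``es_lo``).  The insert runs from the gap just after the forward
    footprint through the gap just before the reverse footprint.
    """
    if len(u_window) != w.n_es:
        raise LengthMismatch(
            f"u_window has length {len(u_window)}, window spans {w.n_es} ES"
        )
    m = s.n_es
    parts = [w.fwd_primer]
    for res in range(w.fwd_end + 1, w.rev_start + 1):
        es = m + 1 - res  # gap between residues res-1 and res
        parts.append("T" * u_window[es - w.es_lo])
        if res < w.rev_start:
            parts.append(s.backbone[res])
    parts.append(w.rev_primer)
    return "".join(parts)


# ---------------------------------------------------------------------------
# reference I/O

def load_reference_pair(fasta_path: str | Path, name: str) -> EditingScaffold:
    """Build a scaffold from a multi-FASTA holding ``<name>_preedited`` and
    ``<name>_edited`` records."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        pre = records[f"{name}_preedited"]
        edt = records[f"{name}_edited"]
    except KeyError as e:
        raise UindelError(
            f"reference FASTA {fasta_path} lacks record {e.args[0]!r}"
        ) from None
    return build_scaffold(pre, edt, name=name)


def write_scaffold_tsv(s: EditingScaffold, path: str | Path) -> None:
    """Export per-ES U counts (columns: es, pre_u, can_u) for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# scaffold\t{s.name}\tn_es={s.n_es}\n")
        fh.write("es\tpre_u\tcan_u\n")
        for es in range(1, s.n_es + 1):
            fh.write(f"{es}\t{s.pre_u[es - 1]}\t{s.can_u[es - 1]}\n")
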