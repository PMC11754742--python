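"""Synthetic amplicon reads with the population structure of U-indel editing.

The generator emulates what a real amplicon library from a progressively
3'->5' edited transcript looks like: a mixture of pre-edited reads, fully
edited reads, and partially edited intermediates that carry canonical
editing over their 3' block, pre-edited sequence 5' of the leading edge,
and a short *junction* of non-canonical U counts in between.  Where the
junction ends (the JES) is drawn from a per-ES pause-weight distribution,
so condition-dependent pause sites can be planted and later recovered by
the differential analysis.

Two layers are exposed:

* :func:`draw_read_states` — vectorized sampling of per-read U-count
  vectors and their ground-truth class/JSS/JES (no sequence rendering);
* :func:`simulate_read` / :func:`simulate_experiment` — full rendering to
  primer-flanked sequences with a substitution-error model, FASTQ output,
  sample sheet and truth table.

Error model: an error event on a primer base or backbone residue
substitutes it with a random different base, which breaks exact backbone
or primer matching and gets the read excluded downstream.  An error event
inside a U (T) run instead perturbs the run length by +-1 — the realistic
failure mode that creates spurious non-canonical U counts without
triggering exclusion.  With per-base rate eps the expected exclusion
fraction is therefore exactly 1 - (1-eps)^(primer bases + backbone
residues between the primers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .reads import ReadClass
from .scaffold import AmpliconWindow, EditingScaffold, UindelError, render_amplicon

__all__ = [
    "ConfigError",
    "SimConfig",
    "ReadStates",
    "draw_read_states",
    "simulate_read",
    "simulate_sample",
    "simulate_experiment",
    "profile_from_states",
    "synthetic_reference_pair",
]


class ConfigError(UindelError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated sample.

    frac_pre / frac_full
        Fractions of reads that are pre-edited / fully edited over the
        amplicon window; the remainder are partially edited intermediates.
    pause_weights
        Per-ES multiplier on the probability that editing halts with its
        JES at that ES (unlisted ES have weight 1); a planted pause site
        is an entry like ``{121: 5.0}``.
    junction_len_mean
        Mean junction length in ES of the geometric length distribution
        (support 0, 1, 2, ...; 0 is an empty junction — a clean pause
        after a block of purely canonical editing).
    noncanonical_extra
        Junction-site U counts are uniform over 0..max(pre_u, can_u) +
        this margin, excluding values that would make the site canonical
        (and, at the JES itself, the pre-edited value, so the truth JES is
        well defined).
    error_rate
        Per-base substitution-error probability (see module docstring).
    """

    n_reads: int = 20_000
    frac_pre: float = 0.30
    frac_full: float = 0.10
    pause_weights: Mapping[int, float] = field(default_factory=dict)
    junction_len_mean: float = 2.0
    noncanonical_extra: int = 2
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        if not (0 <= self.frac_pre <= 1 and 0 <= self.frac_full <= 1):
            raise ConfigError("class fractions must lie in [0, 1]")
        if self.frac_pre + self.frac_full > 1 + 1e-12:
            raise ConfigError("frac_pre + frac_full must be <= 1")
        if any(v <= 0 for v in self.pause_weights.values()):
            raise ConfigError("pause weights must be positive")
        if self.junction_len_mean < 0:
            raise ConfigError("junction_len_mean must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ReadStates:
    """Ground-truth editing states for a batch of simulated reads.

    ``u`` has one row per read, columns ES ``es_lo..es_hi``.  ``jss`` and
    ``jes`` are -1 for reads without a junction (pre-/fully edited).
    """

    u: np.ndarray
    read_class: np.ndarray  # array of str (ReadClass values)
    jss: np.ndarray
    jes: np.ndarray
    es_lo: int


def _truth_from_u(u: np.ndarray, pre: np.ndarray, can: np.ndarray, es_lo: int):
    """Definitional scan: class, JSS, JES for each row of a u matrix."""
    n, width = u.shape
    diff_can = u != can
    diff_pre = u != pre
    any_can = diff_can.any(axis=1)
    any_pre = diff_pre.any(axis=1)
    cls = np.full(n, ReadClass.PARTIALLY_EDITED.value, dtype=object)
    cls[~any_can] = ReadClass.FULLY_EDITED.value
    cls[any_can & ~any_pre] = ReadClass.PRE_EDITED.value
    partial = any_can & any_pre
    jss = np.full(n, -1, dtype=np.int64)
    jes = np.full(n, -1, dtype=np.int64)
    jss[partial] = es_lo + diff_can[partial].argmax(axis=1)
    jes[partial] = es_lo + width - 1 - diff_pre[partial, ::-1].argmax(axis=1)
    return cls, jss, jes


def draw_read_states(
    s: EditingScaffold,
    w: AmpliconWindow,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> ReadStates:
    """Draw per-read U-count vectors (no sequences) with ground truth.

    Partially edited reads get a pause site (their JES) from the
    pause-weighted categorical over the window, a geometric junction
    length, canonical U counts 3' of the junction and pre-edited counts
    5' of it, and junction-site counts from the non-canonical
    distribution.  Truth labels are recomputed from the finished vectors
    by the definitional scan, so they are exact even at edge cases (e.g.
    a junction collapsing onto the window boundary).
    """
    cfg.validate()
    n = cfg.n_reads if n_reads is None else n_reads
    es = np.arange(w.es_lo, w.es_hi + 1)
    width = es.size
    pre = np.array(s.window_u(s.pre_u, w.es_lo, w.es_hi), dtype=np.int64)
    can = np.array(s.window_u(s.can_u, w.es_lo, w.es_hi), dtype=np.int64)
    if n == 0:
        empty = np.empty((0, width), dtype=np.int64)
        return ReadStates(empty, np.empty(0, dtype=object),
                          np.empty(0, np.int64), np.empty(0, np.int64), w.es_lo)

    r = rng.random(n)
    is_pre = r < cfg.frac_pre
    is_full = (~is_pre) & (r < cfg.frac_pre + cfg.frac_full)
    is_part = ~(is_pre | is_full)
    u = np.tile(pre, (n, 1))
    u[is_full] = can

    n_part = int(is_part.sum())
    if n_part:
        weights = np.array([cfg.pause_weights.get(int(e), 1.0) for e in es])
        weights = weights / weights.sum()
        jes_t = es[rng.choice(width, size=n_part, p=weights)]
        # geometric junction length on {0,1,...} with the configured mean
        p_len = 1.0 / (1.0 + cfg.junction_len_mean)
        length = rng.geometric(p_len, size=n_part) - 1
        # an empty junction needs pre != can at its JES; force length >= 1 there
        editable = pre != can
        needs_sites = (length == 0) & ~editable[jes_t - w.es_lo]
        length[needs_sites] = 1
        jss_t = np.maximum(jes_t - length + 1, w.es_lo)

        cols = es[None, :]
        up = u[is_part]
        canonical_block = cols < jss_t[:, None]
        up[canonical_block] = np.broadcast_to(can, up.shape)[canonical_block]
        junction = (cols >= jss_t[:, None]) & (cols <= jes_t[:, None])
        at_jes = cols == jes_t[:, None]
        hi = np.maximum(pre, can) + cfg.noncanonical_extra  # inclusive upper bound
        draws = np.floor(rng.random(up.shape) * (hi + 1)).astype(np.int64)
        # resample draws that hit the excluded values (canonical anywhere in
        # the junction; also the pre-edited value at the JES itself)
        for _ in range(200):
            bad = junction & ((draws == can) | (at_jes & (draws == pre)))
            if not bad.any():
                break
            redraw = np.floor(rng.random(int(bad.sum())) * (hi + 1)[
                np.broadcast_to(np.arange(up.shape[1]), up.shape)[bad]
            ]).astype(np.int64)
            draws[bad] = redraw
        up[junction] = draws[junction]
        u[is_part] = up

    cls, jss, jes = _truth_from_u(u, pre, can, w.es_lo)
    return ReadStates(u, cls, jss, jes, w.es_lo)


def _render_with_errors(
    s: EditingScaffold,
    w: AmpliconWindow,
    u_true: Sequence[int],
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...], bool]:
    """Render one read, applying the substitution-error model.

    Returns (sequence, rendered U counts, whether an error hit a primer
    base or backbone residue).
    """
    u_obs = list(u_true)
    if error_rate > 0:
        total_t = int(sum(u_true))
        if total_t:
            hits = rng.binomial(total_t, error_rate)
            if hits:
                cum = np.cumsum(u_true)
                for _ in range(hits):
                    pos = int(rng.integers(total_t))
                    idx = int(np.searchsorted(cum, pos, side="right"))
                    step = 1 if rng.random() < 0.5 else -1
                    u_obs[idx] = max(0, u_obs[idx] + step)
    seq = render_amplicon(s, w, u_obs)
    err_backbone = False
    if error_rate > 0:
        # positions of primer bases and backbone residues in the rendering
        eligible = list(range(len(w.fwd_primer)))
        pos = len(w.fwd_primer)
        m = s.n_es
        for res in range(w.fwd_end + 1, w.rev_start):
            es_idx = m - res + 1  # gap before this residue
            pos += u_obs[es_idx - w.es_lo]
            eligible.append(pos)
            pos += 1
        eligible.extend(range(len(seq) - len(w.rev_primer), len(seq)))
        hits = rng.binomial(len(eligible), error_rate)
        if hits:
            err_backbone = True
            chars = list(seq)
            where = rng.choice(len(eligible), size=min(hits, len(eligible)),
                               replace=False)
            for wi in where:
                p = eligible[int(wi)]
                alt = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alt[int(rng.integers(3))]
            seq = "".join(chars)
    return seq, tuple(u_obs), err_backbone


def simulate_read(
    s: EditingScaffold,
    w: AmpliconWindow,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Draw and render a single read; returns (sequence, truth record)."""
    states = draw_read_states(s, w, cfg, rng, n_reads=1)
    u_true = tuple(int(x) for x in states.u[0])
    seq, u_obs, err = _render_with_errors(s, w, u_true, cfg.error_rate, rng)
    truth = {
        "read_class": str(states.read_class[0]),
        "jss": int(states.jss[0]) if states.jss[0] >= 0 else None,
        "jes": int(states.jes[0]) if states.jes[0] >= 0 else None,
        "u_true": u_true,
        "u_rendered": u_obs,
        "error_on_backbone": err,
    }
    return seq, truth


def simulate_sample(
    s: EditingScaffold,
    w: AmpliconWindow,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Simulate one sample: list of (read_id, sequence) plus truth records."""
    states = draw_read_states(s, w, cfg, rng)
    reads: list[tuple[str, str]] = []
    truths: list[dict] = []
    for i in range(states.u.shape[0]):
        u_true = tuple(int(x) for x in states.u[i])
        seq, u_obs, err = _render_with_errors(s, w, u_true, cfg.error_rate, rng)
        rid = f"{read_prefix}_{i:06d}"
        reads.append((rid, seq))
        truths.append(
            {
                "read_id": rid,
                "read_class": str(states.read_class[i]),
                "jss": int(states.jss[i]) if states.jss[i] >= 0 else None,
                "jes": int(states.jes[i]) if states.jes[i] >= 0 else None,
                "u_true": ",".join(map(str, u_true)),
                "error_on_backbone": int(err),
            }
        )
    return reads, truths


def simulate_experiment(
    s: EditingScaffold,
    w: AmpliconWindow,
    cfg_by_condition: Mapping[str, SimConfig],
    *,
    replicates: int = 2,
    outdir: str | Path,
    master_seed: int = 0,
) -> Path:
    """Write a full two-condition experiment to disk.

    One FASTQ per replicate (constant Q30 placeholder qualities), a truth
    TSV joined on read_id, and a sample sheet TSV (sample_id, condition,
    replicate, path).  Per-replicate RNG streams are spawned
    deterministically from the master seed, so a rerun is byte-identical.
    Returns the sample-sheet path.
    """
    if replicates < 1:
        raise ConfigError("need >= 1 replicate per condition")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet_path = outdir / "samples.tsv"
    truth_path = outdir / "truth.tsv"
    with open(sheet_path, "w") as sheet, open(truth_path, "w") as truth:
        sheet.write("sample_id\tcondition\treplicate\tpath\n")
        truth.write("read_id\tsample_id\tread_class\tjss\tjes\tu_true\terror_on_backbone\n")
        for ci, (cond, cfg) in enumerate(cfg_by_condition.items()):
            for rep in range(1, replicates + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(ci, rep))
                )
                sample_id = f"{cond}_{rep}"
                reads, truths = simulate_sample(
                    s, w, cfg, rng, read_prefix=sample_id
                )
                fq = outdir / f"{sample_id}.fastq"
                with open(fq, "w") as out:
                    for rid, seq in reads:
                        out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                sheet.write(f"{sample_id}\t{cond}\t{rep}\t{fq.name}\n")
                for t in truths:
                    truth.write(
                        f"{t['read_id']}\t{sample_id}\t{t['read_class']}\t"
                        f"{'' if t['jss'] is None else t['jss']}\t"
                        f"{'' if t['jes'] is None else t['jes']}\t"
                        f"{t['u_true']}\t{t['error_on_backbone']}\n"
                    )
    return sheet_path


def profile_from_states(
    states: ReadStates,
    *,
    sample_id: str = "sample",
    condition: str = "",
    replicate: int = 1,
    es_hi: int | None = None,
    with_seq_table: bool = True,
):
    """Build a normalized :class:`~uindel.pause.SampleProfile` directly from
    ground-truth read states (no sequence rendering / realignment).

    Equivalent to rendering the states at error_rate 0 and pushing the
    reads through alignment and normalization — the sequence layer is an
    exact round trip there — but vectorized, so large replicate grids for
    calibration studies stay cheap.
    """
    import pandas as pd

    from .pause import NORM_TOTAL, EmptySample, SampleProfile

    n = states.u.shape[0]
    if n == 0:
        raise EmptySample(f"{sample_id}: no reads")
    weight = NORM_TOTAL / n
    es_lo = states.es_lo
    if es_hi is None:
        es_hi = es_lo + states.u.shape[1] - 1

    class_counts = {
        ReadClass.PRE_EDITED: 0.0,
        ReadClass.PARTIALLY_EDITED: 0.0,
        ReadClass.FULLY_EDITED: 0.0,
    }
    vals, counts = np.unique(states.read_class, return_counts=True)
    for v, c in zip(vals, counts):
        class_counts[ReadClass(v)] = float(c) * weight

    with_jes = states.jes >= 0
    jes_hist = {}
    if with_jes.any():
        es_vals, es_counts = np.unique(states.jes[with_jes], return_counts=True)
        jes_hist = {int(e): float(c) * weight for e, c in zip(es_vals, es_counts)}

    if with_seq_table:
        uniq, first, inv = np.unique(
            states.u, axis=0, return_index=True, return_inverse=True
        )
        counts = np.bincount(inv)
        seq_table = pd.DataFrame(
            {
                "u_vector": [",".join(map(str, row)) for row in uniq],
                "read_class": [str(states.read_class[i]) for i in first],
                "jss": [int(states.jss[i]) if states.jss[i] >= 0 else None
                        for i in first],
                "jes": [int(states.jes[i]) if states.jes[i] >= 0 else None
                        for i in first],
                "count_norm": counts * weight,
            }
        ).sort_values("count_norm", ascending=False, kind="mergesort",
                      ignore_index=True)
    else:
        seq_table = pd.DataFrame(
            columns=["u_vector", "read_class", "jss", "jes", "count_norm"]
        )

    return SampleProfile(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        es_lo=es_lo,
        es_hi=es_hi,
        n_reads=n,
        n_excluded=0,
        exclusion_counts={},
        class_counts=class_counts,
        jes_hist=jes_hist,
        seq_table=seq_table,
    )


def synthetic_reference_pair(
    n_es: int = 150,
    *,
    seed: int = 20_240_901,
    never_edited_flank: int = 16,
    max_insert: int = 12,
) -> tuple[str, str]:
    """Deterministic synthetic pre-edited / fully-edited reference pair.

    A stand-in editing pair with the broad statistics of a pan-edited
    mitochondrial transcript: a random A/C/G backbone, never-edited flanks
    at both ends (primer landing sites), sparse U's in the pre-edited
    sequence and frequent multi-U insertions in the canonical sequence.
    Purely synthetic; fixed seed makes it reproducible.
    """
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(list("ACG"), size=n_es + 1))
    pre_u = np.zeros(n_es, dtype=int)
    can_u = np.zeros(n_es, dtype=int)
    lo = never_edited_flank  # ES1..lo and the top flank stay never-edited
    hi = n_es - never_edited_flank
    for i in range(lo, hi):
        pre_u[i] = rng.choice([0, 0, 0, 1, 1, 2, 3])
        if rng.random() < 0.85:  # most sites are insertion sites
            can_u[i] = int(rng.integers(0, max_insert + 1))
        else:
            can_u[i] = 0
    # never-edited flanks share whatever U content the pre-edited strand has
    can_u[:lo] = pre_u[:lo]
    can_u[hi:] = pre_u[hi:]
    from .scaffold import EditingScaffold, reconstruct_sequence

    s = EditingScaffold("synthetic", backbone, tuple(pre_u), tuple(can_u))
    return reconstruct_sequence(s, s.pre_u), reconstruct_sequence(s, s.can_u)
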