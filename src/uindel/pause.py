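"""Sample-level junction statistics and differential pause-site detection.

Reads surviving the exclusion filter are normalized to 100,000 counts per
sample so relative abundances compare across libraries of different depth.
The per-sample JES histogram (normalized read count whose junction ends at
each ES) is the primary profile; exacerbated junction end sites (EJES) are
the ES whose JES counts are elevated in a perturbed condition relative to
control by fold-change and read-floor criteria evaluated across replicates.

Normalized counts are carried as exact non-integer weights internally;
conservation (class totals and sequence-table totals each summing to
100,000) holds pre-rounding, and reports round to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reads import ExclusionReason, ReadCall, ReadClass
from .scaffold import AmpliconWindow, EditingScaffold, UindelError

__all__ = [
    "EmptySample",
    "EmptyWindow",
    "ReplicateMismatch",
    "SampleProfile",
    "TTestResult",
    "NORM_TOTAL",
    "normalize_sample",
    "detect_ejes",
    "filter_window_sequences",
    "percent_jes_in_window",
    "compare_conditions",
    "render_sequence_alignment",
]

NORM_TOTAL = 100_000.0


class EmptySample(UindelError):
    """A sample contains no non-excluded reads to normalize."""


class EmptyWindow(UindelError):
    """An ES window lies outside the profiled range (or is inverted)."""


class ReplicateMismatch(UindelError):
    """A condition has fewer replicates than the analysis requires."""


@dataclass(frozen=True)
class SampleProfile:
    """Normalized editing profile of one sequencing sample.

    ``jes_hist`` maps ES -> normalized count of reads whose JES is that ES
    (only partially edited reads have a JES).  ``seq_table`` has one row
    per distinct observed U-count vector with its class, junction call and
    normalized count; its counts sum to 100,000 exactly (pre-rounding).
    """

    sample_id: str
    condition: str
    replicate: int
    es_lo: int
    es_hi: int
    n_reads: int
    n_excluded: int
    exclusion_counts: Mapping[str, int]
    class_counts: Mapping[ReadClass, float]
    jes_hist: Mapping[int, float]
    seq_table: pd.DataFrame

    @property
    def n_used(self) -> int:
        return self.n_reads - self.n_excluded


def normalize_sample(
    calls: Sequence[ReadCall],
    *,
    sample_id: str = "sample",
    condition: str = "",
    replicate: int = 1,
    es_lo: int,
    es_hi: int,
) -> SampleProfile:
    """Normalize one sample's read calls to 100,000 counts.

    Every non-excluded read receives weight ``100000 / n_used``; excluded
    reads are tallied but carry no weight.  Raises :class:`EmptySample`
    if no read survives exclusion.
    """
    n_reads = len(calls)
    used = [c for c in calls if c.read_class is not ReadClass.EXCLUDED]
    if not used:
        raise EmptySample(f"{sample_id}: no non-excluded reads")
    weight = NORM_TOTAL / len(used)

    exclusion_counts = {r.value: 0 for r in ExclusionReason}
    for c in calls:
        if c.exclusion is not None:
            exclusion_counts[c.exclusion.value] += 1

    class_counts: dict[ReadClass, float] = {
        ReadClass.PRE_EDITED: 0.0,
        ReadClass.PARTIALLY_EDITED: 0.0,
        ReadClass.FULLY_EDITED: 0.0,
    }
    jes_raw: dict[int, int] = {}
    seq_raw: dict[tuple[int, ...], list] = {}
    for c in used:
        class_counts[c.read_class] += weight
        if c.jes is not None:
            jes_raw[c.jes] = jes_raw.get(c.jes, 0) + 1
        assert c.u_obs is not None
        row = seq_raw.get(c.u_obs)
        if row is None:
            seq_raw[c.u_obs] = [c.read_class, c.jss, c.jes, 1]
        else:
            row[3] += 1

    seq_table = pd.DataFrame(
        {
            "u_vector": [",".join(map(str, u)) for u in seq_raw],
            "read_class": [str(v[0]) for v in seq_raw.values()],
            "jss": [v[1] for v in seq_raw.values()],
            "jes": [v[2] for v in seq_raw.values()],
            "count_norm": [v[3] * weight for v in seq_raw.values()],
        }
    ).sort_values("count_norm", ascending=False, kind="mergesort", ignore_index=True)

    return SampleProfile(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        es_lo=es_lo,
        es_hi=es_hi,
        n_reads=n_reads,
        n_excluded=n_reads - len(used),
        exclusion_counts=exclusion_counts,
        class_counts=class_counts,
        jes_hist={es: n * weight for es, n in sorted(jes_raw.items())},
        seq_table=seq_table,
    )


def _fold_change(mean_num: float, mean_den: float) -> float:
    """Fold change with a 1-normalized-read pseudocount on zero denominators."""
    if mean_den == 0.0:
        return (mean_num + 1.0) / (mean_den + 1.0)
    return mean_num / mean_den


def _check_replicates(profiles: Sequence[SampleProfile], label: str, minimum: int) -> None:
    if len(profiles) < minimum:
        raise ReplicateMismatch(
            f"{label} condition has {len(profiles)} replicate(s); need >= {minimum}"
        )


def detect_ejes(
    induced: Sequence[SampleProfile],
    uninduced: Sequence[SampleProfile],
    *,
    fold_min: float = 3.0,
    min_norm_reads: float = 100.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Detect exacerbated junction end sites between two conditions.

    An ES passes iff the mean normalized JES count in the induced
    (perturbed) condition is at least ``fold_min`` times the uninduced
    mean AND at least ``min_replicates`` induced replicates individually
    carry >= ``min_norm_reads`` normalized JES reads there.  The full
    per-ES table is returned regardless of pass status, one row per ES of
    the profiled window, with per-replicate counts, means, fold change and
    the pass flag.
    """
    if min_replicates >= 2:
        _check_replicates(induced, "induced", 2)
        _check_replicates(uninduced, "uninduced", 2)
    elif not induced or not uninduced:
        raise ReplicateMismatch("both conditions need at least one replicate")

    es_lo = induced[0].es_lo
    es_hi = induced[0].es_hi
    es_index = list(range(es_lo, es_hi + 1))
    ind = np.array([[p.jes_hist.get(es, 0.0) for es in es_index] for p in induced])
    uni = np.array([[p.jes_hist.get(es, 0.0) for es in es_index] for p in uninduced])
    mean_ind = ind.mean(axis=0)
    mean_uni = uni.mean(axis=0)
    fold = np.array([_fold_change(a, b) for a, b in zip(mean_ind, mean_uni)])
    reps_over = (ind >= min_norm_reads).sum(axis=0)
    passed = (fold >= fold_min) & (reps_over >= min_replicates)

    table = pd.DataFrame({"es": es_index})
    for i, p in enumerate(induced):
        table[f"induced_{p.sample_id}"] = ind[i]
    for i, p in enumerate(uninduced):
        table[f"uninduced_{p.sample_id}"] = uni[i]
    table["mean_induced"] = mean_ind
    table["mean_uninduced"] = mean_uni
    table["fold_change"] = fold
    table["induced_reps_over_floor"] = reps_over
    table["ejes"] = passed
    return table


def _mean_seq_counts(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Per-distinct-u-vector mean normalized count across replicates.

    A vector absent from a replicate contributes 0 to the mean.
    """
    frames = [
        p.seq_table[["u_vector", "read_class", "jss", "jes", "count_norm"]]
        for p in profiles
    ]
    cat = pd.concat(frames, ignore_index=True)
    agg = cat.groupby(["u_vector", "read_class"], as_index=False).agg(
        jss=("jss", "first"), jes=("jes", "first"), total=("count_norm", "sum")
    )
    agg["mean_count"] = agg["total"] / len(profiles)
    return agg.drop(columns="total")


def filter_window_sequences(
    induced: Sequence[SampleProfile],
    uninduced: Sequence[SampleProfile],
    window: tuple[int, int],
    *,
    fold_min: float = 3.0,
    min_reads: float = 100.0,
) -> pd.DataFrame:
    """Distinct sequences pausing in a window, enriched in the perturbed condition.

    Returns the distinct U-count vectors whose JES lies inside the
    inclusive ES ``window``, whose mean normalized count in the induced
    (depleted) condition is >= ``min_reads``, and whose induced/uninduced
    mean ratio is >= ``fold_min``; sorted by induced count descending.
    """
    lo, hi = window
    p0 = induced[0] if induced else uninduced[0]
    if lo > hi or hi < p0.es_lo or lo > p0.es_hi:
        raise EmptyWindow(f"ES window [{lo},{hi}] outside profiled range "
                          f"[{p0.es_lo},{p0.es_hi}]")
    mi = _mean_seq_counts(induced).rename(columns={"mean_count": "mean_induced"})
    mu = _mean_seq_counts(uninduced).rename(columns={"mean_count": "mean_uninduced"})
    merged = mi.merge(
        mu[["u_vector", "mean_uninduced"]], on="u_vector", how="outer"
    )
    merged["mean_induced"] = merged["mean_induced"].fillna(0.0)
    merged["mean_uninduced"] = merged["mean_uninduced"].fillna(0.0)
    in_window = merged["jes"].apply(lambda j: j is not None and not pd.isna(j) and lo <= j <= hi)
    merged = merged[in_window & (merged["mean_induced"] >= min_reads)].copy()
    merged["fold_change"] = [
        _fold_change(a, b)
        for a, b in zip(merged["mean_induced"], merged["mean_uninduced"])
    ]
    merged = merged[merged["fold_change"] >= fold_min]
    merged = merged.sort_values(
        "mean_induced", ascending=False, kind="mergesort", ignore_index=True
    )
    merged["jss"] = merged["jss"].astype("Int64")
    merged["jes"] = merged["jes"].astype("Int64")
    return merged[
        ["u_vector", "read_class", "jss", "jes",
         "mean_induced", "mean_uninduced", "fold_change"]
    ]


def percent_jes_in_window(p: SampleProfile, window: tuple[int, int]) -> float:
    """Percent of a sample's normalized reads whose JES falls in ``window``."""
    lo, hi = window
    if lo > hi or hi < p.es_lo or lo > p.es_hi:
        raise EmptyWindow(f"ES window [{lo},{hi}] outside profiled range "
                          f"[{p.es_lo},{p.es_hi}]")
    in_win = sum(v for es, v in p.jes_hist.items() if lo <= es <= hi)
    return 100.0 * in_win / NORM_TOTAL


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def compare_conditions(
    a: Sequence[float],
    b: Sequence[float],
    *,
    welch: bool = False,
) -> TTestResult:
    """Two-sample two-sided t-test on per-replicate statistics.

    Student's (equal-variance) t by default; Welch's by flag.  With zero
    variance in both groups: equal means give t=0, p=1; unequal means are
    reported as degenerate (t undefined under zero pooled variance).
    """
    if len(a) < 2 or len(b) < 2:
        raise ReplicateMismatch("need >= 2 replicates per condition for a t-test")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.inf if a.mean() > b.mean() else -math.inf, df, 0.0,
                           degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = int(res.df) if welch else len(a) + len(b) - 2
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def render_sequence_alignment(
    s: EditingScaffold,
    w: AmpliconWindow,
    u_vector: Sequence[int],
    *,
    label: str = "READ",
) -> str:
    """Render a U-count vector aligned against PRE and EDIT reference rows.

    Each ES column is padded to the widest U run among the three rows so
    backbone residues line up vertically (the style used to display
    sequences pausing in a window of interest).
    """
    pre = s.window_u(s.pre_u, w.es_lo, w.es_hi)
    can = s.window_u(s.can_u, w.es_lo, w.es_hi)
    rows = {"PRE ": pre, "EDIT": can, f"{label:<4}": tuple(u_vector)}
    m = s.n_es
    lines = {k: [] for k in rows}
    # walk 5'->3': residues fwd_end..rev_start with the window's gaps between
    for res in range(w.fwd_end, w.rev_start + 1):
        for k in rows:
            lines[k].append(s.backbone[res])
        if res == w.rev_start:
            break
        es = m - res  # gap between residues res and res+1
        width = max(rows[k][es - w.es_lo] for k in rows)
        for k, u in rows.items():
            n = u[es - w.es_lo]
            lines[k].append("t" * n + "-" * (width - n))
    return "\n".join(f"{k} 5'-{''.join(v)}-3'" for k, v in lines.items())
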