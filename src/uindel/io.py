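"""Pipeline orchestration: configuration, file formats, logging, outputs.

Ties the stages together: load the reference pair, restrict to the
amplicon window, process every sample listed in a sample sheet, normalize,
detect EJES between the two conditions, and write the result bundle
(per-read TSV, per-sample profiles, EJES table, filtered-sequence table,
summary JSON, log).  All tabular outputs are tab-separated UTF-8 with a
single header row and '#'-prefixed provenance comments; coordinates are
1-based inclusive ES indices throughout.  Reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

from . import __version__
from .pause import (
    NORM_TOTAL,
    SampleProfile,
    compare_conditions,
    detect_ejes,
    filter_window_sequences,
    normalize_sample,
    percent_jes_in_window,
)
from .reads import ExclusionReason, ReadCall, ReadClass, process_read
from .scaffold import (
    AmpliconWindow,
    EditingScaffold,
    UindelError,
    load_reference_pair,
    restrict_to_amplicon,
    reverse_complement,
    write_scaffold_tsv,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "orient_reads",
    "read_sequences",
    "read_sample_sheet",
    "EXIT_CONFIG",
    "EXIT_REFERENCE",
    "EXIT_READS",
]

# distinct exit codes by failure domain
EXIT_CONFIG = 2
EXIT_REFERENCE = 3
EXIT_READS = 4

log = logging.getLogger("uindel")


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, and to ``logfile`` when given."""
    log.setLevel(level)
    for h in log.handlers:
        h.close()
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile, mode="w")
        fh.setFormatter(fmt)
        log.addHandler(fh)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    reference: str
    transcript: str
    fwd_primer: str
    rev_primer: str
    sample_sheet: str
    outdir: str
    induced: str = "induced"
    uninduced: str = "uninduced"
    fold_min: float = 3.0
    min_norm_reads: float = 100.0
    min_replicates: int = 2
    window: tuple[int, int] | None = None
    orientation: str = "as-is"  # or "auto"
    min_read_length: int = 0
    primer_mismatches: int = 0
    seed: int = 0  # used only by the simulate subcommand

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "window" in data and data["window"] is not None:
            data["window"] = tuple(data["window"])
        try:
            return cls(**data)
        except TypeError as e:
            raise UindelError(f"bad config {path}: {e}") from None

    def validate(self) -> None:
        if self.orientation not in ("as-is", "auto"):
            raise UindelError(f"orientation must be 'as-is' or 'auto', got {self.orientation!r}")
        for p in (self.reference, self.sample_sheet):
            if not Path(p).exists():
                raise UindelError(f"path not found: {p}")


# ---------------------------------------------------------------------------
# input formats

def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA or FASTQ, gzipped or not."""
    from Bio import SeqIO

    p = str(path)
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def read_sample_sheet(path: str | Path) -> list[dict]:
    """Parse the sample sheet TSV: sample_id, condition, replicate, path.

    Relative read-file paths are resolved against the sheet's directory.
    """
    base = Path(path).parent
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"sample_id", "condition", "replicate", "path"}
        if not required.issubset(header):
            raise UindelError(
                f"sample sheet {path} must have columns {sorted(required)}"
            )
        idx = {k: header.index(k) for k in required}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            p = Path(f[idx["path"]])
            if not p.is_absolute():
                p = base / p
            rows.append(
                {
                    "sample_id": f[idx["sample_id"]],
                    "condition": f[idx["condition"]],
                    "replicate": int(f[idx["replicate"]]),
                    "path": p,
                }
            )
    if not rows:
        raise UindelError(f"sample sheet {path} lists no samples")
    return rows


def orient_reads(
    reads: Iterable[tuple[str, str]],
    w: AmpliconWindow,
    policy: str = "as-is",
) -> Iterator[tuple[str, str]]:
    """Bring reads to the sense strand.

    'as-is' passes reads through.  'auto' keeps a read whose forward
    primer prefix and reverse primer suffix match as-is, reverse-
    complements it when only the flipped orientation matches, and passes
    ambiguous or unmatched reads through unchanged (they are then
    excluded as primer-missing downstream, keeping tallies auditable).
    """
    if policy == "as-is":
        yield from reads
        return
    if policy != "auto":
        raise UindelError(f"unknown orientation policy {policy!r}")
    for rid, seq in reads:
        s = seq.strip().upper().replace("U", "T")
        fwd_ok = s.startswith(w.fwd_primer) and s.endswith(w.rev_primer)
        rc = reverse_complement(s)
        rev_ok = rc.startswith(w.fwd_primer) and rc.endswith(w.rev_primer)
        if fwd_ok and not rev_ok:
            yield rid, s
        elif rev_ok and not fwd_ok:
            yield rid, rc
        else:
            # neither, or palindromic-primer ambiguity: leave for exclusion
            yield rid, s


# ---------------------------------------------------------------------------
# output formats

def _provenance(lines: list[str]) -> str:
    return "".join(f"# {ln}\n" for ln in ["uindel " + __version__, *lines])


def write_read_calls_tsv(calls: Sequence[ReadCall], path: Path, sample_id: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance([f"sample {sample_id}"]))
        fh.write("read_id\tclass\tjss\tjes\tu_vector\texclusion_reason\n")
        for c in calls:
            u = "" if c.u_obs is None else ",".join(map(str, c.u_obs))
            fh.write(
                f"{c.read_id}\t{c.read_class}\t"
                f"{'' if c.jss is None else c.jss}\t"
                f"{'' if c.jes is None else c.jes}\t{u}\t"
                f"{'' if c.exclusion is None else c.exclusion}\n"
            )


def write_profile_tsv(p: SampleProfile, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance([
            f"sample {p.sample_id} condition={p.condition} replicate={p.replicate}",
            f"reads total={p.n_reads} excluded={p.n_excluded}",
        ]))
        fh.write("es\tnormalized_jes_count\n")
        for es in range(p.es_lo, p.es_hi + 1):
            fh.write(f"{es}\t{p.jes_hist.get(es, 0.0):.1f}\n")


def _write_df_tsv(df, path: Path, provenance: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(provenance))
        df.to_csv(fh, sep="\t", index=False, float_format="%.1f")


# ---------------------------------------------------------------------------
# orchestration

def process_sample(
    s: EditingScaffold,
    w: AmpliconWindow,
    row: Mapping,
    cfg: RunConfig,
) -> tuple[list[ReadCall], SampleProfile]:
    reads = orient_reads(read_sequences(row["path"]), w, cfg.orientation)
    calls = [
        process_read(
            s, w, seq, rid,
            min_length=cfg.min_read_length,
            primer_mismatches=cfg.primer_mismatches,
        )
        for rid, seq in reads
    ]
    profile = normalize_sample(
        calls,
        sample_id=row["sample_id"],
        condition=row["condition"],
        replicate=row["replicate"],
        es_lo=w.es_lo,
        es_hi=w.es_hi,
    )
    for reason, n in profile.exclusion_counts.items():
        if profile.n_reads and n / profile.n_reads > 0.10:
            log.warning(
                "%s: %.1f%% of reads excluded (%s)",
                profile.sample_id, 100 * n / profile.n_reads, reason,
            )
    return calls, profile


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; writes the result bundle under cfg.outdir.

    Returns the summary dict (also written as summary.json).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir / "run.log")
    log.info("uindel %s", __version__)
    log.info(
        "thresholds: fold_min=%g min_norm_reads=%g min_replicates=%d window=%s",
        cfg.fold_min, cfg.min_norm_reads, cfg.min_replicates, cfg.window,
    )

    s = load_reference_pair(cfg.reference, cfg.transcript)
    w = restrict_to_amplicon(s, cfg.fwd_primer, cfg.rev_primer)
    log.info("scaffold %s: %d ES; amplicon window ES%d-%d",
             s.name, s.n_es, w.es_lo, w.es_hi)
    write_scaffold_tsv(s, outdir / "scaffold.tsv")

    rows = read_sample_sheet(cfg.sample_sheet)
    profiles: dict[str, list[SampleProfile]] = {}
    for row in rows:
        calls, profile = process_sample(s, w, row, cfg)
        write_read_calls_tsv(
            calls, outdir / f"{profile.sample_id}.reads.tsv", profile.sample_id
        )
        write_profile_tsv(profile, outdir / f"{profile.sample_id}.profile.tsv")
        profiles.setdefault(row["condition"], []).append(profile)
        log.info(
            "%s: %d reads, %d excluded", profile.sample_id,
            profile.n_reads, profile.n_excluded,
        )

    window = tuple(cfg.window) if cfg.window else (w.es_lo, w.es_hi)
    summary: dict = {
        "version": __version__,
        "transcript": cfg.transcript,
        "es_window": [w.es_lo, w.es_hi],
        "analysis_window": list(window),
        "thresholds": {
            "fold_min": cfg.fold_min,
            "min_norm_reads": cfg.min_norm_reads,
            "min_replicates": cfg.min_replicates,
        },
        "samples": {},
    }
    for cond, plist in profiles.items():
        for p in plist:
            summary["samples"][p.sample_id] = {
                "condition": p.condition,
                "replicate": p.replicate,
                "n_reads": p.n_reads,
                "n_excluded": p.n_excluded,
                "exclusions": dict(p.exclusion_counts),
                "class_fractions": {
                    str(k): v / NORM_TOTAL for k, v in p.class_counts.items()
                },
                "pct_jes_in_window": percent_jes_in_window(p, window),
            }

    ind = profiles.get(cfg.induced, [])
    uni = profiles.get(cfg.uninduced, [])
    if ind and uni:
        ejes = detect_ejes(
            ind, uni,
            fold_min=cfg.fold_min,
            min_norm_reads=cfg.min_norm_reads,
            min_replicates=cfg.min_replicates,
        )
        _write_df_tsv(ejes, outdir / "ejes.tsv",
                      [f"induced={cfg.induced} uninduced={cfg.uninduced}"])
        seqs = filter_window_sequences(
            ind, uni, window, fold_min=cfg.fold_min, min_reads=cfg.min_norm_reads
        )
        _write_df_tsv(seqs, outdir / "window_sequences.tsv",
                      [f"window ES{window[0]}-{window[1]}"])
        n_ejes = int(ejes["ejes"].sum())
        summary["n_ejes"] = n_ejes
        summary["ejes"] = [int(e) for e in ejes.loc[ejes["ejes"], "es"]]
        summary["pct_jes_in_window"] = {
            cfg.induced: [percent_jes_in_window(p, window) for p in ind],
            cfg.uninduced: [percent_jes_in_window(p, window) for p in uni],
        }
        if len(ind) >= 2 and len(uni) >= 2:
            tt = compare_conditions(
                summary["pct_jes_in_window"][cfg.induced],
                summary["pct_jes_in_window"][cfg.uninduced],
            )
            summary["window_percent_ttest"] = {
                "t": tt.t, "df": tt.df, "p": tt.p, "degenerate": tt.degenerate,
            }
        log.info("EJES detected: %d", n_ejes)
    else:
        log.warning(
            "conditions %r/%r not both present; skipping EJES analysis",
            cfg.induced, cfg.uninduced,
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def plot_jes_profiles(profiles: Sequence[SampleProfile], path: str | Path) -> None:
    """Simple per-ES JES profile figure, one line per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for p in profiles:
        es = list(range(p.es_lo, p.es_hi + 1))
        ax.plot(es, [p.jes_hist.get(e, 0.0) for e in es],
                label=f"{p.condition} r{p.replicate}", linewidth=1)
    ax.set_xlabel("editing site (ES, numbered from 3' end)")
    ax.set_ylabel("normalized reads with JES at ES")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
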