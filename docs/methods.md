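# Methods

## Coordinate system

Editing only adds or removes uridines, so the pre-edited and fully edited
versions of a transcript share an identical string of non-U residues (the
*backbone*). We define an editing site (ES) as each internal gap between
consecutive backbone residues, numbered 1..n_es from the 3' end — ES1 is
the gap between the two 3'-most residues — matching the overall 3'→5'
direction of editing, so low ES indices are edited first. Every editing
intermediate is then a vector of non-negative per-ES U counts, `pre_u` and
`can_u` being the two reference vectors. Terminal U's (5' of the first or
3' of the last backbone residue) are trimmed before scaffold construction:
editing sites are defined *between* residues, and real amplicons are
primer-delimited inside never-edited sequence, so terminal runs are never
observable in a well-formed amplicon. Inputs may use U or T and any case;
degenerate IUPAC codes are rejected rather than guessed.

Interleaving the backbone with T-runs of the given lengths
(`reconstruct_sequence`) is the exact inverse of scaffold construction and
serves as the round-trip oracle throughout the test suite.

## Amplicon window

Primers are located on the pre-edited rendering of the transcript (they
target pre-edited or never-edited sequence); each must match exactly once,
and must end (forward) / begin (reverse) on a backbone residue so the
window boundary is well defined. The window is the maximal ES range
strictly between the primer footprints. "Fully edited" always means
*canonical up to the forward primer*: classification is evaluated only
over the window.

## Read reduction and exclusion

Reads are amplicons, so primer matching is anchored: the forward primer
must be a prefix of the (sense-oriented) read and the reverse primer a
suffix, each within a configurable Hamming distance (default 0 — exact).
Between the primers, the read's non-T residue string must equal the
reference backbone over the window *exactly*; any non-T SNP or non-T
insertion/deletion forces exclusion (`backbone-mismatch`). Since editing
chemistry only changes U counts, no mismatch tolerance or indel-aware
alignment is needed or wanted: a deviation in the non-T string is evidence
the read is an artefact, and tolerating it would corrupt U-count calls.
Reads failing the primer anchors are excluded `primer-missing` (a found 3'
primer with a missing 5' primer is never truncated into a shorter
amplicon), and reads below a configurable length floor are excluded
`too-short`. All exclusions are encoded as per-read reasons, never raised,
so per-sample tallies remain auditable; samples with any exclusion class
above 10% log a warning.

In `auto` orientation mode a read is reverse-complemented when only the
flipped orientation carries both primer anchors; reads matching neither or
both orientations pass through unchanged and are excluded as
`primer-missing` downstream.

## Classification and junction boundaries

Over the window, a read matching the canonical U counts at every ES is
FULLY_EDITED; matching the pre-edited counts, PRE_EDITED; otherwise
PARTIALLY_EDITED. Sites where `pre_u == can_u` are consistent with both
references and constrain neither call; a read consistent with both
everywhere (only possible in a never-edited window) is reported
FULLY_EDITED — "no editing remains to be done" — a tie-break that cannot
arise on any window containing at least one true editing site.

For a partially edited read, the junction start site (JSS) is the smallest
window ES whose U count differs from the canonical value, and the junction
end site (JES) is the largest window ES whose U count differs from the
pre-edited value — any editing action, canonical or non-canonical, counts.
Pre-edited and fully edited reads have no junction (both None). The
encoding `jes = jss − 1` is legal and distinct from "no junction": it
marks a read that paused cleanly after a block of purely canonical
editing. Because never-edited-at-site positions match both references,
`jes` can also sit more than one site 3' of `jss` when only such sites lie
between; the invariant maintained (and property-tested) is that every ES
strictly between JES and JSS matches both references.

## Normalization and pause statistics

Each sample's non-excluded reads are normalized to a total of 100,000
counts (weight `100000 / n_used` per read); excluded reads are tallied but
unweighted. Duplicate reads are *not* collapsed — abundances carry the
signal — but a per-distinct-u-vector table aggregates identical vectors
with their class and junction calls. Normalized counts are exact floats
internally; conservation (class totals and sequence-table totals each
100,000) is asserted pre-rounding, and TSV reports round to one decimal.

The JES histogram (normalized reads whose junction ends at each ES) is the
per-sample pause profile. An ES is an exacerbated junction end site (EJES)
between an induced (perturbed) and uninduced (control) condition iff

* mean induced JES count ≥ `fold_min` × mean uninduced count, and
* ≥ `min_replicates` induced replicates individually hold
  ≥ `min_norm_reads` normalized JES reads at that ES.

Defaults `fold_min = 3`, `min_norm_reads = 100`, `min_replicates = 2`
mirror the windowed sequence filter (below); all three are exposed in the
configuration. Fold changes use the plain ratio of condition means; when
the control mean is exactly zero, one normalized read is added to both
means, keeping the fold finite and monotone. Whether the criteria should
be evaluated on per-replicate fold changes instead of means of replicates
is not uniquely determined; we use means of replicates (with the
per-replicate read floor providing replicate-level support) and expose the
knobs.

The windowed sequence filter returns distinct U-count vectors whose JES
falls in an inclusive ES window (both bounds included), with mean
normalized count in the perturbed condition ≥ `min_reads` and a
perturbed/control ratio ≥ `fold_min`, sorted by perturbed-condition
abundance; a text rendering aligns any vector against the PRE and EDIT
rows with per-ES column padding.

`percent_jes_in_window` is 100 × (normalized reads with JES in the
window) / 100,000, computed over all non-excluded reads (not only
partially edited ones — an alternative normalization that is not uniquely
determined; the denominator choice is fixed and documented here).
Condition comparison uses the two-sided equal-variance Student's t-test on
per-replicate window percentages (Welch's available by flag); with zero
variance in both groups, equal means report t = 0, p = 1, and unequal
means are flagged degenerate rather than given a fabricated p-value.

## Synthetic data generator

The generator emulates the population structure the analysis assumes. Per
sample it draws, for each read: a class (defaults: 30% pre-edited, 10%
fully edited, 60% partial — a partial-dominated mixture typical of a
pan-edited transcript's steady state); for partial reads a JES from a
categorical over the window ES weighted by `pause_weights` (default
uniform; a planted pause site is a single elevated weight, e.g. 5×), a
junction length from a geometric distribution on {0, 1, 2, ...} with mean
2 ES (length 0 = empty junction; if the drawn JES cannot support an empty
junction because `pre_u == can_u` there, length is promoted to 1), and
junction U counts uniform on 0..max(pre_u, can_u)+2 excluding the
canonical value (and, at the JES itself, also the pre-edited value, so the
truth JES is well defined). Canonical counts fill ES 3' of the junction,
pre-edited counts 5' of it. Truth labels are recomputed from the finished
vectors by the definitional scan, so boundary effects (a junction clamped
at the window edge, or an empty junction indistinguishable from a fully
edited read when only never-edited sites lie 5' of it) are labelled
exactly.

Sequencing errors are substitutions at a per-base rate (default 0.001,
typical of Illumina amplicon data). An error event on a primer base or
backbone residue substitutes a random different base — under exact
matching this always excludes the read. An error event inside a U run
perturbs the run length by ±1 instead: this is the deliberate model of the
one realistic error mode that *survives* the exclusion filter and creates
spurious non-canonical U counts. It makes the exclusion fraction exactly
`1 − (1−ε)^(primer bases + backbone residues)`, an analytic target the
tests verify, and it means observed class fractions at ε > 0 sit slightly
below truth (a pre-edited read with a perturbed run becomes partial) —
which is precisely the artefact a user of the real pipeline should expect.
Qualities are a constant Q30 placeholder; the pipeline ignores them by
default. PCR bias, chimeras and indel sequencing errors are not modelled.

Per-replicate RNG streams are spawned from the master seed
(`SeedSequence(master_seed, spawn_key=...)`), so experiment output is
byte-identical across reruns. Two layers are exposed: full sequence
rendering (FASTQ + truth TSV + sample sheet), and a vectorized
editing-state layer (`draw_read_states` / `profile_from_states`) that
skips rendering. The state layer equals render→align→normalize exactly at
ε = 0 (asserted by test), which lets the large calibration studies —
planted-pause recovery over 100 seeded 2+2×20,000-read experiments, and
the label-swap null over 100 seeded 4×5,000-read experiments — run in
seconds without weakening what they demonstrate.

The bundled synthetic reference (`synthetic_reference_pair`, fixed
structural seed) has 150 ES, 16-ES never-edited flanks serving as primer
landing sites, sparse pre-edited U's and insertion-dominated canonical
editing (up to 12 U per site). It reproduces the *structure* of real
pan-edited substrates, not any real sequence; passing tests demonstrate
correctness of the computation under this structure, not concordance with
any particular biological dataset (real libraries add PCR bias, indel
errors, quality variation and off-target molecules, which only the
exclusion tallies would reflect).

## Pipeline, outputs, determinism

`run_pipeline` orchestrates: reference pair → scaffold → amplicon window →
per-sample read processing → normalization → EJES detection → windowed
sequence filter → summary. Outputs are TSV (UTF-8, one header row,
`#`-prefixed provenance comments, 1-based inclusive ES coordinates —
nucleotide coordinates are never exposed) plus `summary.json` and a log;
reruns on identical inputs are byte-identical (a test target). The CLI
(`uindel scaffold/simulate/run/ejes/report`) is a thin wrapper; exit codes
distinguish configuration (2), reference (3) and read-file (4) failures.

## Problem sizes and numerical choices

Test and acceptance workloads use a 4-ES toy scaffold for exhaustive
enumeration (all 625 U-vectors with entries 0–4 against an independent
brute-force scan), 10,000 random vectors on random scaffolds for
round-trip exactness, an 80-ES scaffold for the 100-seed recovery and null
studies, and the 150-ES reference with 2×2×20,000 reads for the end-to-end
acceptance run — sizes chosen so each property is statistically
identifiable while the whole suite stays fast. Conservation checks use an
absolute tolerance of 1e-6 on totals of 100,000 (pure float-summation
slack); statistical calibration checks use 3σ binomial bands.

## Known limitations

* Exact primer anchoring (Hamming knob aside) means primer-region
  sequencing errors cost reads; real pipelines may trim primers upstream.
* No multiple-testing correction is applied across ES in the EJES table —
  the fold/floor/replicate rule is a filter, not an inferential procedure.
* The t-test is applied to n = 2 replicates per condition when used with
  duplicate designs; p-values at such sizes are indicative only.
* Single-transcript, sense-strand amplicons only: no genome alignment, no
  chimera detection, no non-U editing chemistries.
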