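# Methods

## Mismatch model

A degenerate primer is treated as the set of concrete oligos obtained by
expanding its IUPAC codes positionwise. Because environmental fragments are
concrete (A/C/G/T) sequences, a per-position set-membership count — the
number of positions where the fragment base falls outside the primer code's
set — equals the minimum Hamming distance between the fragment and any oligo
in the mixture. The implementation uses the per-position rule; the
equivalence with the brute-force minimum over expansions is asserted by a
property test on random primer/fragment pairs. A fragment with 0 mismatches
is "perfectly matched": at least one synthesised oligo anneals with no
mismatch. All mismatch positions are weighted equally; the model carries no
position-specific penalty even though 3′-terminal mismatches are more
damaging in practice — coverage here is a sequence-identity statement, not a
PCR-efficiency prediction.

Fragments containing any ambiguity code (including N) are excluded before
scoring rather than counted as match or mismatch: an uncalled base is
evidence for neither outcome. U is normalized to T and lowercase to
uppercase on input. Expansion is capped at 4,096 oligos by default (the
widest mixture seriously discussed in this domain is 144), overridable.

## Fragment extraction

Primer windows are located by 1-based inclusive coordinates on the
reference each group's reads were aligned to (the conventional coordinate
frame is the E. coli K-12 MG1655 16S rRNA gene). A read yields a fragment
when its alignment

1. covers every reference column of the window with aligned bases,
2. has no insertion or deletion inside the window (length-changing variants
   cannot be scored positionally and are skipped, counted separately), and
3. extends at least `flank` (default 5) reference bases beyond the window on
   at least one side. Requiring the flank on both sides is available via
   `require_both_flanks`; the one-sided rule is the default because it keeps
   every read that contains the complete primer site plus context on one
   flank, and the side(s) achieved are recorded per fragment.

Fragments are stored in reference (plus-strand) orientation; a reverse
primer is compared as the reverse complement of its written sequence, so one
extraction pass serves both primers of a pair. Filters run in a fixed order
— extract → mean-quality filter → drop non-ACGT → exclusion filter — and a
tally guarantees read conservation: every input record is counted exactly
once across skips, removals and retained fragments.

Defaults, all configurable: mean Phred quality over the window ≥ 30
(arithmetic mean of per-base scores; the upstream pipeline this emulates
quality-filters without publishing a cutoff, and Q30 is the conventional
"high-quality" line); exclusion of fragments with more than 6 mismatches
(inclusive boundary), which separates genuine primer-site variation from
misalignments and distantly related genes.

## Coverage and pair combination

Coverage is counted per sample × organismal group at cumulative mismatch
thresholds 0, 1, 2. Cells with no fragments report null (NA), never 0/0:
absence of evidence is not zero coverage.

A primer pair is summarized only over the groups both primers are declared
to target (each primer definition carries a `targeted_groups` set; e.g. a
reverse primer with no 18S binding site contributes no Eukarya rows). The
observed forward- and reverse-site fragments come from different reads, so
per-molecule linkage is unobservable; three combination rules are therefore
emitted side by side: the independence product (default), the minimum, and
the worst-case bound max(0, 1 − ((1−c_f) + (1−c_r))) which assumes the two
primers' missed organism sets are disjoint. Product ≥ worst-case always
((1−a)(1−b) ≥ 0) and min ≥ product; no single rule is presented as "the"
pair coverage.

## Variant tables and mixture design

Variant tables count distinct window sequences per dataset (dataset =
sample by default, or a supplied pooling), reported in primer synthesis
orientation. "Overall relative abundance" is the unweighted mean of
per-dataset relative abundances, so a deeply sequenced dataset cannot
dominate the design; pooled-read weighting was considered and rejected as
the default for that reason. Variants below 2 observations in every dataset
are flagged as possible sequencing error but kept in the table.

A minimal mixture is {seed} ∪ {variants with overall abundance strictly
above the threshold, default 0.02} ∪ curated additions supplied as FASTA
(no database access inside the tool). The seed defaults to the
highest-abundance variant already matched by the current primer. Achieved
coverage is recomputed from the table — the summed abundance of variants
equal to a mixture member — never cached. The minimal IUPAC consensus
covering the mixture is reported with its degeneracy and the number of its
expansions never observed in the data, quantifying the redundancy a fully
degenerate redesign would synthesise.

Single-degeneracy suggestions consider, per primer position, the unmatched
variants whose only mismatch lies at that position (exactly the set a single
widening can rescue), rank positions by abundance recovered, and report the
minimal widened code and the resulting degeneracy. The reported gain is, by
construction, exactly the coverage increase of applying the edit; a test
recomputes it independently.

## Concordance

Both abundance tables are collapsed by an explicit taxon → group mapping
(error on unmapped taxa), columns normalized to the simplex, and each
sample fitted by ordinary least squares of amplicon on metagenome relative
abundance (scipy's linregress; cross-checked against statsmodels OLS in the
tests). The fit uses untransformed abundances and a free intercept — the
plain reading of "linear least-squares regression" — with slope and
intercept emitted so an origin-forced or log-scale convention can be
audited; a log10 option exists but is off by default. Groups with zero
abundance in both sources are dropped from that sample; zero in one source
stays as an explicit zero. A fit requires ≥ 3 groups and nonconstant
predictor; otherwise the result is null with a reason. The depth summary
reports the fraction of samples with R² below a threshold (default 0.95)
on either side of a depth split (default 150 m).

## Synthetic data

The generator emulates randomly sheared SSU rRNA fragments: per group, a
uniform-random reference with each primer window overwritten by its variant
pool's consensus; uniform read starts; fixed read length (default 150 bp,
short-read scale); every read fully covering a window redraws the window
bases from the pool at the planted frequencies. The default pool plants a
perfect-match fraction of 0.75 with a 0.15/0.07/0.03 tail of 1/2/3-mismatch
variants — far more mismatch-rich than a well-designed primer would show in
the field, chosen so both tails of the mismatch histogram are exercised.
Default scale is 2,000 reads per sample across 10 samples, enough for the
binomial error of a planted frequency to be a few percentage points.
Quality strings are two-level (Q40 pass / Q2 fail, 5% failing) so the
quality filter's outcome is exactly predictable; substitution errors are
off by default and uniform when enabled. Abundance-table pairs are a
Dirichlet composition (metagenome) times per-cell multiplicative lognormal
noise (amplicon), σ = 0 giving exact equality.

What passing tests on this generator do **not** show about real data: no
coverage or GC bias, no chimeras, no PCR amplification model, no realistic
taxon abundance curves, and group labels are exact rather than classified.
The generator validates the arithmetic and the plumbing, not ecological
realism.

Determinism: every generator consumes `numpy.random.default_rng` seeded
with (spec seed, stream index, sample/group index), so all outputs are
byte-identical across runs for a fixed seed, which the pipeline's
reproducibility contract (identical config + inputs + seed ⇒ byte-identical
TSVs) inherits.

## Command-line interface

One subcommand per stage (`expand`, `simulate`, `evaluate`, `pairs`,
`variants`, `design`, `concordance`) rather than a workflow engine: the
stages exchange plain TSVs, so any of them can be replaced by external
data. Outputs are tab-separated UTF-8 with `#`-prefixed headers recording
the tool version and a digest of the configuration. Validation failures
(malformed config, missing inputs, incompatible lengths) exit with status 2
and name the offending key. The `--threads` flag is accepted and validated
for interface stability but execution is single-process; per-sample
fan-out is trivially scripted outside the tool.

## Known limitations

- Coverage is a perfect-match statistic; it does not model annealing
  thermodynamics, 3′-end criticality, or amplification efficiency, and no
  melting-temperature/self-dimer screening is applied to designed mixtures.
- Retrieval of SSU rRNA reads from raw metagenomes, taxonomic
  classification, and ASV denoising are upstream of this package: reads
  arrive aligned and group-labelled.
- The pair-coverage rules bound, but cannot identify, the true per-molecule
  pair coverage from unlinked short reads.
- The 6-mismatch exclusion cannot distinguish a genuinely hypervariable
  primer site from systematic misalignment; it is a threshold, not a
  classifier.
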