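# Methods

## Data model

A *database version* is a set of superfamilies keyed by SCOP-style numeric
code. Each superfamily carries ≥ 3 member domains and a gapped multiple
sequence alignment (FASTA, `-` gaps only); de-gapping a member's row must
reproduce its sequence. Members are identified as lowercase PDB code +
`_` + chain (e.g. `1jce_A`); optional per-member annotations are a
secondary-structure string over {H, E, C} and an ordered Cα trace, both
exactly one entry per residue. A version additionally lists *outliers*:
member ids excluded from alignments because they could not be structurally
aligned.

## Length variation

For a superfamily with member lengths `L_i` and mean `L̄` (arithmetic
mean), the extent of length variation of member *i* is

    v_i = 100 · (L_i − L̄) / L̄   [signed percent]

Signed values sum to zero by construction and are scale-invariant. The
per-superfamily profile records the signed map, its **population** standard
deviation (ddof = 0 — the superfamily *is* the population of its members,
not a sample), and the maximum |v_i|. Distributions use half-open 5%-wide
bins `[lo, lo+5)` with a terminal open bin `[45, ∞)`; a value of exactly
5.0 falls in `[5, 10)`. Per-superfamily binning uses max |v_i| by default
(`mean_abs` and `sd` are selectable — the choice of summary statistic for
that view is genuinely open, and max-abs is the most conservative reading
of "how deviant can this superfamily get"). Classes absent from a version
are omitted from per-class maps rather than zero-filled.

## Classification

Member thresholds compare |v_i|: deviant above 30%, rigid below 10%;
signed values are kept for reporting only.

**Original scheme** (any size): deviant iff ≥ 75% of members are deviant;
else rigid iff ≥ 75% are rigid; else normal ("normal" here also stands in
for the superfamilies the historical scheme left unclassified).

**Improved scheme**: superfamilies with ≥ 10 members use the same 75%
three-way rule (the mirror of the deviant rule at 75% is assumed for the
rigid side; the historical description does not restate the fraction).
Sparse superfamilies (< 10 members — the boundary value 10 is treated as
dense, configurable) use the relaxed "more-than-one" strategy:

1. `count(|v| > 30) ≥ sparse_deviant_min` → deviant
   (`sparse_deviant_min = 2` by default; the single-member variant that
   some descriptions imply is reachable via config = 1);
2. otherwise the larger of `count(|v| > 30)` and `count(|v| < 10)` wins;
3. ties (including 0–0, i.e. all members mid-band) fall to the configured
   tie label — normal by default — with `tie_broken` flagged, standing in
   for what was historically manual curation.

Label counts always partition the superfamily set, and raising the deviant
cutoff can only shrink the deviant count.

The headline database-scale label counts reported for the real
PASS2.2/PASS2.3 releases (e.g. 67 deviant / 416 rigid / 152 normal) depend
on data that was never deposited in machine-readable form; they are
documented here as context, not recomputed.

## Version diffing

**Mapping** partitions codes into common / absent-from-new / new.
**Splits and merges** come from the bipartite member-overlap graph (member
identity across versions is the member-id string): an old superfamily
overlapping ≥ 2 new ones (each sharing ≥ `min_shared` = 1 members) is a
split; the symmetric pattern a merge. Detection is symmetric: swapping the
version arguments exchanges split and merge.

**Member fates.** Every old member receives the first matching rule:

1. *retained* — id present in the new version;
2. *superseded* — a same-superfamily candidate with 100% alignment
   identity, equal length and a different PDB code (a better-resolution
   redeposit); candidates scanned in sorted id order;
3. *outlier* — listed in the new version's outlier set;
4. *rescued_by_search* — best identity against same-superfamily new
   members ≥ 40% (stand-in for the BLAST/HMM searches of the original
   workflow; 40% mirrors the database's redundancy cutoff);
5. *rescued_by_identity* — best identity > 30% (stand-in for forcible
   multiple alignment followed by percent-identity placement);
6. *unaccounted*.

Members present only in the new version are *new*. If a member's
superfamily is absent from the new version, rules 4–5 are unavailable and
it falls through to *unaccounted* with that evidence.

**Accounting cascade.** Stage counts telescope by definition:
`missing = total − retained`, `queries = missing − outliers`,
`still_missing = queries − search_hits`,
`unaccounted = still_missing − identity_rescued`. Superseded members are
counted among search hits: a 100%-identity replacement is the strongest
possible hit, and this keeps the telescoping identities exact against the
per-member fate list.

### Pairwise identity

The aligner is global Needleman–Wunsch with match +1, mismatch −1, linear
gap −2, filled row-wise (the linear gap cost lets the in-row dependency
collapse to a cumulative maximum, so the fill is vectorised). Co-optimal
alignments can carry **different match counts**, so determinism matters:
traceback prefers diagonal, then up (gap in the second sequence), then
left. Identity is gap-excluded: 100 × matches / columns where both
sequences hold residues. Because the tie-break is not symmetric in its
arguments, `global_align_identity` aligns the pair in canonical (sorted)
order and swaps the rows back, making identity(a, b) ≡ identity(b, a).

Two identity conventions coexist deliberately. The fate rules (4–5)
re-align pairs from scratch, mirroring the search tools they stand in for.
The < 40% entry-redundancy rule, by contrast, is checked on the
superfamily's **own alignment rows** (positional identity), which is how an
alignment database's entry rule is actually defined. The distinction is
load-bearing: gap-excluded identity under re-alignment is strongly
inflated for unequal-length pairs (two unrelated random sequences of 26
vs 70 residues typically re-align at ~44% identity), so a pairwise-NW
redundancy check would be unsatisfiable for exactly the length-deviant
superfamilies the analysis cares about.

## Alignment quality

*Initial equivalences* are fully gapless columns (a deliberate, simple
proxy for the structure-derived equivalences of the original tooling,
whose internal definition is not public). *SST equivalences* are gapless
columns unanimous in the 3-state secondary-structure alphabet.

*Kabsch superposition* is the SVD least-squares rigid fit with the
determinant sign correction, so reflections are never returned; it needs
≥ 3 points. RMSD is invariant to any common rigid motion and never worse
than the unfitted RMSD. *Consensus superposition* initialises the
reference from the lexicographically first member (determinism), then
alternates member-onto-mean fitting with mean recomputation at the
all-member-gapless columns until the mean moves < 1e−6 Å RMS or 50
iterations; the total squared deviation to the mean is non-increasing
across iterations. Mean pairwise RMSD uses the columns gapless across
each *pair* (pairs see more columns than the full core); the consensus
uses the common core. Quality reports include each metric only where its
inputs exist (SST needs secondary structure for every member, RMSDs need
≥ 2 members with coordinates).

## Statistics

Welch's unequal-variance t-test, two-sided, with Welch–Satterthwaite
degrees of freedom (the historical analysis says only "t-test"; Welch is
the safe default since the compared superfamily sets differ, which also
dictates an unpaired test). Two constant identical samples raise a
degenerate-variance error; comparisons omit such metrics with a reason
instead of failing. Member-count histograms use bins of 5 members.
Historical significance annotations (e.g. starring p = 0.093) are not
reproduced as logic; raw p-values are reported.

## Synthetic data generator

The generator emulates the *entry rules and bookkeeping* of a curated
alignment database, not protein evolution. Design targets:

- **Forced-margin labels.** Member lengths are the rounded mean times
  (1 + d): rigid d = ±1–3%, deviant d = ±45% for the required count
  (⌈0.75 n⌉ dense, 2 sparse), normal d inside 12–25% with the span capped
  (see below). Deviations sum to ~0, so each label is recovered *exactly*
  by the improved scheme — recovery is a construction invariant, not a
  statistical outcome, and generation re-classifies as a hard
  post-condition.
- **Alignment model.** Terminal extensions over a shared N-terminal core:
  every row is the full sequence padded with C-terminal gaps. This is the
  simplest alignment-consistent indel model; gapless columns = the
  shortest member's length.
- **Fate realisation.** Retained members are copied; superseded ones
  re-emitted under fresh PDB codes; outliers listed; rescuable members
  replaced by substitution-only homologs in verified identity bands
  (45–60% for search rescue, 33–37% for identity rescue); unaccounted
  members dropped. Every band is *measured with the pipeline's own
  aligner* and resampled on collision, because background identity between
  unrelated sequences is not negligible: at equal length ~50 it
  occasionally exceeds 30%, and between members whose lengths differ by
  1.5× or more it routinely exceeds 30–40%. Identity-banded fates are
  therefore only planted in superfamilies whose length span is ≤ 1.45×
  (rigid and normal); deviant superfamilies (span ≥ ~1.8×) receive only
  identity-unconstrained fates. The normal-label deviation bands are
  chosen to respect that cap, including the (+24, −12, −12)% triple that
  odd member counts require.
- **Identity floor.** Substitution-only mutation cannot reach 0% measured
  identity: optimal gapped re-alignment of two unrelated same-length
  100-mers recovers ~11–15% spurious matches. `mutate_to_identity`
  verifies against measurement and raises a floor error for unreachable
  targets rather than silently missing them.
- **Coordinates.** An idealised α-helical curve (1.5 Å rise, 100° turn,
  2.3 Å radius) plus isotropic Gaussian noise — enough to give RMSD
  metrics known expectations (per-residue noise σ puts the fit RMSD near
  σ√3), nothing more.
- **Determinism.** One `numpy` Generator seeded from the spec drives
  everything; equal seeds give identical databases.

The worked accounting example is a 64-superfamily fixture (41 of 13
members, 23 of 12; mean lengths 48–64 residues) whose fate plan is
333 retained / 162 outliers / 201 search-rescued / 80 identity-rescued /
33 unaccounted out of 809. The stage counts are construction invariants —
any seed reproduces them — and the fixture uses length-rigid superfamilies
so that every planted band separates cleanly from the re-alignment
background; the historical audit this mirrors concerned length-deviant
superfamilies, but the cascade arithmetic is independent of the length
labels. Sequence lengths and superfamily counts throughout the test suite
are kept at this modest scale because the guarantees being tested
(partitions, telescoping identities, exact recovery) are size-independent.

### What passing tests do and do not show

Synthetic sequences are uniform random over 20 amino acids; there are no
substitution matrices, phylogenies, conserved motifs, internal indels or
realistic geometry. Passing the recovery suites shows the *bookkeeping* is
exact — fates, events and labels planted under the stated margins are
found by the inference rules alone — and that the numerics (aligner,
superposition, statistics) meet their oracles. It does not validate the
biological choice of thresholds (30/10/75%, 40/30% identity) on real
databases, nor how the rules would behave on genuinely homologous
sequences, where identity bands overlap far more than the forced margins
allow.

## Known limitations

- Real release data for the historical database pair is not available in
  machine-readable form; all database-scale historical numbers are
  context, not reproduction targets.
- Split/merge detection relies on member-id stability across versions;
  renamed chains are recoverable only through the supersession and rescue
  rules, and a simultaneous split *plus* wholesale renaming would be
  invisible.
- The 19.5% / 45.5% / 35% member-fate percentages quoted for the
  historical update are mutually inconsistent under any single
  denominator; the pipeline reports raw counts and leaves percentage
  conventions to the caller.
- Gap-excluded identity is the stated convention for the fate rules, but
  (as noted above) it is a biased quantity for unequal-length pairs;
  interpreting rescue rates for length-deviant superfamilies on real data
  would need a length-aware convention.
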