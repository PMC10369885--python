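# Methods

This note documents the models, conventions and numerical choices behind
msaforge, in the spirit of a methods appendix: what each quantity means,
which knobs matter, what the synthetic data does and does not emulate, and
where the implementation makes a choice the field leaves open.

## Query-anchored alignments and sequence identity

All alignments are query-anchored A3M: columns are defined by the query's
residues (the match columns, count `L`), uppercase/`-` characters occupy
them, and lowercase characters are insertions relative to the query that
carry no column. The query is the first record and contains neither gaps
nor insertions.

Sequence identity ("qid") of a member to the query is the fraction of the
`L` match columns carrying the identical residue. The denominator is
always `L` — not the pairwise-aligned length — so fragments score low even
when everything they align is correct; this matches the query-identity
semantics of standard MSA filters. `-` matches nothing, and the unknown
residue `X` matches nothing either, with one deliberate exception: a member
whose match-state string equals the query's exactly scores 1.0, so that
identity 1 holds precisely when the strings are equal. Identity is by
construction invariant to insertions.

## The identity/diversity filter

The filter mirrors the behaviour of identity-window MSA filters used ahead
of structure prediction, with three ordered stages applied to the
non-query members:

1. **Identity window.** Members with qid < `min_qid` (default 0.2) are
   removed as unlikely homologs, members with qid > `max_qid` (default
   0.95) as uninformative near-copies of the query. The boundaries are
   inclusive (exactly 0.2 or 0.95 is kept), since the removal rules are
   strict inequalities.
2. **Redundancy collapse.** Exact duplicates by match-state string are
   collapsed to the first occurrence, regardless of header. (Merging two
   MSAs, by contrast, deduplicates on the (header, match-string) pair, so
   two differently labelled identical sequences from different sources
   survive a merge but not the filter.)
3. **Diversity cap.** If more than `max_kept` members (default 3000)
   survive, a diversity-maximizing subset is selected by greedy
   farthest-point selection on the distance d(x, y) = 1 − pairwise
   identity, seeded at the query: repeatedly add the member whose minimum
   distance to the selected set is largest, breaking ties by higher qid
   and then input order. Greedy max-min selection is the standard
   2-approximation to the (NP-hard) exact max-min-diversity subset; it is
   deterministic, and on well-separated lineage structures it attains the
   exhaustive optimum (the test suite checks this on a constructed
   3-lineage example).

Output order is query first, then members by descending qid (ties by input
order). The filter is idempotent, and the filtered member set is always a
subset of the input.

## N_eff: the effective number of sequences

Diversity of an alignment is summarized as

    N_eff = exp( mean_c H_c ),

where `H_c` is the Shannon entropy (natural log) of the weighted residue
frequencies in match column `c`. Sequences are weighted with the Henikoff
position-based scheme over match columns: each column distributes
1/(r·s) to every sequence, where `r` is the number of distinct residues in
the column and `s` the multiplicity of the sequence's own residue;
weights are normalized to sum to one. Gaps and `X` are excluded from
column counts, and an all-gap column contributes zero entropy.

Anchors: N identical sequences give N_eff = 1 (every column entropy 0); a
single-column alignment carrying all 20 residues at equal weight gives
N_eff = 20 = exp(ln 20), the upper bound. Profile tools each use their own
internal weighting, so numerical agreement with any particular external
N_eff implementation is approximate; the definition here is fixed and
self-consistent, and all claims in the package compare N_eff values
computed by this one definition.

## GDT_TS and superposition

GDT_TS is the mean over cutoffs {1, 2, 4, 8} Å of the largest fraction of
shared CA atoms that can be placed within the cutoff of the reference by a
rigid superposition, ×100. Residue correspondence is by residue number
(predicted models are assumed renumbered to the target); no sequence
alignment is performed.

The exact maximization is combinatorial, so — like the assessors'
scorers — we use a deterministic seeded local search: for each seed
subset, superpose (least squares), collect all residues within the cutoff,
re-superpose on them and iterate to a fixed point (at most 10 iterations);
seeds are every contiguous window of 3, 5 and 7 shared residues plus the
full common set, and the best fraction seen over all seeds and iterations
is reported. Properties: exact (fraction 1) for identical or rigidly
transformed structures; never below the single full-set superposition
(the full set is a seed); non-decreasing in the cutoff; invariant under a
common rigid transform of both structures. Fixed points are memoized
across seeds, which cuts the superposition count several-fold without
changing the result. Official CASP scoring uses LGA with its own settings;
small discrepancies against it are expected on borderline residues and are
a documented approximation, not hidden.

Superposition is the classical SVD solution minimizing RMSD, with the
determinant forced to +1: reflections are excluded because a mirror-image
CA trace is not a physically attainable model. Degenerate inputs (fewer
than 3 points) are rejected.

Per-residue pLDDT (0–100) is read from the B-factor column of predicted
models; domain confidence is the unweighted mean over the domain's
residues. Domain definitions are 1-based inclusive residue intervals,
sorted and non-overlapping, with the usual difficulty categories (FM,
FM/TBM, TBM-hard, TBM-easy).

## Ranking arithmetic

Per domain, a strategy's Z-score is (own GDT_TS − mean of the server
field) / sd of the server field, with the **sample** sd (n−1), the
convention of assessor practice; a degenerate field (sd 0) maps to z = 0.
A strategy's headline number is Sum Z (> 0), the sum of its positive
Z-scores — z ≤ 0 contributes nothing, so "non-negative" and "strictly
positive" summation coincide. High accuracy is the fraction of domains
with GDT_TS strictly above 70.

Model1 selects, per domain, the strategy with the highest mean pLDDT over
the domain (what a blind predictor can do); Model_best selects the highest
GDT_TS (the oracle ceiling). Ties break by a configurable strategy
priority, default the table's column order. By construction Model1's
GDT_TS never exceeds Model_best's on any domain.

Paired strategy comparisons use the two-sided Wilcoxon signed-rank test:
zero differences are dropped (p = 1 if none remain), tied absolute
differences receive average ranks, and the p-value is exact — the full
2^n sign-assignment distribution of W+, computed by dynamic programming
over doubled ranks — for n ≤ 25, with a normal approximation with
continuity and tie corrections above. The two-sided p is 2·min(lower
tail, upper tail) capped at 1, which makes the test symmetric in its
arguments. This is implemented in-package because library exact paths
decline ties and zeros; the test suite cross-checks it against
`scipy.stats.wilcoxon` on tie-free cases and against brute-force
enumeration on tied ones.

## The synthetic-data generator

The generator stands in for three real input classes.

**Homolog pools.** Each homolog draws a target identity `t` from a named
distribution (`point`, `uniform`, `truncnorm`, support within [0, 1]) and
substitutes every query position independently with probability 1 − t,
uniformly over the 19 alternative residues; insertions (lowercase) and
deletions (`-`) are applied per site at `indel_rate` (default 0, demo
0.02). The generative alignment is emitted directly as A3M, so realized
identity is binomially distributed around `t` and no aligner is needed.
Database-like pools use broad identity support (e.g. uniform(0.05, 1));
SRA-like pools are truncated below 0.5, reflecting the ~50% identity floor
of petabase-scale read mining.

With `n_founders` set, homologs are not independent: that many founder
lineages are drawn from the identity distribution and each member is a
near-copy of one founder, diverged at rate 1 − `within_id` (default
within-lineage identity 0.95). This models the redundancy of real pools —
a database holds many close relatives of few distinct lineages, which is
why real MSAs of thousands of sequences have N_eff values near 5 — and it
is what makes enrichment raise diversity: a merged source contributes
*new* lineages. Under the independent (star-tree) model, by contrast,
every sequence is maximally novel given its identity, pool diversity
saturates in n, and adding a ≥0.5-identity pool to a broad pool provably
*dilutes* mean column entropy; the star-tree model is retained as the
default because its realized identities are exactly controllable
(identity-recovery tests use it), but direction-of-effect claims about
merging use the clustered mode, which carries the feature the claim is
about.

**Decoy structures.** References are persistent self-avoiding random CA
walks (step 3.8 ± 0.1 Å, non-consecutive clearance ≥ 3.0 Å). Decoys come
in three modes: `rigid` (random proper rotation + translation — a perfect
model in a moved frame), `noise` (i.i.d. Gaussian displacement of sigma Å
per coordinate), and `split_displace` (a fraction kept exact, the rest
moved ~100 Å and scrambled with 5 Å noise, giving GDT_TS ≈ 100 × fraction
by construction). pLDDT is assigned as 100·exp(−d/4) clipped to [0, 100],
where d is the per-residue deviation **after** optimal superposition onto
the reference — measuring in the superposed frame is what makes a rigid
decoy score pLDDT 100, as a perfect model should. The exponential form is
a declared, monotone stand-in for a confidence head, not a calibrated
one; tests that need pLDDT/GDT disagreement construct it explicitly.

**Server fields.** Per-domain Gaussian GDT_TS draws (demo: 20 servers,
mean 55, sd 15) clipped to [0, 100].

What the generator does **not** emulate: real substitution preferences
(no substitution matrix — uniform replacement keeps expected identity
exact), phylogenetic tree structure beyond one level of lineages,
alignment errors (the true alignment is emitted), correlated structural
error along the chain, or calibrated confidence. Passing tests therefore
demonstrate the correctness and the qualitative directions of the
analysis arithmetic, not quantitative agreement with any real prediction
system.

## The demo study

`demo(seed)` is a scaled-down synthetic mirror of a multi-strategy
evaluation: 12 single-domain targets of length 60; four strategies
(database-only baseline, +SRA-like merge, +deep-search merge, and an
extra-recycles variant) built from pools of 60/80/60 members with 6/10/8
founders; per-strategy decoys at noise 3.0/2.0/1.8/1.0 Å, so better
enrichment and more recycles yield better models by construction; and a
20-server Gaussian field. The sizes keep a full end-to-end run near ten
seconds on one CPU while leaving every effect direction visible; all
randomness derives from the single seed, making runs byte-identical.

## Known limitations

- The GDT_TS search is a documented heuristic, not LGA; it can undercount
  marginal residues near a cutoff on highly fragmented models.
- N_eff values are tied to this package's weighting; cross-tool
  comparisons of absolute N_eff are approximate.
- The filter's greedy diversity cap is a 2-approximation; pathological
  distance structures exist where the exhaustive optimum differs.
- In the demo, pLDDT is monotone in true error by construction, so Model1
  equals Model_best there; the disagreement between them (the real-world
  selection gap) is exercised with constructed tables instead.
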