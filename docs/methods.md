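# Methods

## Contact definition

A contact site is an unordered residue pair with Cβ–Cβ distance ≤ *cutoff*
and sequence separation |i − j| ≥ *separation*; adjacent residues have
separation 1.  Both predicates are inclusive ("not greater than",
"no less than"); a `strict_separation` flag switches to |i − j| >
*separation* for comparison with tools that use the strict convention.
Supported sweeps cover cutoffs 6–12 Å and separations 1–15; prediction
truth uses 8 Å / separation 10, and the topology-divergence profiles use
10 Å and 12 Å at separation 7.

Glycine has no Cβ, so its Cα is the contact representative — the standard
convention.  A non-glycine residue whose side chain was not resolved falls
back to Cα with a warning; a residue with neither atom is carried with an
absent representative and excluded from every pair (never placed at the
origin).  Alternate locations resolve to the highest-occupancy conformer.

Residues are renumbered 1..n consecutively over observed residues, with
author numbering kept as metadata; `honor_numbering_gaps=True` preserves
author gaps instead.  Consecutive renumbering is the default because a
chain break would otherwise inflate the sequence separation of pairs that
flank it; neither behavior is canonical, so both are exposed.

## Degree statistics and the power fit

Average contact degree is taken over *all* residues of all domains,
including degree-0 residues and residues without coordinates.  Two spreads
are reported, because error bars on such plots can follow either
convention: the standard deviation over pooled residues (`std`) and over
per-domain means (`std_proteins`).

`fit_power_law` fits y = a·xᵇ by ordinary least squares on log-transformed
data — the deterministic textbook choice — and reports R² on the original
linear scale against a·xᵇ.  The convention matters when comparing with
fits performed in log space, so it is stated here and in the docstring.
Exact power data is recovered to machine precision; under multiplicative
lognormal noise the bias of b̂ shrinks with the noise (tested).

## Propensity statistics

`W_c` (per class) and `W_t` (per topology) average the per-protein ratio
Ic/Iw without weighting: each protein containing the type contributes one
ratio, exactly as the defining sum prescribes.  Types absent from every
protein of the group are NaN, never 0 — a 0 would assert "never in
contact".  The reported spread is over per-protein ratios, matching the
per-protein structure of the definition.

`f_p` tallies every contact once under its canonical unordered type pair;
homotypic pairs are not double-counted and `f_pn = f_p/(f_{a₁}·f_{a₂})`
carries no factor-2 correction for identical types (the definition divides
by the plain frequency product).  Consequence, verified by a null-model
test: with uniformly random contacts among equifrequent types, f_pn
converges to a constant *within* the homotypic and heterotypic categories,
with heterotypic ≈ 2 × homotypic.  Users comparing against double-counting
conventions must halve the heterotypic entries.

'X' handling: occurrence frequencies f_{a,k} exclude 'X' from numerator
and denominator; W_c/W_t report an 'X' row but S_t excludes it (maximum 20
types).  For f_p, X-containing contacts stay in the denominator Jw (the
literal "all contact sites") and appear under their own rows, so the table
still sums to 1; `include_x_in_total=False` drops them from both.

`S_t` uses the (N−1)-normalized root mean square of W_t − W_c over the
types present in the topology; with fewer than 2 types it is NaN with a
warning.  A topology coinciding with its whole class gives exactly 0.

## Class assignment

8-state codes simplify as H/G/I → helix, E → sheet, else coil; then
maximal helix runs ≤ 4 and sheet runs ≤ 2 dissolve to coil ("shorter than
five"/"shorter than three", read literally).  Fractions use the full
residue count.  The threshold rules are implemented with strict
inequalities exactly as stated, so helix = 15 % or sheet = 10 % satisfies
no rule and the domain is unassigned; this boundary behavior is pinned by
tests.  The alpha+beta rule as printed (< 15 % helix *and* < 10 % sheet)
labels structure-poor domains, which is unusual for that class name and
may be a transcription slip of the original composition scheme; it is
implemented as printed, with `conventional_alpha_beta=True` offering the
both-rich variant.  Unknown codes become coil with a warning.

## Re-ranking

The procedure partitions score-sorted pairs into a top-set of K (default
200), walks the top-set lowest-score-first removing pairs whose inclusion
moves the empirical type-pair frequency Jc/K away from the class value,
walks the rest-set highest-score-first adding pairs that move it closer,
and finally backfills from the removed pairs, latest-removed first, until
exactly K pairs remain.  Numerical choices:

- The denominator is K throughout, even while the top-set is temporarily
  smaller — the final set must again hold exactly K pairs.
- Removal decisions see the *current* top-set (counts update after every
  move); whether the original used live or frozen counts is not stated, so
  a `frozen_removal_counts` flag provides the alternative for sensitivity
  analysis.  The addition pass always updates live, mirroring the default.
- Score ties break by (i, j) lexicographic order before partitioning, so
  identical inputs give identical outputs.
- Final ordering for TP-rate evaluation: retained pairs keep descending
  score order, additions append in acceptance order, backfills append
  last.
- Pairs containing 'X' are never evaluated or moved; they occupy their
  original top-set slots.
- In f_pn mode the empirical value is (Jc/K)/(f_{a₁,d}·f_{a₂,d}) with
  frequencies computed within the domain ('X' excluded); the class table
  must then hold class-level f_pn values.

Unassigned domains have no class table and are skipped, as in the
assignment step.  A class table equal to the top-set's own empirical
distribution removes nothing (fixed point, tested).

## Evaluation

tp_rate(n) is the fraction of the first n ranked predictions that are true
contacts at exact (i, j) identity (a ±1-residue tolerance is not used, as
the looser convention is not universal).  Curves truncate when a domain
has fewer than n predictions rather than padding with failures; the
ensemble curve is the unweighted mean over domains wherever each domain is
defined, with the contributing count reported per n.

## Synthetic generator

Geometries are idealized: an α-helix with 1.5 Å rise, 100° turn and
~2.3 Å Cα radius (Cβ displaced 1.5 Å radially outward); an antiparallel
hairpin of two extended strands (3.4 Å rise) joined by a short arc, with
Cβ alternating ±0.6 Å out of the strand plane so registered cross-strand
pairs sit at the requested gap; and a self-avoiding random coil with
3.8 Å steps.  Cβ placement is a fixed offset, not side-chain modeling,
because only Cβ positions enter any computation.  A straight helix has an
empty map at separation 10 (its i,i+3/i,i+4 contacts are short-range),
while a hairpin is rich in long-range contacts — reproducing the
sheet-denser-than-helix degree ordering.

The prediction-improvement study uses `make_contact_biased_domain`: a
14-per-strand hairpin whose strand and turn residues are hydrophobic
(AVILMFWY) plus a 20-residue polar (DEKRNQST) tail placed far from the
hairpin and internally contact-free.  Every true contact is therefore
hydrophobic–hydrophobic while candidate pairs involving the tail are not —
the same kind of type bias that makes class-level pair statistics
informative in real structures.  Scores follow the Gaussian model
signal ~ N(1.0, 0.8) vs background ~ N(0.0, 0.8), chosen so raw top-10
precision sits near the 0.4 level typical of direct-information
predictors; re-ranking with K = 50 (~250 candidate pairs per domain) then
operates in the regime where the top-set holds both kinds of pairs.  The
study runs 200 evaluation domains with a class table estimated from a
separate 100-domain batch of the same generator.

What passing these tests does *not* show: the generator has no side-chain
packing, no realistic loop geometry, no correlated coevolution noise, and
its class bias is sharper than real class statistics, so the measured
improvement magnitude says nothing quantitative about real predictors —
only that the procedure moves the top-set composition in the intended
direction when the class statistics are informative.

## Problem sizes

The test-suite and acceptance-script ensembles are desk-scale by design:
500 mixed domains of 10–200 residues for the contact-map equivalence scan,
100 domains for the statistic transcriptions, 1000 random instances for
re-ranking equivalence, and 200 + 100 domains for the improvement study.
These sizes give stable statistics (standard errors an order of magnitude
below the tested margins) while the whole suite runs in well under a
minute.

## Known limitations

- PDB input only (no mmCIF); DSSP is parsed, never executed.
- No atom-level contact definitions beyond the Cβ representative.
- Propensity tables from small ensembles carry sampling noise that the
  package does not model; undefined entries are NaN and must be handled by
  the caller.
- The re-ranking quality depends entirely on how informative the supplied
  class table is for the domain at hand; with a flat or mismatched table
  the procedure approaches a no-op but cannot improve on the input scores.
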