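# Methods

## The sheet model

The package models the supramolecular Fuchsine sheet as a parametric graph
family F[m,n], m, n ≥ 1. The published description fixes three facts about
the family: a unit contributes 40 vertices and 42 edges with edge partition
{(3,3): 24, (1,3): 18}; units are joined by identifying pendant vertices of
adjacent units into common connector vertices; and the assembled sheet has
38mn + m + n vertices and 42mn edges with edge partition

    (3,3): 24mn,   (1,3): 14mn + 2(m+n),   (2,3): n(2m−2) + 2m(n−1).

The atom-level adjacency of the unit is only available as a drawing, not as
machine-readable data, and degree-based indices cannot see it anyway: they
are functions of the edge partition alone. The package therefore defines a
**canonical unit template** that provably realises the required partition: a
22-cycle `c0..c21` with two chords (`c0–c11`, `c5–c16`) and one pendant
`p_i` on each of the 18 cycle vertices not touched by a chord. That gives
22 degree-3 core vertices (4 via chords, 18 via pendants), 24 core–core
edges (22 cycle + 2 chords) and 18 (1,3) pendant edges — exactly the unit
contract. Template-independence is a tested property, not an assumption:
an alternative chord placement (`c0–c11`, `c3–c14`) and alternative port
choices yield bit-identical partitions and index values for every sheet
tested. Users can supply their own unit as a plain-text template file; it
is validated against the same contract (40/42 counts, partition, four
distinct pendant ports with degree-3 neighbours, connected, simple).

**Fusion is vertex identification, not edge insertion.** This is forced by
the published counts: the edge count stays 42mn while the vertex count
drops by one per junction. Each of the 2mn − m − n junctions merges two
pendants into one degree-2 connector, converting two (1,3) edges into two
(2,3) edges — which reproduces the three partition polynomials above, a
property the tests check for all m, n in 1..6.

Grid conventions: units are addressed 1-based as (column i, row j), i ≤ m,
j ≤ n; E/W ports fuse within a row, S/N ports fuse between consecutive
rows. Which published colour corresponds to which direction is irrelevant
to every output. Vertex labels carry `i.j:local` provenance and fused
vertices carry both parents' labels, so construction is deterministic and
exports are reproducible byte-for-byte.

## Exact arithmetic

All nine indices on the sheet's three degree pairs take values in
ℚ + ℚ√2 + ℚ√3 + ℚ√6 (the biquadratic field ℚ(√2, √3)); the `Surd` type
implements this ring over `fractions.Fraction` coefficients, with
multiplication driven by √2·√3 = √6 and inversion via the three Galois
conjugates. The exact square-root helper factors the radicand's squarefree
part and succeeds whenever that part is in {1, 2, 3, 6}, so the exact path
actually covers many degree pairs beyond the sheet's three; anything
outside the ring (e.g. ABC on a (3,5) pair, or general Randić with an
exponent outside {±1, ±1/2}) falls back to floating point with an explicit
warning. Float cross-checks use relative tolerance 1e-9: every sum here is
a few thousand well-conditioned terms. ABC on a (1,1) degree pair is 0 by
the formula (numerator d_u + d_v − 2 = 0) and is treated as defined, which
matters only for arbitrary user graphs. The test suite cross-checks the
ring arithmetic against sympy's symbolic radicals; sympy is a test-only
dependency.

## Closed forms

Because the partition counts are bilinear in (m, n), every index of the
family is `c_mn·mn + c_m·m + c_n·n + c_1` with coefficients in the surd
ring. Two independent routes compute it:

1. **Derivation**: multiply each partition polynomial by the exact
   per-edge value and sum (the published proof technique, executed in exact
   arithmetic).
2. **Fit**: build the four sheets F[1,1], F[1,2], F[2,1], F[2,2], compute
   each index by direct edge summation, and solve the exact 4×4 linear
   system in the basis {mn, m, n, 1} by Fraction-pivot Gaussian
   elimination. Degenerate sample sets (e.g. all m = n) are rejected as
   singular designs.

The master invariant — derivation, fit, and direct summation on built
sheets agree *exactly* for all m, n in 1..6 — is what the package means by
"the closed forms are correct". Derived forms satisfy c_m = c_n and
c_1 = 0 (the family is m↔n symmetric and every edge class count vanishes
at the formal point mn = m = n = 0); both are asserted after derivation
rather than assumed. Forms are rendered over the basis {mn, m+n}.

## Auditing the published results

Published closed forms and the published comparison table are stored
verbatim, including suspect entries; correctness is always decided by
direct graph computation, never by the fixtures. The comparison logic
classifies each index MATCH/MISMATCH against the literal reading of the
published statement and additionally records proof lines and alternative
readings of ambiguous typesetting:

- **HM**: statement header 118mn − 18m − 18n vs both its own proof line
  and the derivation, 1188mn − 18(m+n) — a dropped digit.
- **ABC**: the statement's `14√2/3` and `2√2/3` disagree with the derived
  `(14/3)√6` and `(2/3)√6`; reading the tokens as `14·√(2/3)` makes the
  statement correct. Both readings are recorded; neither is silently
  corrected. The published table's ABC column tracks the literal printed
  form, which supports the typo reading but is not conclusive.
- **R\_{−1/2}**: the statement's (m+n)(2 − √2) term is missing a division
  by √3; the mn coefficient is equivalent as printed.

The table audit recomputes all ten columns for F[k,k], k = 1..10, by
direct edge summation, renders integers by round-half-away-from-zero
(consistent with every verifiable published cell; no half-integer arises
on those rows), and flags every cell whose printed integer differs. Five
rows — F[1,1], F[2,2], F[3,3], F[5,5], F[10,10] — are treated as
verifiable worked examples; the mid-table rows contain cells
irreconcilable with any formula variant (e.g. the F[2,2] M1 entry 874,
off by 2 from every reading, whose origin the audit records but does not
rationalise) and are audited only. The audit also records one
discussion-level erratum: the claim that R_{−1/2} is the maximal index,
where computation shows HM dominates at every m = n (the companion claim
that R_{−1} is minimal is confirmed).

## Problem sizes, determinism, limitations

Everything here is desk-scale: the largest graph the package routinely
builds, F[10,10], has 3,820 vertices and 4,200 edges and computes in well
under a second; the full test suite and the reproduction script each run
in tens of seconds. There is no randomness anywhere in the pipeline —
identical inputs give identical bytes; property tests that use random
graphs fix their own seeds, and the reproduction script uses its seed only
to shuffle vertex labels as a relabelling-invariance exercise.

Known limitations: the unit template is a degree-faithful stand-in, not
the chemical structure — anything beyond the edge partition (distances,
resistance distances, eccentricities, 3D geometry, atom identities) is out
of reach of this representation and out of scope; directed graphs,
multigraphs and weighted edges are not supported; closed forms are
implemented for this family only, since nothing beyond bilinear shapes is
needed for it.
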