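# fuchsheet

Exact computation of degree-based topological indices on the supramolecular
Fuchsine sheet graph family **F[m,n]**.

Fuchsine (C20H19N3·HCl) is a magenta dye whose supramolecular assemblies are
of interest as drug carriers, stains, and sensing materials. In chemical
graph theory such a structure is studied through its molecular graph: atoms
are vertices, bonds are edges, and *topological indices* — numeric graph
invariants of the form

```
I(G) = Σ_{uv ∈ E(G)} f(d_u, d_v)
```

for a symmetric function `f` of the endpoint degrees — serve as structure
descriptors in QSPR/QSAR work. This package is for researchers who want
those indices on the Fuchsine sheet family computed **exactly**, with every
published closed form independently re-derived and audited.

## The graph family and its indices

A single Fuchsine unit is a 40-vertex, 42-edge graph whose edge partition by
endpoint degrees is `{(3,3): 24, (1,3): 18}`. The sheet F[m,n] joins an
m × n grid of units by *pendant fusion*: designated degree-1 "port" vertices
of adjacent units are identified into one degree-2 connector. Hence

- |V(F[m,n])| = 38mn + m + n,  |E(F[m,n])| = 42mn,
- edge partition: (3,3): 24mn, (1,3): 14mn + 2(m+n), (2,3): 4mn − 2m − 2n.

Supported indices (per-edge functions): first/second Zagreb `M1 = d_u+d_v`,
`M2 = d_u·d_v`, hyper-Zagreb `HM = (d_u+d_v)²`, forgotten `F = d_u²+d_v²`,
harmonic `H = 2/(d_u+d_v)`, general Randić `R_λ = (d_u d_v)^λ`,
atom-bond connectivity `ABC = √((d_u+d_v−2)/(d_u d_v))`, and
geometric–arithmetic `GA = 2√(d_u d_v)/(d_u+d_v)`.

On this family every per-edge value lies in the ring ℚ + ℚ√2 + ℚ√3 + ℚ√6,
so the package computes index values and closed forms in exact surd
arithmetic; "the derived formula equals the direct summation" is a decidable
equality, not a tolerance check. Each index of the family is a bilinear
polynomial `c_mn·mn + c_m·m + c_n·n + c_1`, obtained two independent ways
(symbolic derivation over the partition, and an exact 4-point fit against
graphs actually built) and compared coefficient-by-coefficient with the
published statements.

## Worked example

```text
$ fuchsheet indices --m 1 --n 1 --exact
M1      216      = 216
M2      270      = 270
HM      1152     = 1152
F       612      = 612
ABC     30.6969  = 16 + 6*sqrt6
GA      39.5885  = 24 + 9*sqrt3
R-1     8.66667  = 26/3
R1/2    103.177  = 72 + 18*sqrt3
R-1/2   18.3923  = 8 + 6*sqrt3
R1      270      = 270
```

These are the ten indices of the single unit F[1,1] (42 edges), each shown
as a decimal and as its exact surd value. The integer-valued indices match
the published comparison table directly; GA and R_{1/2} match it after
rounding (40 and 103). The published R_{−1} entry (7) disagrees with the
exact value 26/3 ≈ 8.67 — one of the discrepancies the audit reports.

```text
$ fuchsheet closed-form --index HM --index ABC --compare-published
HM: (1188)*mn + (-18)*(m+n)   [MISMATCH vs published]
ABC: (16 + 2*sqrt2 + 14/3*sqrt6)*mn + (-sqrt2 + 2/3*sqrt6)*(m+n)   [MISMATCH vs published]
```

The hyper-Zagreb closed form derives to 1188mn − 18(m+n); the published
statement's header prints 118mn (its own proof line agrees with 1188).
The published ABC statement prints √2 where the derivation gives √6 —
reading its ambiguous `14√2/3` as `14·√(2/3)` makes it correct, and the
comparison records both readings. `fuchsheet errata --json` emits the full
machine-readable audit of every inconsistent published cell and formula;
`fuchsheet table` recomputes the comparison table and `fuchsheet plot`
draws the index-growth comparison figure.

Other subcommands: `fuchsheet generate --m M --n N` writes the sheet as an
edge list or GraphML; `--template FILE` substitutes a user-supplied unit
template (plain-text `edge u v` / `port W|E|N|S v` format).

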