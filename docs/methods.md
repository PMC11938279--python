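# Methods

This note records the models, conventions and numerical choices behind
`fullertk`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open design decisions
were resolved.

## Graph model and conventions

A fullerene on `n` vertices is represented purely combinatorially as a
rotation system: for each vertex the counterclockwise cyclic order of its
neighbours. Faces are traced with the fixed rule "leave through the edge
clockwise-next after the reversed edge"; Euler's relation `V − E + F = 2`
is enforced on every constructed embedding, so genus errors surface
immediately. Vertex ids are 0-based and contiguous; pentagon positions in
spiral codes are 1-based, following the established convention for
pentagon-index sequences. Most algorithms run on the dual triangulation
`T_n` (`m = n/2 + 2` vertices, twelve of degree 5), because every face
operation becomes a vertex/edge operation there. Duals built from plain
edge lists get their embedding from planarity testing; for the
3-connected graphs in scope the embedding is unique up to reflection, and
all spiral machinery scans both orientations, so no result depends on the
reflection choice.

Isomorphism of fullerenes is decided by canonical-spiral equality.
A graph-isomorphism routine (VF2) is used only inside tests as an
independent oracle on small cases.

## Face spirals

Windup follows the classical dual-side algorithm: vertex `j` (target
degree 5 or 6) connects to the head and tail of the open spiral boundary,
cascading over saturated vertices; the final vertex must close every open
vertex exactly. Failure modes (double edge, degree overflow, premature
closure, pinched spiral) are rejections, not errors: a well-formed code
may simply not close. Unwinding mirrors the same rule on a finished
triangulation — the next face is the unique unvisited common neighbour of
the boundary head and tail — and every completed walk is verified by
winding its size sequence back up before it can influence a canonicity
decision.

The canonical code is the lexicographic minimum over all start pairs and
both winding directions (rather than a fixed "6n starts" count, whose
bookkeeping is ambiguous for small graphs); this is exactly what
canonicity requires. Enumeration is a depth-first search over partial
size sequences with three prunings: windup failure, pentagon-count
feasibility, and a branch-and-bound bound on the boundary's missing
degree (the `R` remaining faces supply at most `6R − (pentagons left)`
edge-endpoints, of which `2(R−1)` are consumed internally). Each
completed spiral is emitted iff it equals its own canonical form, which
makes the output duplicate-free without storing previously seen graphs.
The enumerator, canonicity filter and sampler are numba kernels; a pure
Python reference implementation of the same semantics is kept alongside
and cross-checked in the tests (including brute-force 12-subset
enumeration for n ≤ 28). Enumerated counts for n ≤ 68 agree with the
published fullerene census.

The acceptance–rejection sampler draws uniform 12-subsets of face
positions, winds them up and accepts exactly the canonical vectors; since
each isomer class has exactly one canonical code, accepted isomers are
uniform on `C_n`. Candidate sequences default to the face count
`m = n/2 + 2`; a length-`n` compatibility convention is kept only to
reproduce the often-quoted ~1e−9 acceptance rate for C60
(`1812 / C(60,12) ≈ 1.3e−9`).

Generalized spirals with jumps are out of scope: the first fullerene
without any face spiral has n = 380, far beyond the desk-scale ranges
used here, and unspiralable inputs raise an explicit error.

## Stone–Wales operations

The polyhedral flip removes an edge of the triangulation and joins the
apexes of its two faces; apexes are read off the rotation system (not
graph-common neighbours, which mislead on dense small graphs), and flips
that would create a parallel edge or a degree-2 vertex are refused — a
stricter guard than the textbook description, needed for closure on
simple graphs.

The gSW operation is defined functionally (the reversed-pairs sequence
must be a gSW path of the image). The edge rewiring implemented here is
the minimal cascade of `w − 1` diagonal flips along the path: remove
`(v_2k, v_2k+1)` and insert `(v_2k−1, v_2k+2)` for `k = 1..w−1`. This
realizes the defining condition, exchanges degrees exactly at the two
ends (so the result is again a dual fullerene), preserves a valid planar
embedding, and is self-inverse along the image path — all verified as
postconditions over every isomer with n ≤ 40. The classic Stone–Wales
rotation is the w = 2 case and coincides with the single flip. The
*radial* generalization is not implemented.

Path search is a zigzag DFS with branching factor ≤ 2 (the skip rule
forces each extension to be a common neighbour of the last two vertices),
explored in ascending vertex order for deterministic output. Two notions
are exposed: full paths (interior degrees unconstrained, the notion used
for the applicability scan) and hexagon-interior paths (interior vertices
restricted to `T_n^6`, the zigzag formulation that the cut-partition
geometry controls). The distinction matters: C32,5 carries a w = 3 path
through two pentagon-interior vertices although its hexagonal subgraph is
just two disjoint triangles, so the partition predicate below is
evaluated against the hexagon-interior notion.

Uniform random flip walks flag every state that satisfies the
dual-fullerene census. With uniform edge selection such walks do not, in
practice, reach fullerene states from prism-dual seeds at desk scale
(probed to 3×10⁴ steps over 20 seeds at m = 12, 14); the energy-guided
selection of the original randomized algorithm is deliberately out of
scope, so the walk is offered as a primitive, not a sampler.

## Families

*Triangular patches.* A t-triangle is the lattice triangle with `t + 1`
rows (`(t+1)(t+2)/2` vertices, `t²` inner triangles). Truncating corner
`i` removes its `r_i` nearest rows — `r_i(r_i+1)/2` vertices and `r_i²`
inner triangles — exposing a cut row of `r_i + 1` vertices whose mutual
edges are the open edges. This row-count convention is the one under
which the glued family's stated census works out exactly (per piece
`4t² − 3(t−1)² = t² + 6t − 3` triangles; see below).

*The gSW-free family.* Four `(2t,(t−1,t−1,t−1))`-triangles are glued in
a tetrahedral pattern: piece `p`'s corner toward `q` is identified with
piece `q`'s corner toward `p`, cut row against cut row. The six gluings
identify `6t` vertices, giving a hexagonal graph with `2(t² + 6t + 2)`
vertices and four hexagonal holes whose boundary degrees alternate 4 and
5; inserting a triangle of pentagonal vertices into each hole yields a
valid dual fullerene with `n = 4(t² + 6t + 7)`. The per-gluing
orientations are fixed by a deterministic search over the 2⁶
identification patterns, validated by planarity and the face census; the
construction is then checked against its postconditions (validity,
pentagon partition (3,3,3,3), no gSW path) for t = 2, 3, 4.

*Seed fullerenes for n ≥ 36.* The dual of the first C36 isomer is split,
once, into a fixed cap and a growable component whose boundary 6-cycle
has degree-deficit labels (1,2,2,2,2,3); the split is found by an
exhaustive search over connected caps, so no figure-derived edge list is
hard-coded. Each growth step attaches one new vertex to the label-1
vertex and its boundary neighbours labelled 2 and 3, which provably
reproduces the same label vector; after `n/2 − 18` steps the cap is sewn
back along the recorded cyclic slot matching. The n = 36 case round-trips
to the original isomer exactly.

*Nanotubes, Goldberg polyhedra, chamfer.* The `(5,0)`-nanotube dual is
built layer by layer (two 6-pentagon caps, `(n−20)/10` five-vertex
belts). Goldberg duals are built by Goldberg–Coxeter subdivision: lattice
points of the `(p,q)` master triangle are mapped barycentrically onto
consistently oriented icosahedron faces, projected to the sphere, and the
triangulation is read off the convex hull — this handles chiral classes
such as (2,1) without bespoke edge bookkeeping. Chamfering implements the
(2,0) subdivision of an arbitrary dual and maps `C_n` to `C_{4n}`; the
n = 80 and n = 96 gSW-free counterexamples are realized as Goldberg(2,0)
and the chamfered C24 respectively, and verified against their published
cut-partitions.

## Cut-partitions

The hexagonal subgraph inherits its rotation (and hence faces) from the
dual; faces larger than a triangle mark removed pentagon clusters.
Two readings resolved here deserve note. First, large-face incidences
are counted *with multiplicity*: once cuts merge two holes into one face,
a vertex meeting that face twice still separates two regions and must be
cut again. Second, the degree-5 slitting pass is a rotation-level
operation: the slit runs along the path, duplicates its vertices and
edges on both sides, and exits each endpoint through its unique
large-face wedge. That replication is what lets two glued patches each
keep a copy of a shared open edge. Cut arcs are chosen by simulation
(all contiguous arcs are tried; minimal moved-edge count wins, ties by
lexicographically smallest moved neighbours); qualifying slit paths are
the shortest triangle-bordered paths between degree-5 vertices, pairs
ordered by (length, lexicographic). Inputs on which no admissible cut or
path exists raise a typed error rather than guessing; the predicate scan
records such cases as non-triangle partitions.

Component recognition is constructive: candidate `(t,(r1,r2,r3))`
parameters compatible with the vertex count are generated and compared by
graph isomorphism against freshly built patches.

## Spectral characters

Characters are computed from symmetric eigendecompositions of
`A + (β/α)D` (numerically stable for the 30–80 vertex matrices in
scope); the trace of the dense matrix exponential is retained as an
independent cross-check at 1e−9 relative. The dual-graph working
parameters are `α = 2β = 1/2`; `(1, 0)` is the direct-graph convention.
Newton polynomials double as closed-walk counts and are cross-checked
against explicit walk enumeration on small graphs.

Injectivity scans compare sorted characters at a relative tolerance of
1e−11 by default: above the ~1e−13 eigensolver noise, below the smallest
genuine character gap observed between distinct isomers at desk scale
(~9e−10 relative, within C50). A coarser tolerance would misreport that
resolvable near-pair as a collision; the tolerance is a parameter for
sensitivity studies. Range experiments report per-`n` character minima
and maxima and consecutive-range overlap flags; histograms use
equal-width density bins on [0, 1] after centring by the Goldberg dual
and scaling by the nanotube dual, available only for `n` admitting both
(20, 60, 80, 140, …).

`riemann_zeta` — the constant `ζ(9) ≈ 1.00200839` enters the asymptotic
isomer-count formula — evaluates the Dirichlet series by a 200-term
partial sum plus the Euler–Maclaurin tail through the `B_6` term
(first omitted term `O(200^{−s−7})`), machine-precise for all `s > 1`
used here; the plain integral-test bound is exposed for error analysis.

## Problem sizes and what the tests show

The default experiments enumerate all isomers with n ≤ 68 (the
gSW-applicability scan), evaluate characters for n ∈ {58, 60, 62} (about
5,400 eigenproblems), scan character collisions to n = 50, exercise
operation properties (spiral roundtrip, gSW self-inverse, SW ≡ gSW(w=2))
on every isomer with n ≤ 40, and draw 10,000 accepted samples at n = 28.
These sizes keep a full run in the minutes range on a single core.
All inputs are generated by the package itself; the experiments therefore
validate internal consistency and agreement with published desk-scale
values (census counts, the buckminsterfullerene spiral and rank, the
known gSW-free isomers and their partitions), not behaviour at the
n ≳ 100 scales where different phenomena (spiral failures, new
counterexample structures) are known to appear.
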