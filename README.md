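# fullertk

A combinatorial toolkit for **fullerene graphs**: 3-regular planar graphs
whose faces are 12 pentagons and `n/2 − 10` hexagons, the mathematical
skeleton of hollow-carbon molecules. Most algorithms work on the **dual
fullerene** `T_n`, a sphere triangulation on `m = n/2 + 2` vertices with
degrees in {5, 6} and exactly twelve vertices of degree 5.

It is aimed at researchers studying fullerene enumeration, isomerization
and spectral descriptors, and implements:

* **Face spirals** — peel the polyhedron face by face in a tight spiral and
  record pentagon (5) vs hexagon (6). The canonical code of an isomer is
  the lexicographically smallest successful spiral; listing canonical codes
  in order enumerates the isomer classes `C_{n,1} … C_{n,iso(n)}`.
  Includes a backtracking enumerator (numba-accelerated), windup/unwind,
  ranking, and the acceptance–rejection sampler that draws uniform random
  isomers by accepting exactly the canonical pentagon-position vectors.
* **Stone–Wales rewriting** on dual triangulations: the polyhedral flip
  (pSW, a single diagonal flip), the generalized Stone–Wales operation
  (gSW) that transports a pentagonal defect along a zigzag path
  `(v_1, …, v_2w)` with degree-5 ends and skip-edges `(v_i, v_{i+2})`,
  gSW-path search, and random flip walks.
* **Named families**: `(5,0)`-nanotubes, Goldberg polyhedra `G(p,q)`
  (`n = 20(p² + pq + q²)`), chamfering (Goldberg–Coxeter (2,0)
  subdivision), an infinite gSW-free family built from four glued
  truncated triangular patches (`n = 4(t² + 6t + 7)`), a seed-fullerene
  construction for every feasible `n ≥ 36`, and prism-dual bipyramids.
* **Cut-partitions**: decompose the hexagonal subgraph `T_n^6` by vertex
  cuts and path slits into *t-triangles* and corner-truncated
  `(t,(r1,r2,r3))`-triangles, and evaluate the partition ↔ gSW-path
  predicate on isomer ranges.
* **Spectral characters**: Newton polynomials `N(M,k) = tr M^k` and the
  `(α,β)`-character `tr exp(αA + βD) = Σ_j exp(α λ_j)` with
  `λ_j` the eigenvalues of `A + (β/α)D`; normalization against the
  extremal nanotube/Goldberg structures; range-separation and histogram
  experiments; collision scans supporting the character's conjectured
  injectivity.

## Worked example

```python
from fullertk.spiral import enumerate_codes, isomer_count, unwind_canonical, windup
from fullertk.fullerene import dualize, pentagon_partition
from fullertk.spectra import character
from fullertk.families import goldberg

print("iso(28) =", isomer_count(28))
for j, code in enumerate(enumerate_codes(28), 1):
    t = dualize(windup(code))
    print(f"C28,{j}: positions={code.pentagon_positions} "
          f"partition={pentagon_partition(t).parts} ch={character(t):.6f}")

code = unwind_canonical(goldberg(1, 1))
print("goldberg(1,1) code:", code.pentagon_positions)
print("rank:", enumerate_codes(60).index(code) + 1)
```

prints

```
iso(28) = 2
C28,1: positions=(1, 2, 3, 4, 5, 7, 10, 12, 13, 14, 15, 16) partition=(12,) ch=131.175247
C28,2: positions=(1, 2, 3, 5, 7, 9, 10, 11, 12, 13, 14, 15) partition=(12,) ch=131.092990
goldberg(1,1) code: (1, 7, 9, 11, 13, 15, 18, 20, 22, 24, 26, 32)
rank: 1812
```

There are two C28 isomers; in both, all 12 pentagons form one cluster
(partition `(12,)` of the pentagon-adjacency components), and their
`(1/2, 1/4)`-characters differ already in the third digit — the character
separates them. The `(1,1)`-Goldberg polyhedron is buckminsterfullerene:
its canonical spiral is the classic sequence `1 7 9 11 13 15 18 20 22 24
26 32` and it is the 1812-th (last) C60 isomer in lexicographic order —
the unique one obeying the isolated-pentagon rule.

A command-line interface mirrors the library:

```sh
fullertk enumerate --n 60 --count-only     # 1812
fullertk sample --n 28 --seed 7 --count 3
fullertk make --family goldberg --params 1,1
fullertk gsw-scan --n-min 20 --n-max 40
```

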