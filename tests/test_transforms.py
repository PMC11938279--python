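import collections
from itertools import permutations

import pytest

from fullertk.embedding import PlanarEmbedding
from fullertk.fullerene import DualTriangulation
from fullertk.spiral import canonical_code, enumerate_codes, windup_adjacency, windup_dual
from fullertk.transforms import (
    FlipError,
    GswPath,
    apply_gsw,
    find_gsw_paths,
    has_gsw_path,
    is_dual_fullerene,
    psw_flip,
    psw_random_walk,
    transformed_path,
)


def brute_force_gsw_paths(adj, degs, max_len=6):
    """Oracle: scan all vertex sequences up to ``max_len`` for gSW paths."""
    m = len(adj)
    found = []
    for length in range(4, max_len + 1, 2):
        for seq in permutations(range(m), length):
            if degs[seq[0]] != 5 or degs[seq[-1]] != 5:
                continue
            if degs[seq[1]] != 6 or degs[seq[-2]] != 6:
                continue
            if any(seq[i + 1] not in adj[seq[i]] for i in range(length - 1)):
                continue
            if any(seq[i + 2] not in adj[seq[i]] for i in range(length - 2)):
                continue
            found.append(seq)
    return sorted(found)


def test_psw_flip_is_involution(c24_dual):
    edge = (0, sorted(c24_dual.adjacency[0])[0])
    flipped = psw_flip(c24_dual, edge)
    # the new edge joins the two previous common neighbours
    new_edge = [
        e for e in flipped.edges() if e not in set(c24_dual.embedding.edges())
    ]
    assert len(new_edge) == 1
    back = psw_flip(flipped, new_edge[0])
    assert sorted(back.edges()) == sorted(c24_dual.embedding.edges())


def test_psw_flip_degree_bookkeeping(c20_dual):
    e = (0, sorted(c20_dual.adjacency[0])[0])
    flipped = psw_flip(c20_dual, e)
    assert sorted(collections.Counter(flipped.degrees()).items()) == [
        (4, 2), (5, 8), (6, 2)
    ]
    assert not is_dual_fullerene(flipped)


def test_psw_flip_rejects_nonedge_and_bad_flip(c20_dual):
    with pytest.raises(FlipError):
        psw_flip(c20_dual, (0, 11))  # antipodal: not an edge in icosahedron
    # SW configuration: flipping (deg6, deg6) with deg5 common nbrs stays a dual
    t = windup_dual(enumerate_codes(28)[0])
    paths = [p for p in find_gsw_paths(t, max_w=2)]
    v = paths[0].vertices
    out = psw_flip(t, (v[1], v[2]))
    assert is_dual_fullerene(out)


def test_c20_has_no_gsw_path(c20_dual):
    assert find_gsw_paths(c20_dual) == []
    assert not has_gsw_path(c20_dual)


def test_c24_paths_match_bruteforce(c24_dual):
    adj = [set(s) for s in c24_dual.adjacency]
    degs = c24_dual.embedding.degrees()
    ours = [
        p.vertices for p in find_gsw_paths(c24_dual, max_w=3)
    ]
    # C24's shortest gSW paths have w = 4, so both searches agree on empty
    assert sorted(ours) == brute_force_gsw_paths(adj, degs, max_len=6)
    assert find_gsw_paths(c24_dual)  # longer paths do exist


def test_c28_w2_paths_match_bruteforce():
    t = windup_dual(enumerate_codes(28)[0])
    adj = [set(s) for s in t.adjacency]
    degs = t.embedding.degrees()
    ours = [p.vertices for p in find_gsw_paths(t, max_w=2)]
    oracle = brute_force_gsw_paths(adj, degs, max_len=4)
    assert sorted(ours) == oracle
    assert ours  # classic SW sites exist


def test_gsw_path_validation(c24_dual):
    from fullertk.embedding import ValidationError

    with pytest.raises(ValidationError):
        GswPath((0, 1, 2)).validate_in(c24_dual)  # odd length
    good = find_gsw_paths(c24_dual)[0]
    good.validate_in(c24_dual)


@pytest.mark.parametrize("n", [24, 26, 28, 30, 32, 34, 36, 38, 40])
def test_gsw_apply_postconditions_and_self_inverse(n):
    """For one path of each length per isomer: closure, degree exchange,
    Definition-style image path, and double application returning the input."""
    for code in enumerate_codes(n):
        t = windup_dual(code)
        base = canonical_code(t)
        paths = find_gsw_paths(t)
        seen_w = set()
        for p in paths:
            if p.w in seen_w:
                continue
            seen_w.add(p.w)
            out = apply_gsw(t, p)  # validates internally: still a dual
            v = p.vertices
            degs_in = t.embedding.degrees()
            degs_out = out.embedding.degrees()
            assert degs_out[v[0]] == 6 and degs_out[v[1]] == 5
            assert degs_out[v[-2]] == 5 and degs_out[v[-1]] == 6
            mid = v[2:-2]
            assert all(degs_out[x] == degs_in[x] for x in mid)
            tp = transformed_path(p)
            tp.validate_in(out)
            back = apply_gsw(out, tp)
            assert canonical_code(back) == base


def test_sw_equals_gsw_w2():
    for n in (28, 30, 32):
        for code in enumerate_codes(n):
            t = windup_dual(code)
            for p in find_gsw_paths(t, max_w=2):
                v = p.vertices
                via_flip = DualTriangulation(psw_flip(t, (v[1], v[2])))
                via_gsw = apply_gsw(t, p)
                assert canonical_code(via_flip) == canonical_code(via_gsw)
                break  # one site per isomer suffices


def test_psw_walk_preserves_triangulation():
    from fullertk.embedding import trace_faces
    from fullertk.families import bipyramid_seed

    seed = bipyramid_seed(8)
    trace = psw_random_walk(seed, steps=12, rng_seed=11)
    assert len(trace) == 13
    assert trace[0][0] is seed
    for emb, _flag in trace:
        assert all(len(f) == 3 for f in trace_faces(emb))
    # reproducibility
    again = psw_random_walk(seed, steps=12, rng_seed=11)
    assert [e.rotation for e, _ in again] == [e.rotation for e, _ in trace]


def test_psw_walk_flags_dual_fullerene_states(c24_dual):
    """Walk flags agree with an independent census check at every state;
    starting from a dual fullerene the first flag is set."""
    trace = psw_random_walk(c24_dual, steps=8, rng_seed=3)
    assert trace[0][1] is True
    for emb, flag in trace:
        assert flag == is_dual_fullerene(emb)
    # one flip away from a fullerene the census is broken
    assert trace[1][1] is False
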