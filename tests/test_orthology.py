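"""Protein-pair scoring and best-hit / ortholog / one-to-one rules."""

import numpy as np
import pandas as pd
import pytest

from motiftrace.alphabet import ALPHABET
from motiftrace.orthology import (PairClass, ProteinRecord, best_hits,
                                  build_graph, classify_pairs,
                                  local_align_score, make_aligner,
                                  read_pairs_tsv, score_table,
                                  within_genome_scores, write_pairs_tsv)
from motiftrace.simulate import EvolParams, MotifSpec, simulate_dataset


# ---------------------------------------------------------------------------
# Smith-Waterman scoring

def test_identity_score_sums_blosum_diagonal():
    # BLOSUM62 diagonal: A=4, C=9, D=6, E=5
    assert local_align_score("ACDE", "ACDE") == 24.0


def test_all_negative_matrix_entries_floor_at_zero():
    # W:P = -4 in BLOSUM62; the optimal local alignment is empty
    assert local_align_score("W", "P") == 0.0


def test_score_is_symmetric(rng):
    for _ in range(10):
        s1 = "".join(rng.choice(list(ALPHABET), 30))
        s2 = "".join(rng.choice(list(ALPHABET), 25))
        assert local_align_score(s1, s2) == local_align_score(s2, s1)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        local_align_score("", "ACDE")


def _sw_affine_oracle(s1: str, s2: str, matrix, gap_open=11, gap_extend=1):
    """Independent O(nm) Gotoh dynamic program for local affine alignment;
    a gap of length k costs gap_open + k*gap_extend."""
    n, m = len(s1), len(s2)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))       # best ending in match/mismatch
    E = np.full((n + 1, m + 1), NEG)   # gap in s2 (horizontal)
    F = np.full((n + 1, m + 1), NEG)   # gap in s1 (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            sub = matrix[s1[i - 1], s2[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_scores_match_independent_dynamic_program(rng):
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load("BLOSUM62")
    aligner = make_aligner()
    for _ in range(100):
        s1 = "".join(rng.choice(list(ALPHABET), 50))
        s2 = "".join(rng.choice(list(ALPHABET), 50))
        got = local_align_score(s1, s2, aligner=aligner)
        assert got == pytest.approx(_sw_affine_oracle(s1, s2, mat))


# ---------------------------------------------------------------------------
# best hits

def _rec(genome, protein, seq):
    return ProteinRecord(genome, protein, seq)


def test_single_proteins_are_mutual_best_hits():
    A = [_rec("gA", "a1", "MKWVLLLA")]
    B = [_rec("gB", "b1", "MKWVLLLA")]
    hAB = best_hits(A, B)
    hBA = best_hits(B, A)
    assert list(hAB.itertuples(index=False))[0][:2] == ("a1", "b1")
    assert list(hBA.itertuples(index=False))[0][:2] == ("b1", "a1")


def test_best_hit_takes_highest_score():
    A = [_rec("gA", "a1", "MKWVLLLAGHHEW")]
    B = [_rec("gB", "b1", "MKWVLLLAGHHEW"),     # identical: higher score
         _rec("gB", "b2", "MKWVAAAAGHHEW")]
    h = best_hits(A, B)
    assert h.loc[h["query"] == "a1", "subject"].item() == "b1"


def test_equal_scores_break_ties_lexicographically():
    scores = pd.DataFrame([("a1", "b2", 50.0), ("a1", "b1", 50.0)],
                          columns=["query", "subject", "score"])
    A = [_rec("gA", "a1", "MKWV")]
    B = [_rec("gB", "b1", "MKWV"), _rec("gB", "b2", "MKWV")]
    h = best_hits(A, B, scores=scores)
    assert h.loc[h["query"] == "a1", "subject"].item() == "b1"


def test_same_genome_rejected_and_empty_warns():
    A = [_rec("g", "a1", "MKWV")]
    with pytest.raises(ValueError):
        best_hits(A, A)
    with pytest.warns(UserWarning):
        out = best_hits(A, [])
    assert out.empty


# ---------------------------------------------------------------------------
# classification rules

def _tables(cross, withinA=(), withinB=()):
    """cross: dict (a, b) -> score; within: iterable of (p, q, score)."""
    scores = pd.DataFrame([(a, b, s) for (a, b), s in cross.items()],
                          columns=["query", "subject", "score"])
    rev = pd.DataFrame([(b, a, s) for (a, b), s in cross.items()],
                       columns=["query", "subject", "score"])
    bestAB = scores.sort_values(["query", "score", "subject"],
                                ascending=[True, False, True]
                                ).groupby("query", as_index=False).first()
    bestBA = rev.sort_values(["query", "score", "subject"],
                             ascending=[True, False, True]
                             ).groupby("query", as_index=False).first()

    def wtab(rows):
        out = []
        for p, q, s in rows:
            out.append((p, q, s))
            out.append((q, p, s))
        return pd.DataFrame(out, columns=["query", "subject", "score"])

    return bestAB, bestBA, wtab(withinA), wtab(withinB), scores


def test_single_mutual_pair_is_one_to_one():
    hAB, hBA, wA, wB, cross = _tables({("a", "b"): 50.0})
    out = classify_pairs(hAB, hBA, wA, wB, "gA", "gB", cross_scores=cross)
    assert out == [PairClass(("gA", "a"), ("gB", "b"), "one_to_one")]


def test_stronger_within_genome_paralog_downgrades_to_ortholog():
    hAB, hBA, wA, wB, cross = _tables({("a", "b"): 50.0},
                                      withinA=[("a", "a2", 60.0)])
    out = classify_pairs(hAB, hBA, wA, wB, "gA", "gB", cross_scores=cross)
    assert out[0].cls == "ortholog"


def test_weaker_paralog_keeps_one_to_one():
    hAB, hBA, wA, wB, cross = _tables({("a", "b"): 50.0},
                                      withinA=[("a", "a2", 40.0)])
    out = classify_pairs(hAB, hBA, wA, wB, "gA", "gB", cross_scores=cross)
    assert out[0].cls == "one_to_one"


def test_nonreciprocal_best_is_best_hit_only():
    # a's best is b, but b's best is a2
    cross = {("a", "b"): 50.0, ("a2", "b"): 70.0, ("a", "b2"): 10.0}
    hAB, hBA, wA, wB, scores = _tables(cross)
    out = classify_pairs(hAB, hBA, wA, wB, "gA", "gB", cross_scores=scores)
    classes = {(p.a[1], p.b[1]): p.cls for p in out}
    assert classes[("a", "b")] == "best_hit"
    assert classes[("a2", "b")] == "one_to_one"


def test_classification_invariant_under_genome_swap():
    cross = {("a", "b"): 50.0, ("a2", "b"): 70.0, ("a", "b2"): 30.0,
             ("a2", "b2"): 20.0}
    hAB, hBA, wA, wB, scores = _tables(cross)
    fwd = classify_pairs(hAB, hBA, wA, wB, "gA", "gB", cross_scores=scores)
    swapped = {(b, a): s for (a, b), s in cross.items()}
    hBA2, hAB2, wB2, wA2, scores2 = _tables(swapped)
    rev = classify_pairs(hBA2, hAB2, wB2, wA2, "gB", "gA",
                         cross_scores=scores2)
    fwd_set = {(p.a, p.b, p.cls) for p in fwd}
    rev_set = {(p.b, p.a, p.cls) for p in rev}
    assert fwd_set == rev_set


def test_class_hierarchy_subsets(rng):
    """one_to_one set is a subset of the reciprocal-best (ortholog) set."""
    for trial in range(20):
        na, nb = rng.integers(2, 5), rng.integers(2, 5)
        cross = {(f"a{i}", f"b{j}"): float(rng.integers(1, 100))
                 for i in range(na) for j in range(nb)}
        withinA = [(f"a{i}", f"a{j}", float(rng.integers(1, 100)))
                   for i in range(na) for j in range(i + 1, na)]
        hAB, hBA, wA, wB, scores = _tables(cross, withinA=withinA)
        out = classify_pairs(hAB, hBA, wA, wB, "gA", "gB",
                             cross_scores=scores)
        o2o = {(p.a, p.b) for p in out if p.cls == "one_to_one"}
        orth = {(p.a, p.b) for p in out
                if p.cls in ("ortholog", "one_to_one")}
        assert o2o <= orth


# ---------------------------------------------------------------------------
# graph building

def test_empty_and_triangle_graphs():
    assert build_graph([]).number_of_edges() == 0
    pairs = [PairClass(("g1", "p"), ("g2", "p"), "one_to_one"),
             PairClass(("g1", "p"), ("g3", "p"), "one_to_one"),
             PairClass(("g2", "p"), ("g3", "p"), "one_to_one")]
    g = build_graph(pairs)
    assert g.number_of_edges() == 3
    assert g.number_of_nodes() == 3


def test_class_filter_excludes_weaker_pairs():
    pairs = [PairClass(("g1", "p"), ("g2", "p"), "best_hit"),
             PairClass(("g1", "q"), ("g2", "q"), "ortholog")]
    assert build_graph(pairs, "one_to_one").number_of_edges() == 0
    assert build_graph(pairs, "ortholog").number_of_edges() == 1


def test_pairs_tsv_round_trip(tmp_path):
    pairs = [PairClass(("g1", "p"), ("g2", "q"), "ortholog"),
             PairClass(("g1", "x"), ("g3", "y"), "best_hit")]
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(pairs, path)
    assert read_pairs_tsv(path) == pairs


# ---------------------------------------------------------------------------
# simulator truth

def test_recovered_one_to_one_pairs_equal_simulated_truth():
    """On simulated proteomes without paralogs and modest divergence, the
    one-to-one pairs across genomes are exactly the true ortholog map."""
    params = EvolParams(n_taxa=6, seed=11, core_length=120,
                        id_length_mean=150.0, id_length_sd=5.0,
                        n_decoys=2, decoy_length=90,
                        motif_specs=[MotifSpec("m1", "WQHKCMFDYW")])
    _, proteomes, bundle = simulate_dataset(params)
    recs = {g: [ProteinRecord(g, p, s) for p, s in prots]
            for g, prots in proteomes.items()}
    aligner = make_aligner()
    genomes = sorted(recs)
    within = {g: within_genome_scores(recs[g], aligner) for g in genomes}
    found = set()
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            scores = score_table(recs[ga], recs[gb], aligner=aligner)
            hab = best_hits(recs[ga], recs[gb], scores=scores)
            hba = best_hits(recs[gb], recs[ga], scores=scores)
            for p in classify_pairs(hab, hba, within[ga], within[gb],
                                    ga, gb, cross_scores=scores):
                if p.cls == "one_to_one":
                    found.add(frozenset((p.a, p.b)))
    assert found == bundle.ortholog_pairs()
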