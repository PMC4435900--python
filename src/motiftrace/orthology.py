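"""All-vs-all protein scoring and best-hit / ortholog / one-to-one classification.

Pairs of proteomes are compared with exact Smith–Waterman local alignment
(BLOSUM62, affine gaps — BLAST's default scoring without its heuristics),
then classified with the classical reciprocal-best-hit rules: if *a* from
genome A and *b* from genome B are each other's best hits they are
orthologs; they are one-to-one orthologs when additionally neither genome
contains a paralog scoring higher against its own family member than *a*
scores against *b*.  The one-to-one pairs form the unweighted, undirected
graph handed to the Markov clustering step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord", "PairClass", "read_proteome_fasta", "make_aligner",
    "local_align_score", "score_table", "best_hits", "within_genome_scores",
    "classify_pairs", "build_graph",
]

PairClassName = Literal["best_hit", "ortholog", "one_to_one"]
_CLASS_RANK = {"best_hit": 0, "ortholog": 1, "one_to_one": 2}


@dataclass(frozen=True)
class ProteinRecord:
    genome: str
    protein: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.genome}|{self.protein}: empty sequence")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome, self.protein)


@dataclass(frozen=True)
class PairClass:
    a: tuple[str, str]
    b: tuple[str, str]
    cls: PairClassName


def read_proteome_fasta(path: str | Path, genome: str | None = None
                        ) -> list[ProteinRecord]:
    """Read one genome's proteins from FASTA.  Headers of the form
    ``genomeID|proteinID`` are split; otherwise ``genome`` must be given."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "|" in name:
            g, p = name.split("|", 1)
        elif genome is not None:
            g, p = genome, name
        else:
            raise ValueError(f"header {name!r} lacks 'genome|protein' form "
                             "and no genome id was supplied")
        records.append(ProteinRecord(g, p, str(rec.seq).upper()))
    return records


# ---------------------------------------------------------------------------
# scoring

def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11,
                 gap_extend: float = 1) -> Align.PairwiseAligner:
    """Local affine-gap aligner; a gap of length k costs gap_open +
    k * gap_extend (BLAST convention)."""
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be > 0")
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return aligner


def local_align_score(seq1: str, seq2: str, matrix: str = "BLOSUM62",
                      gap_open: float = 11, gap_extend: float = 1,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Smith–Waterman local alignment score (never negative; the empty
    alignment scores 0).  Unknown residues are scored via the matrix's X
    column."""
    if not seq1 or not seq2:
        raise ValueError("sequences must be nonempty")
    if aligner is None:
        aligner = make_aligner(matrix, gap_open, gap_extend)
    alpha = set(str(aligner.substitution_matrix.alphabet))
    s1 = "".join(c if c in alpha else "X" for c in seq1.upper())
    s2 = "".join(c if c in alpha else "X" for c in seq2.upper())
    return max(0.0, float(aligner.score(s1, s2)))


def score_table(proteomeA: Sequence[ProteinRecord],
                proteomeB: Sequence[ProteinRecord],
                aligner: Align.PairwiseAligner | None = None) -> pd.DataFrame:
    """All-vs-all scores between two proteomes (or within one, passing the
    same list twice; self-pairs are then skipped).  Columns: query, subject,
    score.  Scores are symmetric so each unordered pair is aligned once."""
    if aligner is None:
        aligner = make_aligner()
    same = proteomeA is proteomeB or (
        len(proteomeA) == len(proteomeB)
        and all(x.key == y.key for x, y in zip(proteomeA, proteomeB)))
    rows = []
    for i, ra in enumerate(proteomeA):
        start = i + 1 if same else 0
        for rb in proteomeB[start:]:
            s = local_align_score(ra.sequence, rb.sequence, aligner=aligner)
            rows.append((ra.protein, rb.protein, s))
            rows.append((rb.protein, ra.protein, s))
    return pd.DataFrame(rows, columns=["query", "subject", "score"])


def best_hits(proteomeA: Sequence[ProteinRecord],
              proteomeB: Sequence[ProteinRecord],
              score_floor: float = 0.0,
              aligner: Align.PairwiseAligner | None = None,
              scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Best hit in B for every protein of A (hit table, one direction).

    Ties are broken lexicographically by subject protein id; hits scoring
    below ``score_floor`` are dropped.  ``scores`` may supply a precomputed
    query/subject/score table to avoid re-alignment.
    """
    genomes_a = {r.genome for r in proteomeA}
    genomes_b = {r.genome for r in proteomeB}
    if genomes_a & genomes_b:
        raise ValueError("proteomes must come from distinct genomes")
    if not proteomeA or not proteomeB:
        warnings.warn("empty proteome: returning empty hit table")
        return pd.DataFrame(columns=["query", "subject", "score"])
    if scores is None:
        scores = score_table(proteomeA, proteomeB, aligner=aligner)
    a_ids = {r.protein for r in proteomeA}
    sub = scores[scores["query"].isin(a_ids) & (scores["score"] >= score_floor)]
    sub = sub.sort_values(["query", "score", "subject"],
                          ascending=[True, False, True], kind="mergesort")
    best = sub.groupby("query", as_index=False).first()
    return best[["query", "subject", "score"]].reset_index(drop=True)


def within_genome_scores(proteome: Sequence[ProteinRecord],
                         aligner: Align.PairwiseAligner | None = None
                         ) -> pd.DataFrame:
    """Scores between distinct proteins of one genome (self-hits excluded)."""
    if len(proteome) < 2:
        return pd.DataFrame(columns=["query", "subject", "score"])
    return score_table(proteome, proteome, aligner=aligner)


def classify_pairs(hitsAB: pd.DataFrame, hitsBA: pd.DataFrame,
                   withinA: pd.DataFrame, withinB: pd.DataFrame,
                   genomeA: str, genomeB: str,
                   cross_scores: pd.DataFrame | None = None
                   ) -> list[PairClass]:
    """Classify protein pairs of genomes A and B.

    * (a, b) reciprocal best hits -> ``ortholog``.
    * additionally ``one_to_one`` iff no within-genome paralog of a (resp. b)
      scores strictly higher than score(a, b).
    * a's best hit b without reciprocity -> ``best_hit`` (and symmetrically).
    """
    bestAB = dict(zip(hitsAB["query"], hitsAB["subject"]))
    bestBA = dict(zip(hitsBA["query"], hitsBA["subject"]))
    scoreAB = dict(zip(zip(hitsAB["query"], hitsAB["subject"]),
                       hitsAB["score"]))
    if cross_scores is not None:
        scoreAB.update(dict(zip(zip(cross_scores["query"],
                                    cross_scores["subject"]),
                                cross_scores["score"])))

    def max_paralog(within: pd.DataFrame, prot: str) -> float:
        if within.empty:
            return float("-inf")
        sub = within[within["query"] == prot]
        return float(sub["score"].max()) if len(sub) else float("-inf")

    out: list[PairClass] = []
    seen: set[tuple[str, str]] = set()
    for a, b in bestAB.items():
        if bestBA.get(b) == a:
            s_ab = scoreAB.get((a, b))
            if s_ab is None:
                raise ValueError(f"missing score for reciprocal pair {a}, {b}")
            cls: PairClassName = "ortholog"
            if (max_paralog(withinA, a) <= s_ab
                    and max_paralog(withinB, b) <= s_ab):
                cls = "one_to_one"
            out.append(PairClass((genomeA, a), (genomeB, b), cls))
            seen.add((a, b))
    for a, b in bestAB.items():
        if (a, b) not in seen:
            out.append(PairClass((genomeA, a), (genomeB, b), "best_hit"))
    for b, a in bestBA.items():
        if (a, b) not in seen and bestAB.get(a) != b:
            out.append(PairClass((genomeA, a), (genomeB, b), "best_hit"))
    out.sort(key=lambda p: (p.a, p.b))
    return out


def build_graph(pairs: Iterable[PairClass],
                class_filter: PairClassName = "one_to_one") -> nx.Graph:
    """Unweighted undirected graph over proteins; edge iff the pair's class
    is at least ``class_filter`` in the best_hit < ortholog < one_to_one
    order."""
    if class_filter not in _CLASS_RANK:
        raise ValueError(f"unknown class filter {class_filter!r}")
    g = nx.Graph()
    rank = _CLASS_RANK[class_filter]
    for p in pairs:
        g.add_node(p.a)
        g.add_node(p.b)
        if _CLASS_RANK[p.cls] >= rank:
            g.add_edge(p.a, p.b)
    return g


# ---------------------------------------------------------------------------
# TSV round-trip

def write_pairs_tsv(pairs: Iterable[PairClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tprotein_a\tgenome_b\tprotein_b\tclass\n")
        for p in pairs:
            fh.write(f"{p.a[0]}\t{p.a[1]}\t{p.b[0]}\t{p.b[1]}\t{p.cls}\n")


def read_pairs_tsv(path: str | Path) -> list[PairClass]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"class": "cls"})
    return [PairClass((r.genome_a, r.protein_a), (r.genome_b, r.protein_b),
                      r.cls) for r in df.itertuples(index=False)]
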