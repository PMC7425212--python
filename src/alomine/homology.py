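"""All-vs-all protein similarity search and single-linkage family clustering.

Alignment is exact Smith-Waterman (BLOSUM62, BLAST-style affine gaps: a gap
of length k costs gap_open + k * gap_extend) via Biopython's PairwiseAligner;
significance uses the Karlin-Altschul formula E = K * m * n * exp(-lambda*S)
with the published gapped BLOSUM62 11/1 constants K = 0.041, lambda = 0.267.
Input sets here are small (post TPR-filter), so exact O(mn) alignment is
affordable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

KA_K = 0.041
KA_LAMBDA = 0.267


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    identity_frac: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@dataclass
class FamilyCluster:
    """A single-linkage connected component of the homology graph."""

    family_id: str
    member_ids: tuple[str, ...]
    representative_id: str


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # PairwiseAligner charges open on the first gap position and extend on the
    # rest; BLAST charges open + k*extend for a length-k gap.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate(seq: str, alphabet: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"invalid residue(s) for alignment: {sorted(bad)}")


def evalue(S: float, m: int, n: int, K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expected number of local alignments scoring >= S."""
    if S < 0:
        raise ValueError("score must be >= 0")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * m * n * math.exp(-lam * S)


def bitscore(S: float, K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    return (lam * S - math.log(K)) / math.log(2)


def align_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "a",
    subject_id: str = "b",
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Score is symmetric in the inputs. When no positive-scoring local
    alignment exists the score is 0 with empty spans and identity 0.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _validate(a, alphabet)
    _validate(b, alphabet)
    score = float(aligner.score(a, b))
    if score <= 0:
        return AlignmentHit(
            query_id, subject_id, 0.0, bitscore(0.0), evalue(0.0, len(a), len(b)),
            0.0, (0, 0), (0, 0),
        )
    aln = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    qspan = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    sspan = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    matches = sum(
        1
        for (qa, qb), (sa, sb) in zip(blocks_a, blocks_b)
        for i in range(qb - qa)
        if a[qa + i] == b[sa + i]
    )
    # identity over aligned columns, gap columns included
    n_cols = (qspan[1] - qspan[0]) + (sspan[1] - sspan[0]) - sum(
        (qb - qa) for (qa, qb) in blocks_a
    )
    ident = matches / n_cols if n_cols else 0.0
    return AlignmentHit(
        query_id,
        subject_id,
        score,
        bitscore(score),
        evalue(score, len(a), len(b)),
        ident,
        qspan,
        sspan,
    )


def all_vs_all(
    proteins: dict[str, str],
    evalue_max: float = 1e-5,
    min_subject_aa: int | None = None,
    contig_of: dict[str, str] | None = None,
    contig_lengths: dict[str, int] | None = None,
    min_scaffold_nt: int | None = None,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[AlignmentHit]:
    """Directed significant hits between every pair of proteins.

    Self-hits are excluded. A directed hit is dropped when its subject is
    shorter than ``min_subject_aa`` or (when contig info is supplied) lies on
    a scaffold shorter than ``min_scaffold_nt``. Scores are computed once per
    unordered pair and emitted in both directions.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")

    def subject_ok(pid: str) -> bool:
        if min_subject_aa is not None and len(proteins[pid]) < min_subject_aa:
            return False
        if (
            min_scaffold_nt is not None
            and contig_of is not None
            and contig_lengths is not None
        ):
            clen = contig_lengths.get(contig_of.get(pid, ""), None)
            if clen is not None and clen < min_scaffold_nt:
                return False
        return True

    hits: list[AlignmentHit] = []
    ids = sorted(proteins)
    for qid, sid in itertools.combinations(ids, 2):
        hit = align_local(
            proteins[qid], proteins[sid], matrix, gap_open, gap_extend, qid, sid
        )
        if hit.evalue > evalue_max:
            continue
        if subject_ok(sid):
            hits.append(hit)
        if subject_ok(qid):
            hits.append(
                AlignmentHit(
                    sid, qid, hit.raw_score, hit.bitscore, hit.evalue,
                    hit.identity_frac, hit.subject_span, hit.query_span,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def cluster(hits: list[AlignmentHit], proteins: dict[str, str]) -> list[FamilyCluster]:
    """Single-linkage families: connected components of the passing-hit graph.

    Every protein is a node, so proteins without hits become singletons.
    The representative is the longest member (ties broken by lexicographic
    id); family ids are assigned in sorted-representative order.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    for h in hits:
        if h.query_id in proteins and h.subject_id in proteins:
            g.add_edge(h.query_id, h.subject_id)
    comps = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda m: (-len(proteins[m]), m))
        comps.append((rep, members))
    comps.sort(key=lambda c: c[0])
    return [
        FamilyCluster(family_id=f"F{i:03d}", member_ids=members, representative_id=rep)
        for i, (rep, members) in enumerate(comps, start=1)
    ]


def hits_to_rows(hits: list[AlignmentHit]) -> list[dict]:
    return [
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "score": h.raw_score,
            "bitscore": f"{h.bitscore:.2f}",
            "evalue": f"{h.evalue:.3e}",
            "identity": f"{h.identity_frac:.3f}",
        }
        for h in hits
    ]
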