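"""Protein local alignment and similarity statistics.

Smith-Waterman with affine gaps on BLOSUM62 (gap cost ``11 1``: a gap of
length L costs 11 + L, i.e. the first gapped position pays open+extend).
E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the
published gapped-BLOSUM62 constants as defaults.  ``X`` scores 0 against
every letter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "local_align",
    "evalue",
    "best_hit",
]

#: (lambda, K) calibration for gapped scoring schemes, keyed by
#: (matrix_name, gap_open, gap_extend).  Overridable via ScoringScheme.
GAPPED_CALIBRATION: Dict[Tuple[str, int, int], Tuple[float, float]] = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
}


def _patched_blosum62():
    m = substitution_matrices.load("BLOSUM62")
    # X is an unknown residue: score 0 vs everything
    arr = m.copy()
    if "X" in arr.alphabet:
        xi = arr.alphabet.index("X")
        for j in range(len(arr.alphabet)):
            arr[xi, j] = 0.0
            arr[j, xi] = 0.0
    return arr


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs (defaults: BLOSUM62, 11/1)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    matrix: object = None
    lam: Optional[float] = None
    k: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.matrix is None:
            if self.matrix_name == "BLOSUM62":
                self.matrix = _patched_blosum62()
            else:
                self.matrix = substitution_matrices.load(self.matrix_name)
        if self.lam is None or self.k is None:
            lam, k = GAPPED_CALIBRATION.get(
                (self.matrix_name, self.gap_open, self.gap_extend), (0.267, 0.041)
            )
            self.lam = self.lam if self.lam is not None else lam
            self.k = self.k if self.k is not None else k

    @classmethod
    def from_matrix_file(cls, path: str, gap_open: int = 11, gap_extend: int = 1):
        """Load a substitution matrix in NCBI text format."""
        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        return cls(matrix_name=path, gap_open=gap_open, gap_extend=gap_extend, matrix=mat)

    def score_pair(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = self.matrix
        # first gap position costs open+extend under the "11 1" convention
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aln_len: int
    identity_pct: float
    similarity_pct: float
    evalue: float
    query_cov: float
    subject_cov: float

    def __post_init__(self):
        assert 0 <= self.identity_pct <= self.similarity_pct <= 100 + 1e-9


def _column_stats(alignment, a: str, b: str, scheme: ScoringScheme):
    """Identity/similarity over the aligned columns of a local alignment."""
    n_id = n_sim = n_cols = 0
    qa, qb = alignment.aligned  # blocks: [(qstart,qend)], [(sstart,send)]
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qa, qb):
        if prev_q is not None:
            # internal gap columns
            n_cols += (qs - prev_q) + (ss - prev_s)
        for i in range(qe - qs):
            x, y = a[qs + i], b[ss + i]
            n_cols += 1
            if x == y and x != "X":
                n_id += 1
                n_sim += 1
            elif scheme.score_pair(x, y) > 0:
                n_sim += 1
        prev_q, prev_s = qe, se
    return n_id, n_sim, n_cols


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    db_len: Optional[int] = None,
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment of two proteins.

    ``db_len`` sets the search-space n for the E-value (defaults to len(b),
    a single-sequence database).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = scheme.aligner()
    score = float(aligner.score(a, b))
    if score <= 0:
        return AlignmentResult(
            score=0.0,
            aln_len=0,
            identity_pct=0.0,
            similarity_pct=0.0,
            evalue=evalue(0.0, len(a), db_len or len(b), scheme),
            query_cov=0.0,
            subject_cov=0.0,
        )
    aln = next(iter(aligner.align(a, b)))
    n_id, n_sim, n_cols = _column_stats(aln, a, b, scheme)
    qa, qb = aln.aligned
    qspan = qa[-1][1] - qa[0][0]
    sspan = qb[-1][1] - qb[0][0]
    return AlignmentResult(
        score=score,
        aln_len=n_cols,
        identity_pct=100.0 * n_id / n_cols if n_cols else 0.0,
        similarity_pct=100.0 * n_sim / n_cols if n_cols else 0.0,
        evalue=evalue(score, len(a), db_len or len(b), scheme),
        query_cov=100.0 * qspan / len(a),
        subject_cov=100.0 * sspan / len(b),
    )


def align_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score-only Smith-Waterman (no traceback; cheaper for screening)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return float(scheme.aligner().score(a, b))


def evalue(
    score: float, query_len: int, db_len: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Karlin-Altschul expect value E = K*m*n*exp(-lambda*S)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return scheme.k * query_len * db_len * math.exp(-scheme.lam * score)


def best_hit(
    query: str,
    db: Sequence[Tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_evalue: float = 1e-1,
) -> Optional[Tuple[str, AlignmentResult]]:
    """Highest-scoring database hit with E <= max_evalue, or None.

    The E-value search space is the whole database (n = total residues).
    Ties are broken by lower E-value, then lexicographic id.
    """
    total = sum(len(s) for _, s in db)
    best: Optional[Tuple[str, AlignmentResult]] = None
    for sid, seq in sorted(db, key=lambda t: t[0]):
        sc = align_score(query, seq, scheme)
        ev = evalue(sc, len(query), total, scheme)
        if ev > max_evalue:
            continue
        if best is None or sc > best[1].score or (
            sc == best[1].score and ev < best[1].evalue
        ):
            res = local_align(query, seq, scheme, db_len=total)
            best = (sid, res)
    return best
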