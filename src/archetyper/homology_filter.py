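"""Homology gating of VWA domains against a reference VWA.

Candidate VWA regions enter the family analysis only if they align to
the reference VWA (the PfuPif VWA in the original study) with an
e-value below a threshold, 1e-10 by default.  Alignment is
Smith–Waterman with affine gaps on BLOSUM62 (gap open 11, extend 1 —
the BLASTP defaults); significance follows Karlin–Altschul statistics
E = K·m·n·exp(-λS), with λ and K either taken as the published ungapped
BLOSUM62 constants or fitted to a Gumbel from scores against shuffled
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# Published Karlin–Altschul parameters for ungapped BLOSUM62 statistics.
CANONICAL_LAMBDA = 0.3176
CANONICAL_K = 0.134

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_THRESHOLD = 1e-10


def _blosum62_x0():
    """BLOSUM62 with the 'X' row/column forced to zero."""
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    xi = m.alphabet.index("X")
    for j in range(len(m.alphabet)):
        arr[xi, j] = 0.0
        arr[j, xi] = 0.0
    return arr


_BLOSUM62_X0 = _blosum62_x0()
_MATRIX_ALPHABET = set(_BLOSUM62_X0.alphabet) - {"*"}


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment summary.

    Spans are 1-based inclusive; an empty alignment (all pair scores
    negative) has ``score`` 0, ``n_columns`` 0 and both spans ``None``.
    ``identity`` is identical pairs over alignment columns (gap columns
    included in the denominator).
    """

    score: float
    query_span: Optional[tuple[int, int]]
    subject_span: Optional[tuple[int, int]]
    n_columns: int
    identity: float

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def _check_residues(seq: str, name: str) -> None:
    bad = set(seq) - _MATRIX_ALPHABET
    if bad:
        raise ValueError(f"{name} contains residues absent from the "
                         f"substitution matrix: {sorted(bad)}")


def _make_aligner(matrix, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Affine model: a gap of length g costs open + (g-1)*extend.
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def local_align(query: str, subject: str, matrix=None,
                gap_open: int = DEFAULT_GAP_OPEN,
                gap_extend: int = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment with affine gaps.

    Returns one optimal alignment; among co-optimal traces the aligner's
    deterministic traversal order decides (only score, spans and
    identity are consumed downstream).  'X' scores 0 against everything.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if not (gap_open >= gap_extend >= 1):
        raise ValueError("need gap_open >= gap_extend >= 1")
    if matrix is None:
        matrix = _BLOSUM62_X0
    _check_residues(query, "query")
    _check_residues(subject, "subject")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return AlignmentResult(score=0.0, query_span=None, subject_span=None,
                               n_columns=0, identity=0.0)
    aln = aligner.align(query, subject)[0]
    qa, sa = aln[0], aln[1]  # aligned strings with gaps
    n_cols = len(qa)
    matches = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    (qblocks, sblocks) = aln.aligned
    qstart = int(qblocks[0][0]) + 1
    qend = int(qblocks[-1][1])
    sstart = int(sblocks[0][0]) + 1
    send = int(sblocks[-1][1])
    return AlignmentResult(score=float(score),
                           query_span=(qstart, qend),
                           subject_span=(sstart, send),
                           n_columns=n_cols,
                           identity=matches / n_cols)


def alignment_score(query: str, subject: str, matrix=None,
                    gap_open: int = DEFAULT_GAP_OPEN,
                    gap_extend: int = DEFAULT_GAP_EXTEND) -> float:
    """Score-only fast path (no traceback)."""
    if matrix is None:
        matrix = _BLOSUM62_X0
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(query, subject)))


@dataclass(frozen=True)
class EvalueModel:
    """Gumbel (Karlin–Altschul) e-value model: E = K·m·n·exp(-λS)."""

    lam: float
    K: float
    calibration: str = "canonical"
    n_shuffles: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @classmethod
    def canonical(cls) -> "EvalueModel":
        """Published ungapped BLOSUM62 constants (λ=0.3176, K=0.134)."""
        return cls(lam=CANONICAL_LAMBDA, K=CANONICAL_K,
                   calibration="canonical")

    @classmethod
    def shuffle_calibrate(cls, query: str, subject: str,
                          n_shuffles: int = 200, seed: int = 0,
                          matrix=None,
                          gap_open: int = DEFAULT_GAP_OPEN,
                          gap_extend: int = DEFAULT_GAP_EXTEND,
                          ) -> "EvalueModel":
        """Fit λ and K to local scores of ``query`` vs shuffled ``subject``.

        Method-of-moments Gumbel fit: λ = π/(σ√6), and K from the mode
        via μ = ln(K·m·n)/λ.  Exact for synthetic alphabets where the
        canonical constants do not apply.
        """
        if n_shuffles < 30:
            raise ValueError("n_shuffles too small for a stable fit")
        rng = np.random.default_rng(seed)
        subj = np.array(list(subject))
        scores = np.empty(n_shuffles)
        for i in range(n_shuffles):
            perm = rng.permutation(len(subj))
            scores[i] = alignment_score(query, "".join(subj[perm]),
                                        matrix=matrix, gap_open=gap_open,
                                        gap_extend=gap_extend)
        sd = float(scores.std(ddof=1))
        if sd == 0:
            raise ValueError("degenerate shuffle scores; cannot calibrate")
        lam = math.pi / (sd * math.sqrt(6.0))
        euler_gamma = 0.57721566490153286
        mu = float(scores.mean()) - euler_gamma / lam
        K = math.exp(lam * mu) / (len(query) * len(subject))
        return cls(lam=lam, K=K, calibration="shuffle",
                   n_shuffles=n_shuffles, seed=seed)


def evalue(score: float, m: int, n: int, model: EvalueModel) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    if model is None:
        raise ValueError("uncalibrated e-value model")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return model.K * m * n * math.exp(-model.lam * score)


def select_candidates(vwa_regions: Sequence[tuple[str, str]],
                      reference_vwa: str,
                      threshold: float = DEFAULT_THRESHOLD,
                      model: Optional[EvalueModel] = None,
                      ) -> tuple[list[tuple[str, str, float]],
                                 list[tuple[str, str, float]]]:
    """Partition (id, sequence) VWA regions by homology to the reference.

    Each region is locally aligned to ``reference_vwa``; it passes iff
    its e-value is below ``threshold`` (default 1e-10).  Returns
    (passed, failed) lists of (id, sequence, evalue), input order
    preserved within each.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if model is None:
        model = EvalueModel.canonical()
    passed, failed = [], []
    for rid, seq in vwa_regions:
        res = local_align(seq, reference_vwa)
        e = evalue(res.score, len(seq), len(reference_vwa), model)
        (passed if e < threshold else failed).append((rid, seq, e))
    return passed, failed
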