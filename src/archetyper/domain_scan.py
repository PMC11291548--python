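"""PSSM scanning, chitin-binding-domain tiers and architecture assembly.

The original survey located domains with profile HMMs against Pfam; here
domain hits either arrive precomputed in a hit table, or are produced by
a self-contained position-specific scoring matrix (PSSM) scanner built
from a seed alignment — sufficient for synthetic profiles, without
Pfam model parsing.

Chitin-binding-like domains are tiered purely by independent e-value:
confident CBM_14 below 1e-5, degenerate CBM_14L1 in [1e-5, 1) and
CBM_14L2 in [1, 1e4) (half-open, lower-inclusive windows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, DomainHit, ProteinRecord

log = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Tier windows on the independent e-value, lower-inclusive.
TIER_CONFIDENT_CEILING = 1e-5
TIER_L1_CEILING = 1.0
TIER_L2_CEILING = 1e4

#: Domain classes treated as chitin-binding for zone geometry.
CB_CLASSES = ("CBM_14", "CBM_14L1", "CBM_14L2")


@dataclass(frozen=True)
class PSSM:
    """Log-odds position-specific scoring matrix (bits).

    ``scores`` is 20 x W in the fixed alphabetical amino-acid order;
    'X' residues score 0 at every column.
    """

    name: str
    scores: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        if self.scores.shape[0] != 20:
            raise ValueError("scores must have 20 rows")
        if self.width < 4:
            raise ValueError("PSSM width must be >= 4")

    @property
    def width(self) -> int:
        return self.scores.shape[1]


def build_pssm(seed_alignment: Sequence[str], background: np.ndarray,
               pseudocount: float = 1.0, name: str = "pssm") -> PSSM:
    """Build a PSSM from a gapless, equal-length seed alignment.

    Per column j and residue a:
    score[a][j] = log2(((count_aj + pc·bg_a) / (N_j + pc)) / bg_a)
    where N_j counts non-'X' residues in the column.  A column of only
    'X' is a hard error.
    """
    if len(seed_alignment) < 2:
        raise ValueError("need at least 2 seed sequences")
    W = len(seed_alignment[0])
    if any(len(s) != W for s in seed_alignment):
        raise ValueError("seed sequences must be equal length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a 20-vector summing to 1")

    counts = np.zeros((20, W))
    for s in seed_alignment:
        for j, a in enumerate(s):
            if a == "X":
                continue
            try:
                counts[_AA_INDEX[a], j] += 1
            except KeyError:
                raise ValueError(f"invalid residue {a!r} in seed alignment")
    n_eff = counts.sum(axis=0)
    if (n_eff == 0).any():
        raise ValueError("seed alignment has a column of only 'X'")
    probs = (counts + pseudocount * background[:, None]) / (n_eff + pseudocount)
    scores = np.log2(probs / background[:, None])
    return PSSM(name=name, scores=scores, background=background,
                pseudocount=pseudocount)


def _window_scores(pssm: PSSM, seq: str) -> np.ndarray:
    """Summed log-odds of every length-W window ('X' contributes 0)."""
    W = pssm.width
    idx = np.array([_AA_INDEX.get(a, -1) for a in seq])
    # Per-position, per-column score lookup; 'X' (-1) scores 0.
    padded = np.vstack([pssm.scores, np.zeros((1, W))])  # row -1 -> zeros
    windows = np.lib.stride_tricks.sliding_window_view(idx, W)
    return padded[windows, np.arange(W)].sum(axis=1)


def scan(pssm: PSSM, protein: ProteinRecord, null_model: str = "shuffle",
         n_null: int = 200, seed: int = 0,
         report_ceiling: float = 1.0) -> list[DomainHit]:
    """Scan a protein with a PSSM, calibrating e-values by shuffling.

    Every length-W window is scored; the null distribution pools window
    scores from ``n_null`` residue shuffles of the protein.  A window's
    e-value is its empirical exceedance probability
    (count_null >= s + 1) / (total_null + 1) scaled by the number of
    windows scanned.  Overlapping windows below ``report_ceiling`` are
    resolved greedily best-score-first; hits come back sorted by start.
    """
    if null_model != "shuffle":
        raise ValueError(f"unknown null model {null_model!r}")
    if n_null < 100:
        raise ValueError("n_null < 100: calibration too coarse")
    W = pssm.width
    if len(protein.seq) < W:
        raise ValueError(f"protein {protein.id!r} shorter than PSSM width")

    obs = _window_scores(pssm, protein.seq)
    n_windows = obs.size

    rng = np.random.default_rng(seed)
    letters = np.array(list(protein.seq))
    null_scores = []
    for _ in range(n_null):
        rng.shuffle(letters)
        null_scores.append(_window_scores(pssm, "".join(letters)))
    null_pool = np.sort(np.concatenate(null_scores))
    total_null = null_pool.size

    # Exceedance counts via binary search on the sorted null pool.
    ge_counts = total_null - np.searchsorted(null_pool, obs, side="left")
    evalues = (ge_counts + 1) / (total_null + 1) * n_windows

    candidates = [(float(obs[i]), int(i), float(evalues[i]))
                  for i in np.nonzero(evalues <= report_ceiling)[0]]
    # Greedy best-score-first overlap resolution.
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for score, i, ev in candidates:
        start, end = i + 1, i + W  # 1-based inclusive
        if any(not (end < s or start > e) for s, e in taken):
            continue
        taken.append((start, end))
        hits.append(DomainHit(protein_id=protein.id, domain_class=pssm.name,
                              start=start, end=end, score=score, ievalue=ev))
    hits.sort(key=lambda h: h.start)
    return hits


def assign_tier(ievalue: float) -> str:
    """Map an independent e-value to a chitin-binding tier label.

    < 1e-5 -> "CBM_14"; [1e-5, 1) -> "CBM_14L1"; [1, 1e4) -> "CBM_14L2";
    >= 1e4 -> "none".  Windows are half-open and lower-inclusive, so the
    labels partition [0, inf) exactly.
    """
    if ievalue < 0:
        raise ValueError("negative e-value")
    if ievalue < TIER_CONFIDENT_CEILING:
        return "CBM_14"
    if ievalue < TIER_L1_CEILING:
        return "CBM_14L1"
    if ievalue < TIER_L2_CEILING:
        return "CBM_14L2"
    return "none"


@dataclass(frozen=True)
class ArchElement:
    """One placed element of an architecture (1-based inclusive span)."""

    cls: str           # domain class, e.g. "VWA", "Sushi"
    tier: Optional[str]  # CB tier label for CB-class elements, else None
    start: int
    end: int
    ievalue: float = float("nan")


@dataclass
class Architecture:
    """Ordered, non-overlapping domain/anchor layout of one protein."""

    protein_id: str
    elements: list[ArchElement]
    signal_span: Optional[tuple[int, int]] = None
    n_anchor_span: Optional[tuple[int, int]] = None
    c_anchor_span: Optional[tuple[int, int]] = None
    lg_status: str = "absent"  # complete | partial | absent

    @property
    def n_vwa(self) -> int:
        return sum(1 for e in self.elements if e.cls == "VWA")

    @property
    def has_cb(self) -> bool:
        return any(e.tier in CB_CLASSES for e in self.elements)

    @property
    def tier_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(e.tier for e in self.elements
                            if e.tier in CB_CLASSES))

    def vwa_elements(self) -> list[ArchElement]:
        return [e for e in self.elements if e.cls == "VWA"]

    def first_cb(self) -> Optional[ArchElement]:
        for e in self.elements:
            if e.tier in CB_CLASSES:
                return e
        return None


def _resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Keep, among overlapping hits, the smallest-ievalue one.

    Ties break toward the longer span, then the smaller start.
    """
    ranked = sorted(hits, key=lambda h: (h.ievalue,
                                         -(h.end - h.start), h.start))
    kept: list[DomainHit] = []
    for h in ranked:
        if any(not (h.end < k.start or h.start > k.end) for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


DEFAULT_MAX_COMPLETE_GAP = 250


def assemble_architecture(protein: ProteinRecord,
                          hits: Sequence[DomainHit],
                          signal_span: Optional[tuple[int, int]] = None,
                          n_anchor_span: Optional[tuple[int, int]] = None,
                          c_anchor_span: Optional[tuple[int, int]] = None,
                          max_complete_gap: int = DEFAULT_MAX_COMPLETE_GAP,
                          ) -> Architecture:
    """Assemble one protein's architecture from its domain hits.

    CB-class hits (class "CBM_14" at any confidence) are tiered by
    independent e-value; hits tiering to "none" are dropped.  Overlaps
    are resolved best-ievalue-first.  LG status is *complete* when both
    anchors are present and either a Laminin_G_3 hit lies between them
    or the inter-anchor gap is at most ``max_complete_gap`` residues;
    *partial* with at least one anchor; *absent* otherwise.
    """
    for h in hits:
        if h.protein_id != protein.id:
            raise ValueError(f"hit for {h.protein_id!r} passed with protein "
                             f"{protein.id!r}")
        if h.end > len(protein.seq):
            raise ValueError(f"hit span {h.span} exceeds protein "
                             f"{protein.id!r} length {len(protein.seq)}")

    usable = []
    for h in hits:
        if h.domain_class == "CBM_14":
            tier = assign_tier(h.ievalue)
            if tier == "none":
                continue
        usable.append(h)
    kept = _resolve_overlaps(usable)

    elements = []
    for h in kept:
        tier = assign_tier(h.ievalue) if h.domain_class == "CBM_14" else None
        elements.append(ArchElement(cls=h.domain_class, tier=tier,
                                    start=h.start, end=h.end,
                                    ievalue=h.ievalue))

    if signal_span is not None:
        for e in elements:
            if not (signal_span[1] < e.start or signal_span[0] > e.end):
                log.warning("signal peptide of %s overlaps a %s domain; "
                            "signal kept", protein.id, e.cls)
                break

    n_found = n_anchor_span is not None
    c_found = c_anchor_span is not None
    if n_found and c_found:
        middle = any(e.cls == "Laminin_G_3"
                     and e.start > n_anchor_span[1]
                     and e.end < c_anchor_span[0]
                     for e in elements)
        gap = c_anchor_span[0] - n_anchor_span[1] - 1
        lg_status = "complete" if (middle or gap <= max_complete_gap) \
            else "partial"
    elif n_found or c_found:
        lg_status = "partial"
    else:
        lg_status = "absent"

    return Architecture(protein_id=protein.id, elements=elements,
                        signal_span=signal_span,
                        n_anchor_span=n_anchor_span,
                        c_anchor_span=c_anchor_span,
                        lg_status=lg_status)
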