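"""Partial laminin-G (LG) anchor location and insert extraction.

In most Pif/BMSP proteins the C-terminal LG domain survives only as two
conserved peptides — a 32-residue N-terminal anchor and a 59-residue
C-terminal anchor — flanking an insert of highly variable length and
composition.  This module finds the anchors by local alignment,
classifies LG completeness, and extracts the inter-anchor insert for
composition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .homology_filter import local_align
from .io_formats import ProteinRecord

#: Conserved N-terminal anchor peptide of the partial LG domain.
N_ANCHOR = "AYFNGRAGLKIPRFSGVPYGKSVFIKMKYKED"
#: Conserved C-terminal anchor peptide of the partial LG domain.
C_ANCHOR = "WKTVSLKISNGHIRGRRDDREDKDVLDGDLKTTFSGFQIGQGASNKNFKGYMDEVYIYF"

DEFAULT_MIN_IDENTITY = 0.5
DEFAULT_MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class AnchorSet:
    """The two anchor peptides plus the acceptance identity threshold."""

    n_anchor: str = N_ANCHOR
    c_anchor: str = C_ANCHOR
    min_identity: float = DEFAULT_MIN_IDENTITY

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class InsertRegion:
    """The region strictly between the two LG anchors (may be empty)."""

    protein_id: str
    start: int  # 1-based inclusive; start > end encodes an empty insert
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def locate_anchor(protein: ProteinRecord, anchor: str,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  search_after: int = 0,
                  min_coverage: float = DEFAULT_MIN_COVERAGE,
                  ) -> Optional[tuple[int, int]]:
    """Best local-alignment placement of an anchor peptide, or ``None``.

    The anchor is aligned against the protein suffix after position
    ``search_after`` (0 = whole protein).  The match is accepted iff
    aligned identity >= ``min_identity`` and the alignment covers at
    least ``min_coverage`` of the anchor's columns.  Returns the
    1-based inclusive span of the anchor's full *footprint* on the
    protein: local alignment trims terminal mismatches, so the aligned
    core is extended outward by the unaligned anchor stubs (clamped to
    the sequence) — for substitution-only divergence this restores the
    anchor's true occupancy, which is what delimits the insert.
    """
    if len(anchor) < 10:
        raise ValueError("anchor too short (< 10 residues)")
    suffix = protein.seq[search_after:]
    if len(suffix) == 0:
        return None
    res = local_align(anchor, suffix)
    if res.is_empty:
        return None
    if res.identity < min_identity:
        return None
    if res.n_columns < min_coverage * len(anchor):
        return None
    s, e = res.subject_span
    q_start, q_end = res.query_span
    s = max(1, s - (q_start - 1))
    e = min(len(suffix), e + (len(anchor) - q_end))
    return (s + search_after, e + search_after)


def extract_insert(protein: ProteinRecord, n_span: tuple[int, int],
                   c_span: tuple[int, int]) -> InsertRegion:
    """Residues strictly between the N-anchor end and C-anchor start."""
    if n_span[1] >= c_span[0]:
        raise ValueError(f"anchors out of order or overlapping on "
                         f"{protein.id!r}: N ends {n_span[1]}, "
                         f"C starts {c_span[0]}")
    start = n_span[1] + 1
    end = c_span[0] - 1
    seq = protein.seq[start - 1:end] if end >= start else ""
    return InsertRegion(protein_id=protein.id, start=start, end=end,
                        sequence=seq)


def lg_completeness(n_found: bool, c_found: bool,
                    middle_lg_hit: bool) -> str:
    """LG status: both anchors + a middle LG signal -> complete;
    any anchor -> partial; none -> absent."""
    if n_found and c_found and middle_lg_hit:
        return "complete"
    if n_found or c_found:
        return "partial"
    return "absent"


def locate_anchor_pair(protein: ProteinRecord,
                       anchors: AnchorSet = AnchorSet(),
                       ) -> tuple[Optional[tuple[int, int]],
                                  Optional[tuple[int, int]]]:
    """Find the N-anchor first, then the C-anchor downstream of it.

    If the N-anchor is absent the C-anchor is searched over the whole
    protein.
    """
    n_span = locate_anchor(protein, anchors.n_anchor,
                           min_identity=anchors.min_identity)
    after = n_span[1] if n_span is not None else 0
    c_span = locate_anchor(protein, anchors.c_anchor,
                           min_identity=anchors.min_identity,
                           search_after=after)
    return n_span, c_span
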