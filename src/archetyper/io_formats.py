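"""Readers and writers for the external formats the pipeline touches.

FASTA, a six-column tab-separated domain-hit table (with an optional
strict HMMER ``--domtblout`` reader), Newick trees with dual
"SH-aLRT/UFBoot" internal node labels as emitted by IQ-TREE, and TSV
matrices.  All residue coordinates are 1-based inclusive, the HMMER/Pfam
convention; conversion happens only at I/O boundaries that demand it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letters accepted in input sequences.  'X' marks an unknown
#: residue; it scores zero in alignments and is excluded from
#: composition denominators.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Domain classes the hit-table reader recognizes; anything else maps to
#: "other" with a warning.
KNOWN_DOMAIN_CLASSES = (
    "VWA", "CBM_14", "Laminin_G_3", "Sushi", "Sulfotransfer_1", "other",
)


class FormatError(ValueError):
    """Raised on malformed or invariant-violating input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a unique id, a free-text taxon tag, and its sequence."""

    id: str
    taxon: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"protein id must be a non-empty token: {self.id!r}")
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence for protein {self.id!r}")
        bad = set(self.seq) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein (1-based inclusive span).

    ``relaxed`` marks rows whose independent e-value is at or above the
    confident ceiling; they stay available for CBM_14-like tiering.
    """

    protein_id: str
    domain_class: str
    start: int
    end: int
    score: float
    ievalue: float
    relaxed: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"invalid span {self.start}..{self.end} on {self.protein_id!r}"
            )
        if self.ievalue < 0:
            raise FormatError(f"negative ievalue on {self.protein_id!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SupportTree:
    """A rooted tree whose internal nodes carry (SH-aLRT, UFBoot) supports.

    Wraps a :class:`dendropy.Tree`; each node gains ``alrt`` and
    ``ufboot`` attributes (percent in [0, 100] or ``None``).  ``rooting``
    records how the root was obtained ("as-parsed" or
    "arbitrary-basal" when the Newick had a basal trifurcation).
    """

    tree: dendropy.Tree
    rooting: str = "as-parsed"

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def support_pairs(self) -> list[tuple[Optional[float], Optional[float]]]:
        """(alrt, ufboot) for every internal non-root node, unordered set."""
        out = []
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            out.append((nd.alrt, nd.ufboot))
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id and the
    remainder the taxon tag.  Sequences are uppercased; a single
    terminal ``*`` (stop) is stripped.  Duplicate ids, empty sequences
    and non-amino-acid characters are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        taxon = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if pid in seen:
            raise FormatError(f"duplicate id {pid}")
        seen.add(pid)
        if not seq:
            raise FormatError(f"empty sequence for record {pid!r}")
        if "*" in seq:
            raise FormatError(f"internal stop '*' in record {pid!r}")
        records.append(ProteinRecord(id=pid, taxon=taxon, seq=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id} {rec.taxon}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain-hit tables

_SIMPLE_COLUMNS = ["protein_id", "domain_class", "start", "end", "score",
                   "ievalue"]


def _coerce_hit_row(fields: dict, lineno: int) -> DomainHit:
    try:
        start = int(fields["start"])
        end = int(fields["end"])
        score = float(fields["score"])
        iev = float(fields["ievalue"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"line {lineno}: malformed hit row ({exc})") from exc
    if start > end:
        raise FormatError(f"line {lineno}: start {start} > end {end}")
    cls = str(fields["domain_class"])
    if cls not in KNOWN_DOMAIN_CLASSES:
        log.warning("line %d: unknown domain class %r mapped to 'other'",
                    lineno, cls)
        cls = "other"
    return DomainHit(protein_id=str(fields["protein_id"]), domain_class=cls,
                     start=start, end=end, score=score, ievalue=iev)


def read_domain_hit_table(path: str | Path, evalue_ceiling: float = 1e-5,
                          dialect: str = "simple") -> list[DomainHit]:
    """Read domain hits; rows with ievalue >= ceiling come back ``relaxed``.

    ``dialect="simple"`` expects a 6-column TSV with header
    ``protein_id  domain_class  start  end  score  ievalue``.
    ``dialect="domtblout"`` reads HMMER's per-domain table, mapping
    target name -> protein_id, query name -> domain_class, the alignment
    coordinates (``ali from``/``ali to``) -> start/end and the
    independent e-value column -> ievalue.
    """
    if evalue_ceiling <= 0:
        raise ValueError("evalue_ceiling must be > 0")
    hits: list[DomainHit] = []
    if dialect == "simple":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _SIMPLE_COLUMNS:
                raise FormatError(
                    f"bad header {header!r}; expected {_SIMPLE_COLUMNS!r}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(_SIMPLE_COLUMNS):
                    raise FormatError(
                        f"line {lineno}: expected {len(_SIMPLE_COLUMNS)} "
                        f"columns, got {len(parts)}")
                hits.append(_coerce_hit_row(dict(zip(_SIMPLE_COLUMNS, parts)),
                                            lineno))
    elif dialect == "domtblout":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 22:
                    raise FormatError(
                        f"line {lineno}: domtblout row has {len(parts)} "
                        "columns, expected >= 22")
                fields = {
                    "protein_id": parts[0],
                    "domain_class": parts[3],
                    "ievalue": parts[12],
                    "score": parts[13],
                    "start": parts[17],
                    "end": parts[18],
                }
                hits.append(_coerce_hit_row(fields, lineno))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out = []
    for h in hits:
        if h.ievalue >= evalue_ceiling:
            h = DomainHit(h.protein_id, h.domain_class, h.start, h.end,
                          h.score, h.ievalue, relaxed=True)
        out.append(h)
    return out


def write_domain_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the simple 6-column dialect (``relaxed`` is derived)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SIMPLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_class}\t{h.start}\t{h.end}\t"
                     f"{h.score}\t{h.ievalue}\n")


# ---------------------------------------------------------------------------
# Support trees


def _parse_support_label(label: Optional[str], label_order: str,
                         ) -> tuple[Optional[float], Optional[float]]:
    """Split an internal node label into (alrt, ufboot) percentages."""
    if label is None or label == "":
        return (None, None)
    parts = label.split("/")
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        raise FormatError(f"unparseable support label {label!r}") from exc
    for v in values:
        if not (0.0 <= v <= 100.0):
            raise FormatError(f"support {v} outside [0, 100] in {label!r}")
    if len(values) == 1:
        # IQ-TREE prints a lone value only when a single support measure
        # was requested; conventionally this is the bootstrap.
        return (None, values[0])
    if len(values) != 2:
        raise FormatError(f"support label {label!r} has {len(values)} fields")
    if label_order == "alrt_ufboot":
        return (values[0], values[1])
    if label_order == "ufboot_alrt":
        return (values[1], values[0])
    raise ValueError(f"unknown label_order {label_order!r}")


def parse_support_tree(newick: str, label_order: str = "alrt_ufboot",
                       ) -> SupportTree:
    """Parse a Newick string with dual-support internal labels.

    Internal labels of the form ``x/y`` are split per ``label_order``
    (default matches IQ-TREE's "SH-aLRT/UFBoot" emission order); a lone
    number is taken as UFBoot; a missing label leaves both supports
    missing.  A basal trifurcation (unrooted convention) is kept as the
    root polytomy and flagged via ``rooting="arbitrary-basal"``.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    seen: set[str] = set()
    for lf in tree.leaf_node_iter():
        if lf.taxon is None:
            raise FormatError("leaf without a name")
        if lf.taxon.label in seen:
            raise FormatError(f"duplicate leaf name {lf.taxon.label!r}")
        seen.add(lf.taxon.label)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.alrt, nd.ufboot = None, None
        else:
            nd.alrt, nd.ufboot = _parse_support_label(nd.label, label_order)
    tree.is_rooted = True
    rooting = "as-parsed"
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        # Unrooted newick: treat the basal polytomy as the root and
        # record that this rooting is arbitrary.
        rooting = "arbitrary-basal"
    return SupportTree(tree=tree, rooting=rooting)


def support_tree_to_newick(st: SupportTree) -> str:
    """Serialize with "alrt/ufboot" internal labels (missing -> blank)."""
    for nd in st.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        if nd.alrt is None and nd.ufboot is None:
            nd.label = None
        else:
            a = "" if nd.alrt is None else f"{nd.alrt:g}"
            u = "" if nd.ufboot is None else f"{nd.ufboot:g}"
            nd.label = f"{a}/{u}" if nd.alrt is not None else u
    return st.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# TSV matrices


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled real matrix as TSV (UTF-8, '.' decimal).

    Non-finite entries and duplicate labels are hard errors; a
    write-then-read round trip reproduces values to 1e-9.
    """
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise FormatError("duplicate row or column labels")
    values = matrix.to_numpy(dtype=float)
    if not all(math.isfinite(v) for v in values.ravel()):
        raise FormatError("matrix contains non-finite values")
    matrix.to_csv(path, sep="\t", float_format="%.12g", encoding="utf-8")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_matrix_tsv`."""
    return pd.read_csv(path, sep="\t", index_col=0)
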