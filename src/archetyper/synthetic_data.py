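"""Synthetic Pif/BMSP-like protein families with a planted truth table.

The real study inputs are multi-gigabyte genome and transcriptome
databases; this module generates families whose *statistical structure*
matches what the downstream analysis assumes, so every stage is
testable without downloads:

* proteins concatenated from background linkers and planted elements —
  an optional signal peptide, 1–4 tandem VWA-like domains, optional
  Sushi repeats, 0–3 chitin-binding domains at chosen e-value tiers,
  and the two conserved LG anchor peptides flanking an insert of
  controlled length and composition;
* a domain-hit table whose independent e-values are drawn log-uniformly
  strictly inside the intended tier window (never on a boundary);
* low-complexity tracts planted in the four architecture zones;
* a support-labelled tree with planted subfamily structure and
  outgroup leaves;
* a machine-readable truth table recording every planted span.

Sequences are i.i.d. draws, not simulated evolution: the tree and the
sequences are generated independently, and there is no indel process —
anchor degradation is substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
import dendropy

from .io_formats import (AMINO_ACIDS, DomainHit, ProteinRecord, SupportTree,
                         write_fasta, write_domain_hit_table,
                         support_tree_to_newick)
from .lg_inserts import N_ANCHOR, C_ANCHOR

# Average SwissProt-like background composition (documented constant;
# the exact values are not biology-critical).
_BG_PERCENT = {
    "A": 8.25, "C": 1.38, "D": 5.45, "E": 6.72, "F": 3.86, "G": 7.07,
    "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65, "M": 2.41, "N": 4.06,
    "P": 4.74, "Q": 3.93, "R": 5.53, "S": 6.64, "T": 5.36, "V": 6.85,
    "W": 1.10, "Y": 2.92,
}
BACKGROUND_COMPOSITION = np.array([_BG_PERCENT[a] for a in AMINO_ACIDS])
BACKGROUND_COMPOSITION = BACKGROUND_COMPOSITION / BACKGROUND_COMPOSITION.sum()

# Synthetic stand-ins for the conserved domain cores.  These are fixed
# random draws from the background — synthetic sequences, not Pfam
# consensi — used as mutation templates so that planted copies of the
# same domain are mutually homologous.
REFERENCE_VWA = (
    "VRRHMAGVSLIDSAEELEGMLAIYAYFSVQMIGDQFYPNVMAPPERAKQKEKHGLSMFNCRTFNKDQ"
    "AVAGEYPVAMAETEDEIFPVLEMLLVIRLHRCNYELQQIFSTFEEVLVSEPLEWKIIILSASFDAGF"
    "QVVIFARTPYKGDGKILGDAHNHEFKY"
)
CB_CORE = "TALLRSAINLSHLKALLMGFSATLILQVFISIATELAMRYRYPIFNNLEPAALRA"
SUSHI_CORE = "GMKIHGLTNKLEMIIEENSDEAVNTKKVKNLKGITHHIEGNLGTMQSMSINYVFLREY"


def _profile(**enriched: float) -> np.ndarray:
    """Composition with named residues fixed, the rest background-scaled."""
    p = np.zeros(20)
    for a, v in enriched.items():
        p[AMINO_ACIDS.index(a)] = v
    rest = 1.0 - p.sum()
    free = p == 0
    p[free] = BACKGROUND_COMPOSITION[free] \
        / BACKGROUND_COMPOSITION[free].sum() * rest
    return p


#: Insert composition profiles.  "pinctada_like" mirrors the Asp/Lys/Arg-
#: rich inserts of *Pinctada* pearl-oyster Pifs (D ~25%, K ~18%, R ~12%);
#: "unionida_like" the Ser/Asp-rich inserts of freshwater pearl oysters
#: (S ~25%, D ~22%).
INSERT_PROFILES: dict[str, np.ndarray] = {
    "pinctada_like": _profile(D=0.25, K=0.18, R=0.12, S=0.035),
    "unionida_like": _profile(D=0.22, S=0.255, K=0.08, R=0.03),
    "background": BACKGROUND_COMPOSITION.copy(),
}

# Tier windows for planted independent e-values (log10 bounds), kept
# strictly inside the assignment windows with a margin so no draw lands
# on a boundary.
_TIER_LOG10_WINDOWS = {
    "CBM_14": (-25.0, -5.5),
    "CBM_14L1": (-4.5, -0.2),
    "CBM_14L2": (0.2, 3.5),
}
_CONFIDENT_LOG10 = (-30.0, -6.0)  # VWA / Sushi / Laminin_G_3 hits

# Support ranges per planted class: (ufboot lo, hi), (alrt lo, hi).
_SUPPORT_RANGES = {
    "strong": ((95.0, 100.0), (85.0, 100.0)),
    "medium": ((75.0, 94.0), (65.0, 100.0)),
    "weak": ((0.0, 74.0), (0.0, 64.0)),
}


@dataclass
class ArchitectureTemplate:
    """Blueprint for one subfamily's domain layout.

    ``cb_tiers`` lists the intended tier of each chitin-binding domain
    in N-to-C order; ``lcr_plan`` maps zone name to the number of
    low-complexity tracts planted there.
    """

    name: str
    has_signal: bool = True
    n_vwa: int = 1
    n_sushi: int = 0
    cb_tiers: tuple[str, ...] = ("CBM_14",)
    has_lg: bool = False
    insert_profile: str = "background"
    insert_length_range: tuple[int, int] = (138, 1438)
    lcr_plan: dict[str, int] = field(default_factory=dict)
    support: str = "strong"

    def __post_init__(self) -> None:
        if not (0 <= self.n_vwa <= 4):
            raise ValueError("n_vwa must be in 0..4")
        if len(self.cb_tiers) > 3:
            raise ValueError("at most 3 chitin-binding domains")
        for t in self.cb_tiers:
            if t not in _TIER_LOG10_WINDOWS:
                raise ValueError(f"unknown tier {t!r}")
        if self.insert_profile not in INSERT_PROFILES:
            raise ValueError(f"unknown insert profile "
                             f"{self.insert_profile!r}")
        if self.support not in _SUPPORT_RANGES:
            raise ValueError(f"unknown support class {self.support!r}")
        bad = set(self.lcr_plan) - {"zone1", "zone2", "zone3", "zone4"}
        if bad:
            raise ValueError(f"unknown zones in lcr_plan: {sorted(bad)}")


def default_templates() -> list[ArchitectureTemplate]:
    """Subfamily templates emulating the canonical family architectures.

    BMSP-like: four tandem VWA domains at the N-terminus; Pif-like: one
    VWA plus confident and degenerate CB domains and a D/K/R-rich LG
    insert; PifN-like: a long Ser/Asp-rich insert; PifCCP-like: Sushi
    repeats between the VWA and CB domains.
    """
    return [
        ArchitectureTemplate(
            name="bmsp", n_vwa=4, cb_tiers=("CBM_14",), has_lg=True,
            insert_profile="background", insert_length_range=(138, 400),
            lcr_plan={"zone2": 1, "zone4": 1}, support="strong"),
        ArchitectureTemplate(
            name="pif", n_vwa=1, cb_tiers=("CBM_14", "CBM_14L1"),
            has_lg=True, insert_profile="pinctada_like",
            insert_length_range=(300, 900),
            lcr_plan={"zone3": 1, "zone4": 2}, support="strong"),
        ArchitectureTemplate(
            name="pifn", n_vwa=1, cb_tiers=("CBM_14", "CBM_14L2"),
            has_lg=True, insert_profile="unionida_like",
            insert_length_range=(600, 1438),
            lcr_plan={"zone3": 2, "zone4": 1}, support="strong"),
        ArchitectureTemplate(
            name="pifccp", n_vwa=2, n_sushi=3, cb_tiers=("CBM_14",),
            has_lg=True, insert_profile="background",
            insert_length_range=(138, 240),
            lcr_plan={"zone1": 1}, support="medium"),
    ]


@dataclass
class SyntheticSpec:
    """Complete recipe for one synthetic study.

    Defaults give a four-subfamily family (20 proteins per subfamily),
    exact anchor peptides, planted tier e-values strictly inside their
    windows, and two outgroup leaves.
    """

    n_per_subfamily: int = 20
    templates: list[ArchitectureTemplate] = field(
        default_factory=default_templates)
    seed: int = 42
    background: np.ndarray = field(
        default_factory=lambda: BACKGROUND_COMPOSITION.copy())
    anchor_identity: float = 1.0   # substitution-only degradation
    vwa_identity: float = 0.75     # identity of planted VWAs to REFERENCE_VWA
    lcr_length_range: tuple[int, int] = (22, 40)
    linker_length_range: tuple[int, int] = (25, 70)
    n_outgroup: int = 2
    jitter_spans: int = 0          # +-k residue jitter on hit spans

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        for name, p in INSERT_PROFILES.items():
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile {name!r} does not sum to 1")
        if not (0.7 <= self.anchor_identity <= 1.0):
            raise ValueError("anchor_identity must be in [0.7, 1]")
        if self.n_per_subfamily < 2:
            raise ValueError("need >= 2 proteins per subfamily")

    def protein_ids(self) -> dict[str, list[str]]:
        """Deterministic protein ids per template."""
        return {t.name: [f"{t.name}{i + 1:03d}"
                         for i in range(self.n_per_subfamily)]
                for t in self.templates}


@dataclass
class TruthTable:
    """Planted ground truth: one row per planted feature.

    ``elements`` columns: protein_id, kind (signal/domain/anchor/insert/
    lcr), label (class or anchor side or profile name), tier, start,
    end, zone, subfamily.  ``node_support`` lists the planted class of
    each subfamily ancestor branch.
    """

    elements: pd.DataFrame
    subfamily_of: dict[str, str]
    node_support: dict[str, str] = field(default_factory=dict)
    lg_status_of: dict[str, str] = field(default_factory=dict)

    def rows_for(self, protein_id: str, kind: Optional[str] = None,
                 ) -> pd.DataFrame:
        df = self.elements[self.elements.protein_id == protein_id]
        if kind is not None:
            df = df[df.kind == kind]
        return df


def sample_sequence(composition: np.ndarray, length: int,
                    rng: np.random.Generator | int) -> str:
    """I.i.d. residues drawn from a 20-vector composition."""
    if length <= 0:
        raise ValueError("length must be >= 1")
    composition = np.asarray(composition, dtype=float)
    if abs(composition.sum() - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=composition))


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitution-only degradation to an expected identity level."""
    out = list(seq)
    for i, a in enumerate(out):
        if rng.random() < 1.0 - identity:
            choices = [c for c in AMINO_ACIDS if c != a]
            out[i] = rng.choice(choices)
    return "".join(out)


def _tier_evalue(tier: str, rng: np.random.Generator) -> float:
    lo, hi = _TIER_LOG10_WINDOWS[tier]
    return float(10.0 ** rng.uniform(lo, hi))


def _confident_evalue(rng: np.random.Generator) -> float:
    lo, hi = _CONFIDENT_LOG10
    return float(10.0 ** rng.uniform(lo, hi))


class _Builder:
    """Accumulates sequence blocks and truth rows for one protein."""

    def __init__(self, pid: str, subfamily: str):
        self.pid = pid
        self.subfamily = subfamily
        self.parts: list[str] = []
        self.pos = 0  # residues emitted so far
        self.truth_rows: list[dict] = []
        self.hits: list[DomainHit] = []

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos + 1
        self.parts.append(seq)
        self.pos += len(seq)
        return (start, self.pos)

    def record(self, kind: str, label: str, span: tuple[int, int],
               tier: str = "", zone: str = "") -> None:
        self.truth_rows.append(dict(protein_id=self.pid, kind=kind,
                                    label=label, tier=tier,
                                    start=span[0], end=span[1], zone=zone,
                                    subfamily=self.subfamily))

    def hit(self, cls: str, span: tuple[int, int], ievalue: float,
            score: float, jitter: int, rng: np.random.Generator) -> None:
        s, e = span
        if jitter:
            s = max(1, s + int(rng.integers(-jitter, jitter + 1)))
            e = max(s, e + int(rng.integers(-jitter, jitter + 1)))
        self.hits.append(DomainHit(protein_id=self.pid, domain_class=cls,
                                   start=s, end=e, score=score,
                                   ievalue=ievalue))

    @property
    def seq(self) -> str:
        return "".join(self.parts)


_LCR_DOMINANTS = "DSTKGPQN"


def _linker_with_lcrs(builder: _Builder, spec: SyntheticSpec,
                      rng: np.random.Generator, n_lcrs: int,
                      zone: str) -> None:
    """Emit a background linker with ``n_lcrs`` low-entropy tracts inside.

    Tracts are two-letter biased (dominant residue at 85%), flanked by
    background so they sit strictly inside the linker.
    """
    lo, hi = spec.linker_length_range
    flank = max(lo, 15)
    pieces = [sample_sequence(spec.background, int(rng.integers(lo, hi + 1)),
                              rng)]
    for _ in range(n_lcrs):
        tract_len = int(rng.integers(*spec.lcr_length_range))
        dom = _LCR_DOMINANTS[int(rng.integers(len(_LCR_DOMINANTS)))]
        other = "A" if dom != "A" else "G"
        comp = np.zeros(20)
        comp[AMINO_ACIDS.index(dom)] = 0.85
        comp[AMINO_ACIDS.index(other)] = 0.15
        tract = sample_sequence(comp, tract_len, rng)
        pieces.append(tract)
        pieces.append(sample_sequence(spec.background,
                                      int(rng.integers(flank, hi + 1)), rng))
    # Emit pieces, recording tract spans.
    for i, piece in enumerate(pieces):
        span = builder.add(piece)
        if i % 2 == 1:  # tracts are at odd indices
            builder.record("lcr", "tract", span, zone=zone)


def plant_family(spec: SyntheticSpec,
                 ) -> tuple[list[ProteinRecord], list[DomainHit], TruthTable]:
    """Generate the protein family, its hit table and the truth table."""
    rng = np.random.default_rng([spec.seed, 101])
    proteins: list[ProteinRecord] = []
    all_hits: list[DomainHit] = []
    all_rows: list[dict] = []
    subfamily_of: dict[str, str] = {}
    lg_status_of: dict[str, str] = {}
    ids = spec.protein_ids()

    for tmpl in spec.templates:
        for pid in ids[tmpl.name]:
            b = _Builder(pid, tmpl.name)
            subfamily_of[pid] = tmpl.name

            if tmpl.has_signal:
                span = b.add(sample_sequence(spec.background, 18, rng))
                b.record("signal", "SP", span)

            _linker_with_lcrs(b, spec, rng,
                              tmpl.lcr_plan.get("zone1", 0), "zone1")

            # Tandem VWA domains with zone-2 linkers between them.
            n_z2_lcrs = tmpl.lcr_plan.get("zone2", 0)
            for i in range(tmpl.n_vwa):
                vwa = _mutate(REFERENCE_VWA, spec.vwa_identity, rng)
                span = b.add(vwa)
                b.record("domain", "VWA", span)
                b.hit("VWA", span, _confident_evalue(rng), 80.0,
                      spec.jitter_spans, rng)
                if i < tmpl.n_vwa - 1:
                    take = 1 if n_z2_lcrs > 0 else 0
                    n_z2_lcrs -= take
                    _linker_with_lcrs(b, spec, rng, take, "zone2")

            # Zone 3: between the last VWA and the first CB domain,
            # optionally interrupted by Sushi repeats.
            _linker_with_lcrs(b, spec, rng,
                              tmpl.lcr_plan.get("zone3", 0), "zone3")
            for _ in range(tmpl.n_sushi):
                sushi = _mutate(SUSHI_CORE, 0.8, rng)
                span = b.add(sushi)
                b.record("domain", "Sushi", span)
                b.hit("Sushi", span, _confident_evalue(rng), 40.0,
                      spec.jitter_spans, rng)
                b.add(sample_sequence(spec.background, 8, rng))

            for tier in tmpl.cb_tiers:
                cb = _mutate(CB_CORE, 0.8, rng)
                span = b.add(cb)
                b.record("domain", "CBM_14", span, tier=tier)
                b.hit("CBM_14", span, _tier_evalue(tier, rng), 30.0,
                      spec.jitter_spans, rng)
                b.add(sample_sequence(spec.background, 10, rng))

            # Partial LG domain: anchors flanking the insert.
            if tmpl.has_lg:
                b.add(sample_sequence(spec.background, 12, rng))
                n_seq = _mutate(N_ANCHOR, spec.anchor_identity, rng)
                span_n = b.add(n_seq)
                b.record("anchor", "N", span_n)

                ins_len = int(rng.integers(*tmpl.insert_length_range))
                profile = INSERT_PROFILES[tmpl.insert_profile].copy()
                n_z4 = tmpl.lcr_plan.get("zone4", 0)
                ins_parts: list[tuple[str, bool]] = []
                remaining = ins_len
                for _ in range(n_z4):
                    tract_len = int(rng.integers(*spec.lcr_length_range))
                    dom = _LCR_DOMINANTS[int(rng.integers(
                        len(_LCR_DOMINANTS)))]
                    comp = np.zeros(20)
                    comp[AMINO_ACIDS.index(dom)] = 0.85
                    comp[AMINO_ACIDS.index("A" if dom != "A" else "G")] = 0.15
                    seg_len = max(20, (remaining - tract_len) // (n_z4 + 1))
                    ins_parts.append((sample_sequence(profile, seg_len, rng),
                                      False))
                    ins_parts.append((sample_sequence(comp, tract_len, rng),
                                      True))
                    remaining -= seg_len + tract_len
                ins_parts.append((sample_sequence(profile, max(remaining, 20),
                                                  rng), False))

                ins_start = b.pos + 1
                for piece, is_tract in ins_parts:
                    span = b.add(piece)
                    if is_tract:
                        b.record("lcr", "tract", span, zone="zone4")
                ins_end = b.pos
                b.record("insert", tmpl.insert_profile,
                         (ins_start, ins_end))

                c_seq = _mutate(C_ANCHOR, spec.anchor_identity, rng)
                span_c = b.add(c_seq)
                b.record("anchor", "C", span_c)
                gap = span_c[0] - span_n[1] - 1
                lg_status_of[pid] = "complete" if gap <= 250 else "partial"
            else:
                lg_status_of[pid] = "absent"

            b.add(sample_sequence(spec.background, 15, rng))  # C-tail

            proteins.append(ProteinRecord(id=pid, taxon=tmpl.name,
                                          seq=b.seq))
            all_hits.extend(b.hits)
            all_rows.extend(b.truth_rows)

    elements = pd.DataFrame(all_rows, columns=["protein_id", "kind", "label",
                                               "tier", "start", "end",
                                               "zone", "subfamily"])
    truth = TruthTable(elements=elements, subfamily_of=subfamily_of,
                       lg_status_of=lg_status_of)
    _check_truth(proteins, truth)
    return proteins, all_hits, truth


def _check_truth(proteins: Sequence[ProteinRecord], truth: TruthTable) -> None:
    """Invariant: every planted span lies within its protein."""
    lengths = {p.id: len(p.seq) for p in proteins}
    for row in truth.elements.itertuples():
        if not (1 <= row.start <= row.end <= lengths[row.protein_id]):
            raise AssertionError(
                f"planted span {row.start}..{row.end} outside "
                f"{row.protein_id}")


def plant_support_tree(spec: SyntheticSpec,
                       ) -> tuple[SupportTree, TruthTable]:
    """Build a support-labelled tree with planted subfamily structure.

    Each subfamily is a caterpillar clade whose ancestor branch gets a
    support pair drawn from its planted class's range; spine branches
    joining subfamilies are weak so the subfamilies are the maximal
    supported clades; the family ancestor branch is strong; outgroup
    leaves attach outside the family clade; the root carries no support.
    """
    rng = np.random.default_rng([spec.seed, 202])
    ids = spec.protein_ids()
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def support_in(cls: str) -> tuple[float, float]:
        (ulo, uhi), (alo, ahi) = _SUPPORT_RANGES[cls]
        return (round(float(rng.uniform(alo, ahi)), 1),
                round(float(rng.uniform(ulo, uhi)), 1))

    def bl() -> float:
        return round(float(rng.uniform(0.02, 0.3)), 4)

    def leaf(name: str) -> dendropy.Node:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(name)
        nd.edge.length = bl()
        nd.alrt, nd.ufboot = None, None
        return nd

    def caterpillar(names: list[str], internal_cls: str = "any",
                    ) -> dendropy.Node:
        node = leaf(names[0])
        for nm in names[1:]:
            parent = dendropy.Node()
            parent.edge.length = bl()
            # Internal joins inside a subfamily may have any support;
            # they are absorbed by the top-down partition.
            parent.alrt, parent.ufboot = support_in("weak") \
                if internal_cls == "weak" else (
                    round(float(rng.uniform(0, 100)), 1),
                    round(float(rng.uniform(0, 100)), 1))
            parent.add_child(node)
            parent.add_child(leaf(nm))
            node = parent
        return node

    node_support: dict[str, str] = {}
    sub_nodes = []
    for tmpl in spec.templates:
        nd = caterpillar(ids[tmpl.name])
        nd.alrt, nd.ufboot = support_in(tmpl.support)
        node_support[tmpl.name] = tmpl.support
        sub_nodes.append(nd)

    # Spine joining subfamilies: weak supports so no supported clade
    # larger than a subfamily exists strictly inside the family.
    family = sub_nodes[0]
    for nd in sub_nodes[1:]:
        parent = dendropy.Node()
        parent.edge.length = bl()
        parent.alrt, parent.ufboot = support_in("weak")
        parent.add_child(family)
        parent.add_child(nd)
        family = parent
    family.alrt, family.ufboot = support_in("strong")
    node_support["family"] = "strong"

    og_names = [f"og{i + 1}" for i in range(spec.n_outgroup)]
    if og_names:
        og = caterpillar(og_names) if len(og_names) > 1 else leaf(og_names[0])
        if not og.is_leaf():
            og.alrt, og.ufboot = support_in("weak")
        root = dendropy.Node()
        root.alrt, root.ufboot = None, None
        root.add_child(og)
        root.add_child(family)
        tree.seed_node = root
    else:
        tree.seed_node = family

    tree.taxon_namespace = taxa
    tree.is_rooted = True
    st = SupportTree(tree=tree, rooting="as-parsed")

    subfamily_of = {pid: t.name for t in spec.templates
                    for pid in ids[t.name]}
    truth = TruthTable(elements=pd.DataFrame(
        columns=["protein_id", "kind", "label", "tier", "start", "end",
                 "zone", "subfamily"]),
        subfamily_of=subfamily_of, node_support=node_support)
    return st, truth


def emit_fixtures(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write proteins.fasta, hits.tsv, tree.nwk, truth.tsv and spec.yaml.

    Re-running with the same spec reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, hits, truth = plant_family(spec)
    st, tree_truth = plant_support_tree(spec)

    paths = {name: outdir / name for name in
             ("proteins.fasta", "hits.tsv", "tree.nwk", "truth.tsv",
              "spec.yaml")}
    write_fasta(proteins, paths["proteins.fasta"])
    write_domain_hit_table(hits, paths["hits.tsv"])
    paths["tree.nwk"].write_text(support_tree_to_newick(st) + "\n",
                                 encoding="utf-8")
    truth_df = truth.elements.copy()
    truth_df.to_csv(paths["truth.tsv"], sep="\t", index=False)

    spec_dict = {
        "n_per_subfamily": spec.n_per_subfamily,
        "seed": spec.seed,
        "anchor_identity": spec.anchor_identity,
        "vwa_identity": spec.vwa_identity,
        "n_outgroup": spec.n_outgroup,
        "jitter_spans": spec.jitter_spans,
        "templates": [
            {"name": t.name, "n_vwa": t.n_vwa, "n_sushi": t.n_sushi,
             "cb_tiers": list(t.cb_tiers), "has_lg": t.has_lg,
             "insert_profile": t.insert_profile,
             "insert_length_range": list(t.insert_length_range),
             "lcr_plan": dict(t.lcr_plan), "support": t.support}
            for t in spec.templates],
    }
    with open(paths["spec.yaml"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=True)
    return paths
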