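"""End-to-end orchestration: hits -> architectures -> anchors/inserts ->
LCR zones -> composition clusters -> clade partition -> report.

The pipeline is deterministic given (inputs, config, seed); the report
is regenerable byte-identically.  A failure in one protein is logged
and skipped without aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from ._version import __version__
from .clade_subfamily import (SupportClass, find_family_clade,
                              partition_subfamilies)
from .composition_cluster import choose_k, composition_matrix
from .domain_scan import assemble_architecture
from .homology_filter import EvalueModel, select_candidates
from .io_formats import (read_domain_hit_table, read_fasta,
                         parse_support_tree, write_matrix_tsv)
from .lcr_zones import LcrParams, assign_zones, detect_lcrs, zone_intervals
from .lg_inserts import AnchorSet, extract_insert, locate_anchor_pair

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run configuration; unknown keys in a config file are fatal."""

    fasta: str
    hits: str
    tree: str
    outdir: str
    references: list[str] = field(default_factory=list)
    reference_id: Optional[str] = None   # protein whose first VWA is the gate reference
    signal_tsv: Optional[str] = None     # optional protein_id/start/end table
    homology_threshold: float = 1e-10
    confident_ceiling: float = 1e-5
    family_min_class: str = "strong"
    subfamily_min_class: str = "medium"
    medium_ufboot_only: bool = False
    anchor_min_identity: float = 0.5
    max_complete_gap: int = 250
    lcr_window: int = 12
    lcr_trigger: float = 2.2
    lcr_extend: float = 2.5
    lcr_core: Optional[float] = 1.5
    zscore: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("homology_threshold", "confident_ceiling",
                     "anchor_min_identity", "lcr_trigger", "lcr_extend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("family_min_class", "subfamily_min_class"):
            if getattr(self, name) not in SupportClass.__members__:
                raise ValueError(f"{name} must be one of "
                                 f"{list(SupportClass.__members__)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def digest(self) -> str:
        """Fingerprint of the analysis parameters (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("fasta", "hits", "tree", "outdir", "signal_tsv")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-protein summary plus family-level results."""

    per_protein: pd.DataFrame
    family_leaves: frozenset[str]
    subfamilies: list[tuple[str, frozenset[str], SupportClass]]
    insert_clusters: Optional[pd.Series]
    lcr_clusters: Optional[pd.Series]
    n_failed: int
    config_digest: str
    version: str = __version__


def _read_signal_spans(path: Optional[str]) -> dict[str, tuple[int, int]]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep="\t")
    return {r.protein_id: (int(r.start), int(r.end))
            for r in df.itertuples()}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and write outputs.

    Raises before any stage runs if a reference leaf is missing from
    the tree; per-protein failures later are isolated and counted.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"archetyper {__version__}",
                            f"config {config.digest()}"]

    proteins = read_fasta(config.fasta)
    hits = read_domain_hit_table(config.hits,
                                 evalue_ceiling=config.confident_ceiling)
    tree = parse_support_tree(Path(config.tree).read_text(encoding="utf-8"))
    signal_spans = _read_signal_spans(config.signal_tsv)
    log_lines.append(f"inputs: {len(proteins)} proteins, {len(hits)} hits, "
                     f"{len(tree.leaf_names)} tree leaves")

    missing = set(config.references) - set(tree.leaf_names)
    if missing:
        raise ValueError(f"reference leaves missing from tree: "
                         f"{sorted(missing)}")

    hits_by_protein: dict[str, list] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    anchors = AnchorSet(min_identity=config.anchor_min_identity)
    lcr_params = LcrParams(window=config.lcr_window,
                           k_trigger=config.lcr_trigger,
                           k_extend=config.lcr_extend,
                           k_core=config.lcr_core)

    arch_rows = []
    insert_regions = []
    lcr_rows = []
    architectures = {}
    failed = 0
    for prot in proteins:
        try:
            n_span, c_span = locate_anchor_pair(prot, anchors)
            arch = assemble_architecture(
                prot, hits_by_protein.get(prot.id, []),
                signal_span=signal_spans.get(prot.id),
                n_anchor_span=n_span, c_anchor_span=c_span,
                max_complete_gap=config.max_complete_gap)
            architectures[prot.id] = arch

            insert_len = 0
            if n_span is not None and c_span is not None \
                    and n_span[1] < c_span[0]:
                ins = extract_insert(prot, n_span, c_span)
                if ins.length > 0:
                    insert_regions.append(ins)
                insert_len = ins.length

            zones = zone_intervals(arch)
            lcrs = assign_zones(detect_lcrs(prot, lcr_params), zones)
            zone_counts = {z: 0 for z in ("zone1", "zone2", "zone3",
                                          "zone4", "outside")}
            for seg in lcrs:
                zone_counts[seg.zone] += 1
                lcr_rows.append(dict(protein_id=prot.id, start=seg.start,
                                     end=seg.end,
                                     mean_entropy=round(seg.mean_entropy, 4),
                                     zone=seg.zone, ordinal=seg.ordinal))

            arch_rows.append(dict(
                protein_id=prot.id, n_vwa=arch.n_vwa,
                tiers=",".join(arch.tier_multiset),
                lg_status=arch.lg_status, insert_length=insert_len,
                **{f"lcr_{z}": c for z, c in zone_counts.items()}))
        except Exception as exc:
            failed += 1
            log.warning("protein %s skipped: %s", prot.id, exc)
            log_lines.append(f"skipped {prot.id}: {exc}")
    log_lines.append(f"architectures: {len(arch_rows)} ok, {failed} skipped")

    # Homology gate on extracted VWA subsequences.
    gate_pass_count: dict[str, int] = {}
    ref_seq = None
    if config.reference_id is not None:
        ref_prot = next((p for p in proteins
                         if p.id == config.reference_id), None)
        if ref_prot is None:
            raise ValueError(f"reference protein {config.reference_id!r} "
                             "not in FASTA")
        ref_arch = architectures.get(config.reference_id)
        vwas = ref_arch.vwa_elements() if ref_arch else []
        if vwas:
            ref_seq = ref_prot.seq[vwas[0].start - 1:vwas[0].end]
    if ref_seq is not None:
        regions = []
        for prot in proteins:
            arch = architectures.get(prot.id)
            if arch is None:
                continue
            for k, e in enumerate(arch.vwa_elements(), start=1):
                regions.append((f"{prot.id}/vwa{k}",
                                prot.seq[e.start - 1:e.end]))
        passed, failed_gate = select_candidates(
            regions, ref_seq, threshold=config.homology_threshold,
            model=EvalueModel.canonical())
        for rid, _, _ in passed:
            pid = rid.split("/")[0]
            gate_pass_count[pid] = gate_pass_count.get(pid, 0) + 1
        log_lines.append(f"gate: {len(passed)} / {len(regions)} VWA regions "
                         f"pass at {config.homology_threshold:g}")

    # Clade extraction and subfamily partition.
    family_leaves: frozenset[str] = frozenset()
    subfams: list = []
    subfamily_of: dict[str, str] = {}
    if config.references:
        family = find_family_clade(
            tree, set(config.references),
            min_class=SupportClass[config.family_min_class],
            medium_ufboot_only=config.medium_ufboot_only)
        part = partition_subfamilies(
            tree, family,
            min_class=SupportClass[config.subfamily_min_class],
            medium_ufboot_only=config.medium_ufboot_only)
        family_leaves = part.family_leaves
        subfams = part.subfamilies
        for name, leaves, _ in subfams:
            for leaf in leaves:
                subfamily_of[leaf] = name
        log_lines.append(f"family clade: {len(family_leaves)} leaves, "
                         f"{len(subfams)} subfamilies")

    # Composition clustering of inserts and of LCRs.
    insert_clusters = lcr_clusters = None
    if len(insert_regions) >= 3:
        mat = composition_matrix([(i.protein_id, i.sequence)
                                  for i in insert_regions])
        if config.zscore:
            mat = (mat - mat.mean()) / mat.std(ddof=0).replace(0, 1.0)
        res = choose_k(mat)
        insert_clusters = pd.Series(res.chosen_labels, index=mat.index,
                                    name="insert_cluster")
        write_matrix_tsv(mat, outdir / "insert_composition.tsv")
        log_lines.append(f"insert clustering: k={res.chosen_k} "
                         f"(weak_structure={res.weak_structure})")
    lcr_df = pd.DataFrame(lcr_rows, columns=["protein_id", "start", "end",
                                             "mean_entropy", "zone",
                                             "ordinal"])
    if len(lcr_df) >= 3:
        prot_by_id = {p.id: p for p in proteins}
        lcr_regions = [(f"{r.protein_id}:{r.start}-{r.end}",
                        prot_by_id[r.protein_id].seq[r.start - 1:r.end])
                       for r in lcr_df.itertuples()]
        lmat = composition_matrix(lcr_regions)
        lres = choose_k(lmat)
        lcr_clusters = pd.Series(lres.chosen_labels, index=lmat.index,
                                 name="lcr_cluster")
        write_matrix_tsv(lmat, outdir / "lcr_composition.tsv")
        log_lines.append(f"LCR clustering: k={lres.chosen_k}")

    per_protein = pd.DataFrame(arch_rows)
    if not per_protein.empty:
        per_protein["vwa_gate_pass"] = per_protein.protein_id.map(
            lambda p: gate_pass_count.get(p, 0))
        per_protein["in_family"] = per_protein.protein_id.isin(family_leaves)
        per_protein["subfamily"] = per_protein.protein_id.map(
            lambda p: subfamily_of.get(p, ""))
        if insert_clusters is not None:
            per_protein["insert_cluster"] = per_protein.protein_id.map(
                lambda p: int(insert_clusters.get(p, 0)))

    per_protein.to_csv(outdir / "report.tsv", sep="\t", index=False)
    lcr_df.to_csv(outdir / "lcrs.tsv", sep="\t", index=False)
    part_rows = [dict(subfamily=name, leaf=leaf, support=cls.name)
                 for name, leaves, cls in subfams for leaf in sorted(leaves)]
    pd.DataFrame(part_rows, columns=["subfamily", "leaf", "support"]).to_csv(
        outdir / "partition.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n",
                                    encoding="utf-8")

    return RunReport(per_protein=per_protein, family_leaves=family_leaves,
                     subfamilies=subfams, insert_clusters=insert_clusters,
                     lcr_clusters=lcr_clusters, n_failed=failed,
                     config_digest=config.digest())
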