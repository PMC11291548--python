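"""PSSM construction/scanning, tier windows, architecture assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from archetyper.domain_scan import (PSSM, build_pssm, scan, assign_tier,
                                    assemble_architecture)
from archetyper.io_formats import AMINO_ACIDS, DomainHit, ProteinRecord
from archetyper.synthetic_data import BACKGROUND_COMPOSITION, sample_sequence

UNIFORM = np.full(20, 0.05)


class TestBuildPssm:
    def test_identical_sequences_tiny_pseudocount_limit(self):
        pssm = build_pssm(["ACDE"] * 5, UNIFORM, pseudocount=1e-9)
        cons = [AMINO_ACIDS.index(a) for a in "ACDE"]
        for j, a in enumerate(cons):
            assert pssm.scores[a, j] == pytest.approx(math.log2(20),
                                                      abs=1e-6)

    def test_background_counts_give_zero_scores(self):
        # A column where every residue appears once over a 20-sequence
        # alignment matches a uniform background exactly.
        seqs = [a * 4 for a in AMINO_ACIDS]
        pssm = build_pssm(seqs, UNIFORM, pseudocount=1.0)
        assert np.allclose(pssm.scores, 0.0, atol=1e-12)

    def test_hand_computed_two_sequence_example(self):
        # counts col0: A=2; col1: A=1,C=1; col2: D=2; col3: E=2;
        # uniform background, pseudocount 1.
        pssm = build_pssm(["AADE", "ACDE"], UNIFORM, pseudocount=1.0)
        expect_a0 = math.log2(((2 + 0.05) / 3) / 0.05)
        expect_a1 = math.log2(((1 + 0.05) / 3) / 0.05)
        expect_g1 = math.log2(((0 + 0.05) / 3) / 0.05)
        assert pssm.scores[AMINO_ACIDS.index("A"), 0] \
            == pytest.approx(expect_a0)
        assert pssm.scores[AMINO_ACIDS.index("A"), 1] \
            == pytest.approx(expect_a1)
        assert pssm.scores[AMINO_ACIDS.index("G"), 1] \
            == pytest.approx(expect_g1)

    def test_all_x_column_fatal(self):
        with pytest.raises(ValueError):
            build_pssm(["AXDE", "AXDE"], UNIFORM)


@pytest.fixture(scope="module")
def planted_pssm():
    """PSSM built from noisy copies of a fixed 18-residue motif."""
    rng = np.random.default_rng(5)
    motif = "WWDDKKHHCCWWDDKKHH"
    seeds = []
    for _ in range(8):
        s = list(motif)
        for i in range(len(s)):
            if rng.random() < 0.1:
                s[i] = AMINO_ACIDS[rng.integers(20)]
        seeds.append("".join(s))
    return motif, build_pssm(seeds, BACKGROUND_COMPOSITION, name="motif")


class TestScan:
    def test_planted_consensus_is_top_hit(self, planted_pssm, rng):
        motif, pssm = planted_pssm
        seq = sample_sequence(BACKGROUND_COMPOSITION, 49, rng) + motif \
            + sample_sequence(BACKGROUND_COMPOSITION, 60, rng)
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        hits = scan(pssm, prot, n_null=150, seed=3)
        assert hits, "planted motif not detected"
        best = min(hits, key=lambda h: h.ievalue)
        assert best.start == 50

    def test_two_planted_copies_two_hits(self, planted_pssm, rng):
        motif, pssm = planted_pssm
        seq = motif + sample_sequence(BACKGROUND_COMPOSITION, 50, rng) \
            + motif
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        hits = scan(pssm, prot, n_null=150, seed=3, report_ceiling=0.5)
        starts = sorted(h.start for h in hits)
        assert 1 in starts and len(seq) - len(motif) + 1 in starts

    def test_background_yields_no_strong_hit(self, planted_pssm):
        _, pssm = planted_pssm
        n_clean = 0
        for i in range(20):
            seq = sample_sequence(BACKGROUND_COMPOSITION, 200, 1000 + i)
            prot = ProteinRecord(id="p", taxon="", seq=seq)
            hits = scan(pssm, prot, n_null=120, seed=i,
                        report_ceiling=0.05)
            n_clean += not hits
        assert n_clean >= 19

    def test_coarse_null_fatal(self, planted_pssm, rng):
        _, pssm = planted_pssm
        prot = ProteinRecord(id="p", taxon="",
                             seq=sample_sequence(BACKGROUND_COMPOSITION,
                                                 60, rng))
        with pytest.raises(ValueError):
            scan(pssm, prot, n_null=50)


class TestAssignTier:
    @pytest.mark.parametrize("ev,label", [
        (1e-6, "CBM_14"),
        (0.5, "CBM_14L1"),
        (5000.0, "CBM_14L2"),
        (20000.0, "none"),
        (1e-5, "CBM_14L1"),   # lower-inclusive boundary
        (1.0, "CBM_14L2"),
        (1e4, "none"),
        (0.0, "CBM_14"),
    ])
    def test_window_assignment(self, ev, label):
        assert assign_tier(ev) == label

    def test_negative_fatal(self):
        with pytest.raises(ValueError):
            assign_tier(-1.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False))
    def test_partition_of_nonnegative_reals(self, ev):
        """Every non-negative e-value maps to exactly one tier label."""
        label = assign_tier(ev)
        windows = {"CBM_14": ev < 1e-5,
                   "CBM_14L1": 1e-5 <= ev < 1.0,
                   "CBM_14L2": 1.0 <= ev < 1e4,
                   "none": ev >= 1e4}
        assert sum(windows.values()) == 1
        assert windows[label]


class TestAssembleArchitecture:
    def _prot(self, n=400):
        return ProteinRecord(id="p", taxon="", seq="A" * n)

    def test_full_layout_flags(self):
        hits = [DomainHit("p", "VWA", 1 + 61 * i, 60 + 61 * i, 50, 1e-20)
                for i in range(4)]
        hits.append(DomainHit("p", "CBM_14", 260, 300, 20, 1e-8))
        arch = assemble_architecture(self._prot(), hits,
                                     n_anchor_span=(310, 341),
                                     c_anchor_span=(350, 400))
        assert arch.n_vwa == 4 and arch.has_cb
        assert arch.lg_status == "complete"  # gap 8 <= 250

    def test_overlap_keeps_better_ievalue(self):
        hits = [DomainHit("p", "VWA", 10, 100, 50, 1e-30),
                DomainHit("p", "VWA", 50, 140, 40, 1e-6)]
        arch = assemble_architecture(self._prot(), hits)
        assert [(e.start, e.end) for e in arch.elements] == [(10, 100)]

    def test_no_hits_empty_architecture(self):
        arch = assemble_architecture(self._prot(), [])
        assert arch.elements == [] and arch.lg_status == "absent"

    def test_one_anchor_is_partial(self):
        arch = assemble_architecture(self._prot(), [],
                                     n_anchor_span=(10, 41))
        assert arch.lg_status == "partial"

    def test_wide_gap_without_middle_hit_is_partial(self):
        arch = assemble_architecture(self._prot(1000), [],
                                     n_anchor_span=(10, 41),
                                     c_anchor_span=(700, 760))
        assert arch.lg_status == "partial"
        arch2 = assemble_architecture(
            self._prot(1000),
            [DomainHit("p", "Laminin_G_3", 200, 400, 30, 1e-9)],
            n_anchor_span=(10, 41), c_anchor_span=(700, 760))
        assert arch2.lg_status == "complete"

    def test_elements_sorted_nonoverlapping(self, small_family):
        _, proteins, hits, truth = small_family
        by_prot = {}
        for h in hits:
            by_prot.setdefault(h.protein_id, []).append(h)
        for prot in proteins:
            arch = assemble_architecture(prot, by_prot.get(prot.id, []))
            spans = [(e.start, e.end) for e in arch.elements]
            assert spans == sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_cb_above_l2_ceiling_dropped(self):
        hits = [DomainHit("p", "CBM_14", 10, 60, 5, 2e4)]
        arch = assemble_architecture(self._prot(), hits)
        assert arch.elements == []
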