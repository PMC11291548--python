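"""Entropy segmenter, zone geometry and ordinal numbering."""

import math

import numpy as np
import pytest

from archetyper.domain_scan import DomainHit, assemble_architecture
from archetyper.io_formats import ProteinRecord, AMINO_ACIDS
from archetyper.lcr_zones import (LcrParams, LcrSegment, assign_zones,
                                  detect_lcrs, window_entropy,
                                  zone_intervals)
from archetyper.synthetic_data import BACKGROUND_COMPOSITION, sample_sequence


class TestWindowEntropy:
    def test_single_letter_floor(self):
        assert window_entropy("AAAAAAAAAAAA") == 0.0

    def test_two_letter_equal_mix(self):
        assert window_entropy("ABABABABABAB".replace("B", "C")) \
            == pytest.approx(1.0)

    def test_uniform_twelve_residues(self):
        assert window_entropy(AMINO_ACIDS[:12]) \
            == pytest.approx(math.log2(12))

    def test_x_excluded(self):
        assert window_entropy("AAXXAA") == 0.0

    def test_all_x_fatal(self):
        with pytest.raises(ValueError):
            window_entropy("XXXX")


def _tract(rng, length=30, dom="D"):
    comp = np.zeros(20)
    comp[AMINO_ACIDS.index(dom)] = 0.85
    comp[AMINO_ACIDS.index("A" if dom != "A" else "G")] = 0.15
    return sample_sequence(comp, length, rng)


class TestDetectLcrs:
    def test_planted_tract_covered(self, rng):
        """A planted poly-D tract is covered by one detected segment,
        cross-checked against brute-force window enumeration."""
        tract = "D" * 30
        seq = sample_sequence(BACKGROUND_COMPOSITION, 100, rng) + tract \
            + sample_sequence(BACKGROUND_COMPOSITION, 100, rng)
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        params = LcrParams()
        segs = detect_lcrs(prot, params)
        covering = [s for s in segs if s.start <= 101 and s.end >= 130]
        assert len(covering) == 1
        # Brute-force oracle: every window fully inside the tract's
        # interior must be below trigger, hence inside some segment.
        W = params.window
        for i in range(101, 131 - W + 1):
            h = window_entropy(seq[i - 1:i - 1 + W])
            assert h <= params.k_trigger
            assert any(s.start <= i and i + W - 1 <= s.end for s in segs)

    def test_high_entropy_random_sequence_clean(self):
        fp = 0
        for i in range(100):
            seq = sample_sequence(BACKGROUND_COMPOSITION, 200, 5000 + i)
            prot = ProteinRecord(id="p", taxon="", seq=seq)
            fp += bool(detect_lcrs(prot))
        assert fp <= 1

    def test_two_separated_tracts_two_segments(self, rng):
        seq = _tract(rng, 30, "K") \
            + sample_sequence(BACKGROUND_COMPOSITION, 50, rng) \
            + _tract(rng, 30, "K")
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        segs = detect_lcrs(prot)
        assert len(segs) == 2

    def test_segments_disjoint_sorted_below_extend(self, rng):
        seq = "".join(_tract(rng, 25) +
                      sample_sequence(BACKGROUND_COMPOSITION, 40, rng)
                      for _ in range(4))
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        params = LcrParams()
        segs = detect_lcrs(prot, params)
        assert segs
        starts = [s.start for s in segs]
        assert starts == sorted(starts)
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start
        for s in segs:
            assert s.mean_entropy <= params.k_extend

    def test_lower_trigger_never_covers_more(self, rng):
        """Lowering K_trig never increases LCR-covered residues."""
        seq = "".join(_tract(rng, 22, d) +
                      sample_sequence(BACKGROUND_COMPOSITION, 35, rng)
                      for d in "DSKT")
        prot = ProteinRecord(id="p", taxon="", seq=seq)
        prev = None
        for kt in (2.2, 1.9, 1.6, 1.3, 1.0):
            params = LcrParams(k_trigger=kt, k_core=min(kt, 1.5))
            covered = sum(s.length for s in detect_lcrs(prot, params))
            if prev is not None:
                assert covered <= prev
            prev = covered


def _arch_with_zones():
    """SP + 4 VWA + CB + both anchors; well-separated spans."""
    prot = ProteinRecord(id="p", taxon="", seq="A" * 1200)
    hits = [DomainHit("p", "VWA", 101 + 200 * i, 200 + 200 * i, 50, 1e-20)
            for i in range(4)]
    hits.append(DomainHit("p", "CBM_14", 901, 950, 20, 1e-7))
    return assemble_architecture(prot, hits, signal_span=(1, 20),
                                 n_anchor_span=(961, 992),
                                 c_anchor_span=(1101, 1160))


class TestZoneGeometry:
    def test_four_tandem_vwa_gives_three_zone2_intervals(self):
        zones = zone_intervals(_arch_with_zones())
        assert zones["zone1"] == [(21, 100)]
        assert len(zones["zone2"]) == 3
        assert zones["zone3"] == [(801, 900)]
        assert zones["zone4"] == [(993, 1100)]
        flat = [iv for ivs in zones.values() for iv in ivs]
        for i, (s1, e1) in enumerate(flat):
            for s2, e2 in flat[i + 1:]:
                assert e1 < s2 or e2 < s1  # pairwise disjoint

    def test_single_vwa_no_cb_drops_zones_2_3(self):
        prot = ProteinRecord(id="p", taxon="", seq="A" * 400)
        arch = assemble_architecture(
            prot, [DomainHit("p", "VWA", 51, 200, 50, 1e-20)])
        zones = zone_intervals(arch)
        assert "zone2" not in zones and "zone3" not in zones

    def test_vwa_at_position_one_drops_zone1(self):
        prot = ProteinRecord(id="p", taxon="", seq="A" * 400)
        arch = assemble_architecture(
            prot, [DomainHit("p", "VWA", 1, 150, 50, 1e-20)])
        assert "zone1" not in zone_intervals(arch)


class TestAssignZones:
    def _seg(self, start, end):
        return LcrSegment(protein_id="p", start=start, end=end,
                          mean_entropy=1.0)

    def test_midpoint_rule(self):
        zones = {"zone1": [(1, 100)], "zone2": [(101, 300)]}
        out = assign_zones([self._seg(90, 120)], zones)  # midpoint 105
        assert out[0].zone == "zone2"

    def test_containment_and_ordinals(self):
        zones = {"zone3": [(140, 400)], "zone4": [(450, 1000)]}
        segs = [self._seg(150, 170), self._seg(500, 520),
                self._seg(700, 730), self._seg(900, 940),
                self._seg(50, 60)]
        out = assign_zones(segs, zones)
        by_span = {(s.start, s.end): s for s in out}
        assert by_span[(150, 170)].zone == "zone3"
        assert by_span[(150, 170)].ordinal == 1
        assert [by_span[k].ordinal for k in [(500, 520), (700, 730),
                                             (900, 940)]] == [1, 2, 3]
        assert by_span[(50, 60)].zone == "outside"

    def test_planted_zone_recovery(self, small_family):
        """Planted tracts interior to zone intervals get their zone."""
        _, proteins, hits, truth = small_family
        by_prot = {}
        for h in hits:
            by_prot.setdefault(h.protein_id, []).append(h)
        from archetyper.lg_inserts import locate_anchor_pair
        checked = 0
        for prot in proteins:
            rows = truth.rows_for(prot.id, "lcr")
            if rows.empty:
                continue
            n_span, c_span = locate_anchor_pair(prot)
            sig = truth.rows_for(prot.id, "signal")
            arch = assemble_architecture(
                prot, by_prot.get(prot.id, []),
                signal_span=None if sig.empty else (sig.iloc[0].start,
                                                    sig.iloc[0].end),
                n_anchor_span=n_span, c_anchor_span=c_span)
            segs = assign_zones(detect_lcrs(prot), zone_intervals(arch))
            for row in rows.itertuples():
                cover = [s for s in segs
                         if s.start <= row.start and s.end >= row.end]
                assert cover, (prot.id, row.start)
                assert cover[0].zone == row.zone, (prot.id, row.start)
                checked += 1
        assert checked >= 10
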