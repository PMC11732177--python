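"""Pair enumeration, distances, confidence filters and distance strata."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_mod_site, make_site
from cyslys.proximity import (
    ProximityConfig,
    apply_quality_filters,
    enumerate_pairs,
    mark_modified,
    nearest_counterpart_histogram,
)
from cyslys.structure_io import PAEMatrix


def _random_protein(rng, n_cys=3, n_lys=4, n_res=20, box=40.0):
    idx = rng.choice(np.arange(1, n_res + 1), size=n_cys + n_lys, replace=False)
    cys = [
        make_site("P1", int(i), "C", tuple(rng.uniform(0, box, 3)),
                  float(rng.uniform(40, 100)))
        for i in sorted(idx[:n_cys])
    ]
    lys = [
        make_site("P1", int(i), "K", tuple(rng.uniform(0, box, 3)),
                  float(rng.uniform(40, 100)))
        for i in sorted(idx[n_cys:])
    ]
    pae = PAEMatrix("P1", rng.uniform(0, 30, (n_res, n_res)))
    return cys, lys, pae


class TestEnumeratePairs:
    def test_three_four_five_triangle(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0))
        k = make_site("P1", 2, "K", (3.0, 4.0, 0.0))
        (pair,) = enumerate_pairs([c], [k])
        assert pair.distance == pytest.approx(5.0)

    def test_cartesian_product_count(self):
        rng = np.random.default_rng(0)
        cys, lys, pae = _random_protein(rng, n_cys=2, n_lys=3)
        assert len(enumerate_pairs(cys, lys, pae)) == 6

    def test_pair_pae_is_symmetrized(self):
        c = make_site("P1", 1, "C")
        k = make_site("P1", 3, "K", (1.0, 0.0, 0.0))
        mat = np.zeros((3, 3))
        mat[0, 2], mat[2, 0] = 4.0, 6.0
        (pair,) = enumerate_pairs([c], [k], PAEMatrix("P1", mat))
        assert pair.pair_pae == pytest.approx(5.0)

    def test_mixed_proteins_rejected(self):
        c = make_site("P1", 1, "C")
        k = make_site("P2", 2, "K")
        with pytest.raises(ValueError, match="multiple proteins"):
            enumerate_pairs([c], [k])

    def test_distance_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        cys, lys, pae = _random_protein(rng)
        base = {
            (p.cys.residue_index, p.lys.residue_index): p.distance
            for p in enumerate_pairs(cys, lys, pae)
        }
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-100, 100, 3)

        def move(s):
            coord = tuple(q @ np.asarray(s.coord) + t)
            return make_site(s.protein_id, s.residue_index, s.aa, coord, s.plddt)

        moved = {
            (p.cys.residue_index, p.lys.residue_index): p.distance
            for p in enumerate_pairs([move(c) for c in cys], [move(k) for k in lys], pae)
        }
        for key in base:
            assert moved[key] == pytest.approx(base[key], abs=1e-9)


class TestQualityFilters:
    def test_passing_and_proximal(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0), 90.0)
        k = make_site("P1", 2, "K", (10.0, 0.0, 0.0), 90.0)
        mat = np.full((2, 2), 5.0)
        pairs = enumerate_pairs([c], [k], PAEMatrix("P1", mat))
        (pair,), tally = apply_quality_filters(pairs)
        assert pair.passes_quality and pair.proximal

    def test_plddt_just_below_cutoff_fails(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0), 69.9)
        k = make_site("P1", 2, "K", (1.0, 0.0, 0.0), 99.0)
        (pair,), tally = apply_quality_filters(enumerate_pairs([c], [k]))
        assert not pair.passes_quality
        assert not pair.proximal
        assert tally["low_plddt"] == 1

    def test_plddt_exactly_70_passes(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0), 70.0)
        k = make_site("P1", 2, "K", (1.0, 0.0, 0.0), 70.0)
        (pair,), _ = apply_quality_filters(enumerate_pairs([c], [k]))
        assert pair.passes_quality

    def test_distance_threshold_inclusive(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0))
        at = make_site("P1", 2, "K", (15.0, 0.0, 0.0))
        beyond = make_site("P1", 3, "K", (15.001, 0.0, 0.0))
        pairs, _ = apply_quality_filters(enumerate_pairs([c], [at, beyond]))
        flags = {p.lys.residue_index: p.proximal for p in pairs}
        assert flags == {2: True, 3: False}

    def test_matches_naive_double_loop(self):
        # independent O(n^2) re-implementation of enumeration + filtering
        rng = np.random.default_rng(7)
        config = ProximityConfig()
        for _ in range(20):
            cys, lys, pae = _random_protein(rng, n_cys=4, n_lys=5, n_res=30)
            got, _ = apply_quality_filters(enumerate_pairs(cys, lys, pae), config)
            got_map = {
                (p.cys.residue_index, p.lys.residue_index):
                    (round(p.distance, 9), p.passes_quality, p.proximal)
                for p in got
            }
            expected = {}
            for c in cys:
                for k in lys:
                    d = sum((a - b) ** 2 for a, b in zip(c.coord, k.coord)) ** 0.5
                    ppae = 0.5 * (
                        pae.values[c.residue_index - 1, k.residue_index - 1]
                        + pae.values[k.residue_index - 1, c.residue_index - 1]
                    )
                    ok = (
                        c.plddt >= config.plddt_min
                        and k.plddt >= config.plddt_min
                        and ppae <= config.pae_max
                    )
                    expected[(c.residue_index, k.residue_index)] = (
                        round(d, 9), ok, ok and d <= config.distance_threshold
                    )
            assert got_map == expected

    @given(dp=st.floats(0, 30), dq=st.floats(0, 10), seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=50)
    def test_filter_monotonicity(self, dp, dq, seed):
        # raising plddt_min or lowering pae_max never adds a passing pair
        rng = np.random.default_rng(seed)
        cys, lys, pae = _random_protein(rng)
        pairs = enumerate_pairs(cys, lys, pae)
        lax, _ = apply_quality_filters(pairs, ProximityConfig())
        strict, _ = apply_quality_filters(
            pairs, ProximityConfig(plddt_min=70 + dq, pae_max=max(15 - dp, 0.1))
        )
        lax_pass = {
            (p.cys.residue_index, p.lys.residue_index) for p in lax if p.passes_quality
        }
        strict_pass = {
            (p.cys.residue_index, p.lys.residue_index) for p in strict if p.passes_quality
        }
        assert strict_pass <= lax_pass

    def test_per_residue_pae_mode(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0), 90.0)
        k = make_site("P1", 2, "K", (5.0, 0.0, 0.0), 90.0)
        # pairwise entry low, but row means above 15: per-pair mode passes,
        # per-residue mode excludes
        row_heavy = np.array([[0.0, 2.0, 50.0], [2.0, 0.0, 50.0], [50.0, 50.0, 0.0]])
        c3 = make_site("P1", 1, "C", (0.0, 0.0, 0.0), 90.0)
        k3 = make_site("P1", 2, "K", (5.0, 0.0, 0.0), 90.0)
        pairs = enumerate_pairs([c3], [k3], PAEMatrix("P1", row_heavy))
        (pair_mode,), _ = apply_quality_filters(pairs, ProximityConfig(pae_mode="pair"))
        (res_mode,), _ = apply_quality_filters(pairs, ProximityConfig(pae_mode="residue"))
        assert pair_mode.passes_quality
        assert not res_mode.passes_quality


class TestMarkModified:
    def test_flags_follow_significant_sites_only(self):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0))
        k = make_site("P1", 2, "K", (3.0, 0.0, 0.0))
        pairs, _ = apply_quality_filters(enumerate_pairs([c], [k]))
        sites = [
            make_mod_site("P1", 1, "redox", significant=True),
            make_mod_site("P1", 2, "acetyl", significant=False),
        ]
        (pair,) = mark_modified(pairs, sites)
        assert pair.cys_modified and not pair.lys_modified


class TestNearestCounterpartHistogram:
    def _pairs(self, lys_distances, plddt=90.0):
        c = make_site("P1", 1, "C", (0.0, 0.0, 0.0), plddt)
        lys = [
            make_site("P1", 10 + i, "K", (d, 0.0, 0.0), plddt)
            for i, d in enumerate(lys_distances)
        ]
        pairs, _ = apply_quality_filters(enumerate_pairs([c], lys))
        return pairs

    def test_min_rule_bins_once(self):
        pairs = self._pairs([6.0, 12.0])
        sites = [make_mod_site("P1", 1, "redox")]
        res = nearest_counterpart_histogram(sites, pairs)
        assert res.counts["redox_cys"]["[5, 7.5)"] == 1
        assert sum(res.counts["redox_cys"].values()) == 1

    def test_no_counterpart_goes_to_overflow(self):
        sites = [make_mod_site("P2", 5, "acetyl")]
        res = nearest_counterpart_histogram(sites, [])
        assert res.counts["acetyl_lys"]["> 15"] == 1
        assert res.unpaired == [("P2", "acetyl", 5)]

    def test_fraction_within_threshold(self):
        pairs = self._pairs([6.0])
        sites = [
            make_mod_site("P1", 1, "redox"),
            make_mod_site("P2", 1, "redox"),  # no structure -> beyond threshold
        ]
        res = nearest_counterpart_histogram(sites, pairs)
        assert res.fraction_within["redox_cys"] == pytest.approx(0.5)

    def test_planted_design_recovered(self):
        # plant known nearest distances and check the histogram matches design
        design = {2.0: "[0, 5)", 5.0: "[5, 7.5)", 7.5: "[7.5, 10)", 14.9: "[12.5, 15)", 22.0: "> 15"}
        sites, all_pairs = [], []
        for i, d in enumerate(sorted(design)):
            pid = f"P{i}"
            c = make_site(pid, 1, "C", (0.0, 0.0, 0.0))
            k = make_site(pid, 2, "K", (d, 0.0, 0.0))
            pairs, _ = apply_quality_filters(enumerate_pairs([c], [k]))
            all_pairs.extend(pairs)
            sites.append(make_mod_site(pid, 1, "redox"))
        res = nearest_counterpart_histogram(sites, all_pairs)
        for d, label in design.items():
            assert res.counts["redox_cys"][label] >= 1
        assert sum(res.counts["redox_cys"].values()) == len(design)
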