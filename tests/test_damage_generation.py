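"""Track emulator, deposition caller, and fibre-rule clustering."""

import numpy as np
import pytest

from nhejsim import correlations as C
from nhejsim import damage_generation as dg
from nhejsim import metrics
from conftest import brute_force_cluster_oracle


class TestPrimariesForDose:
    def test_zero_dose_gives_zero_tracks(self, nucleus):
        spec = dg.ExposureSpec("proton", 0.0, 10.0, 0)
        assert dg.primaries_for_dose(spec, nucleus) == 0.0

    def test_energy_balance_hand_computation(self, nucleus):
        # 5 µm water sphere: mass 6.545e-14 kg -> ~408.5 keV per Gy;
        # mean chord 10/3 µm -> ~12.26 expected tracks at 1 Gy, 10 keV/µm
        spec = dg.ExposureSpec("proton", 1.0, 10.0, 0)
        lam = dg.primaries_for_dose(spec, nucleus)
        mass = 1000.0 * 4 / 3 * np.pi * (2.5e-6) ** 3
        expected = (mass / 1.602176634e-16) / (10.0 * 10.0 / 3.0)
        assert lam == pytest.approx(expected, rel=1e-12)
        assert lam == pytest.approx(12.26, abs=0.05)

    def test_linear_in_dose(self, nucleus):
        lam1 = dg.primaries_for_dose(dg.ExposureSpec("proton", 1.0, 10.0, 0), nucleus)
        lam2 = dg.primaries_for_dose(dg.ExposureSpec("proton", 2.0, 10.0, 0), nucleus)
        assert lam2 == pytest.approx(2 * lam1)

    def test_invalid_let_rejected(self):
        with pytest.raises(ValueError):
            dg.ExposureSpec("proton", 1.0, 0.0, 0)

    def test_carbon_unsupported(self):
        with pytest.raises(ValueError, match="unsupported species"):
            dg.ExposureSpec("carbon", 1.0, 10.0, 0)


class TestGenerateTracks:
    def test_zero_tracks(self, nucleus):
        assert dg.generate_tracks(0, nucleus, np.random.default_rng(0)) == []

    def test_chord_endpoints_on_sphere(self, nucleus):
        rng = np.random.default_rng(1)
        for track in dg.generate_tracks(50, nucleus, rng):
            entry = np.asarray(track.entry_nm)
            exit_ = entry + track.length_nm * np.asarray(track.direction)
            r = nucleus.radius_nm
            assert np.linalg.norm(entry) == pytest.approx(r, rel=1e-9)
            assert np.linalg.norm(exit_) == pytest.approx(r, rel=1e-9)
            assert track.length_nm <= 2 * r + 1e-9

    def test_mean_chord_is_four_thirds_radius(self, nucleus):
        """Cauchy mean-chord theorem via brute-force averaging."""
        rng = np.random.default_rng(2)
        lengths = np.array(
            [t.length_nm for t in dg.generate_tracks(30000, nucleus, rng)]
        )
        expected = 4.0 / 3.0 * nucleus.radius_nm
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - expected) < 3 * se


class TestGeneratedPatterns:
    def test_deterministic_given_seed(self):
        spec = dg.ExposureSpec("proton", 1.0, 10.0, seed=77)
        a = dg.generate_pattern(spec)
        b = dg.generate_pattern(spec)
        assert a.dsbs == b.dsbs

    def test_all_dsbs_inside_nucleus(self, nucleus):
        rng = np.random.default_rng(3)
        for sp, let in (("proton", 20.0), ("alpha", 20.0)):
            pattern = dg.generate_pattern(
                dg.ExposureSpec(sp, 2.0, let, 0), nucleus, rng
            )
            assert nucleus.contains(pattern.positions()).all()

    def test_zero_dose_empty_pattern(self):
        pattern = dg.generate_pattern(dg.ExposureSpec("proton", 0.0, 10.0, 5))
        assert len(pattern) == 0

    @pytest.mark.parametrize("species,let", [("proton", 5.0), ("proton", 20.0),
                                             ("alpha", 10.0)])
    def test_mean_yield_matches_correlation(self, species, let):
        """E[#DSB] = D·(d·L+e) by construction of the line density."""
        params = C.load_params(species)
        rng = np.random.default_rng(11)
        counts = [
            len(dg.generate_pattern(dg.ExposureSpec(species, 1.0, let, 0), rng=rng))
            for _ in range(400)
        ]
        counts = np.asarray(counts)
        target = params.d * let + params.e
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - target) < 3 * se

    def test_cluster_density_matches_quadratic(self):
        params = C.load_params("proton")
        rng = np.random.default_rng(13)
        cds = [
            metrics.cluster_density(
                dg.generate_pattern(dg.ExposureSpec("proton", 1.0, 10.0, 0), rng=rng)
            )
            for _ in range(600)
        ]
        cds = np.asarray(cds)
        target = C.cluster_density_from_let(10.0, params)
        se = cds.std(ddof=1) / np.sqrt(len(cds))
        assert abs(cds.mean() - target) < 3 * se

    def test_cluster_density_independent_of_dose(self):
        """Only intra-track DSBs are proximal enough to matter."""
        rng = np.random.default_rng(17)
        means = {}
        for dose in (1.0, 5.0):
            cds = [
                metrics.cluster_density(
                    dg.generate_pattern(
                        dg.ExposureSpec("proton", dose, 10.0, 0), rng=rng
                    )
                )
                for _ in range(600)
            ]
            means[dose] = (np.mean(cds), np.std(cds, ddof=1) / np.sqrt(len(cds)))
        diff = abs(means[1.0][0] - means[5.0][0])
        se = np.hypot(means[1.0][1], means[5.0][1])
        assert diff < 3.5 * se


class TestComplexity:
    def test_zero_mean_gives_simple_breaks(self):
        cfg = dg.ComplexityConfig(mean_intercept=0.0, mean_slope_per_let=0.0)
        rng = np.random.default_rng(0)
        assert all(
            dg.sample_complexity("proton", 10.0, rng, cfg) == 0 for _ in range(50)
        )

    def test_mean_complexity_increases_with_let(self):
        rng = np.random.default_rng(1)
        lo = np.mean([dg.sample_complexity("proton", 5.0, rng) for _ in range(5000)])
        hi = np.mean([dg.sample_complexity("proton", 30.0, rng) for _ in range(5000)])
        assert hi > lo
        assert hi == pytest.approx(1.0, abs=0.05)  # mean 1 at 30 keV/µm


class TestDepositionCaller:
    def test_empty_list(self, nucleus):
        pattern = dg.call_dsbs_from_depositions([], nucleus)
        assert len(pattern) == 0

    def test_two_guaranteed_sites_on_opposite_strands_make_one_dsb(self, nucleus):
        """Two 40 eV depositions 2 nm apart must cluster into a single DSB."""
        deps = [
            dg.EnergyDeposition((0.0, 0.0, 0.0), 40.0),
            dg.EnergyDeposition((2.0, 0.0, 0.0), 40.0),
        ]
        config = dg.DamageCallConfig(sensitive_fraction=1.0)
        # scan seeds until the fair coin lands opposite; both sites are
        # always accepted (40 eV > 37.5 eV)
        for seed in range(50):
            pattern = dg.call_dsbs_from_depositions(
                deps, nucleus, config, np.random.default_rng(seed)
            )
            if len(pattern) == 1:
                dsb = pattern.dsbs[0]
                assert dsb.position_nm == pytest.approx((1.0, 0.0, 0.0))
                assert dsb.complexity == 0
                return
        pytest.fail("opposite-strand assignment never produced a DSB")

    def test_below_threshold_energy_never_damages(self, nucleus):
        deps = [dg.EnergyDeposition((0, 0, 0), 4.9), dg.EnergyDeposition((1, 0, 0), 4.0)]
        config = dg.DamageCallConfig(sensitive_fraction=1.0)
        for seed in range(20):
            assert len(dg.call_dsbs_from_depositions(
                deps, nucleus, config, np.random.default_rng(seed))) == 0

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            dg.EnergyDeposition((0, 0, 0), -1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_clustering_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        pos = rng.uniform(-15, 15, size=(n, 3))
        strands = rng.integers(1, 3, size=n)
        dsbs = dg.cluster_damage_sites(pos, strands, np.zeros(n, int), 3.32)
        got = {(tuple(np.round(d.position_nm, 9)), d.complexity + 2) for d in dsbs}
        expected = brute_force_cluster_oracle(pos, strands, 3.32)
        assert got == expected

    def test_coincident_positions_cluster_at_distance_zero(self):
        pos = [[0, 0, 0], [0, 0, 0]]
        dsbs = dg.cluster_damage_sites(pos, [1, 2], [0, 0], 3.32)
        assert len(dsbs) == 1


class TestFibreClustering:
    def test_opposite_strand_backbones_within_ten_bp(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=2, kind="backbone", bp_index=105),
        ]
        out = dg.cluster_fibre_damage(sites)
        assert len(out) == 1 and out[0].complexity == 0

    def test_base_within_margin_adds_complexity(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=2, kind="backbone", bp_index=105),
            dg.DamageSite(strand=1, kind="base", bp_index=98),
        ]
        out = dg.cluster_fibre_damage(sites)
        assert len(out) == 1 and out[0].complexity == 1

    def test_base_attached_to_damaged_backbone_excluded(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=2, kind="backbone", bp_index=105),
            dg.DamageSite(strand=1, kind="base", bp_index=100),
        ]
        out = dg.cluster_fibre_damage(sites)
        assert out[0].complexity == 0

    def test_backbones_beyond_ten_bp_do_not_pair(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=2, kind="backbone", bp_index=112),
        ]
        assert dg.cluster_fibre_damage(sites) == []

    def test_same_strand_only_is_not_a_dsb(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=1, kind="backbone", bp_index=104),
        ]
        assert dg.cluster_fibre_damage(sites) == []

    def test_duplicate_sites_collapsed_with_warning(self):
        sites = [
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=1, kind="backbone", bp_index=100),
            dg.DamageSite(strand=2, kind="backbone", bp_index=103),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            out = dg.cluster_fibre_damage(sites)
        assert len(out) == 1 and out[0].n_backbones == 2
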