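import numpy as np
import pytest

from ndjmap.chromosome_model import dm6_chr2
from ndjmap.meiosis_sim import (NDJ_MI, NDJ_MII, NDJ_NONE, P1, P2, SimConfig,
                                SimConfigError, default_panel, draw_gamete,
                                is_detectable, observable_breakpoints,
                                read_depth_table, simulate_backcross_pool,
                                simulate_bivalent, simulate_cohort, simulate_event)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def config(**kw):
    return SimConfig(**kw)


class TestSimulateBivalent:
    def test_no_crossover_chromatids_are_single_origin(self, rng):
        bv = simulate_bivalent(config(crossover_dist={0: 1.0}), rng)
        assert all(not ch.is_recombinant for ch in bv.chromatids)
        assert [ch.centromere_origin for ch in bv.chromatids] == [P1, P1, P2, P2]

    def test_single_crossover_marks_two_reciprocal_chromatids(self, rng):
        bv = simulate_bivalent(
            config(crossover_dist=[{1: 1.0}, {0: 1.0}]), rng
        )
        assert len(bv.crossovers) == 1
        x = bv.crossovers[0].g
        rec = [ch for ch in bv.chromatids if ch.is_recombinant]
        assert len(rec) == 2
        # reciprocal: on either side of x the two recombinants carry opposite origins
        for probe in (x - 1.0, x + 1.0):
            assert {rec[0].origin_at(probe), rec[1].origin_at(probe)} == {P1, P2}

    def test_origin_conservation_across_the_tetrad(self, rng):
        cfg = config(crossover_dist={0: 0.1, 1: 0.5, 2: 0.4})
        probes = np.linspace(0, cfg.model.axis_length - 1, 500)
        for _ in range(20):
            bv = simulate_bivalent(cfg, rng)
            total = sum(ch.origins_at(probes).astype(int) for ch in bv.chromatids)
            assert np.all(total == 2)

    def test_recombinant_fraction_is_half_monte_carlo(self, rng):
        # each crossover marks 2 of 4 chromatids
        cfg = config(crossover_dist=[{1: 1.0}, {0: 1.0}])
        n = 4000
        rec = sum(
            sum(ch.is_recombinant for ch in simulate_bivalent(cfg, rng).chromatids)
            for _ in range(n)
        )
        frac = rec / (4 * n)
        se = np.sqrt(0.25 / (4 * n))
        assert abs(frac - 0.5) < 3 * se

    def test_interference_gap_respected(self, rng):
        cfg = config(crossover_dist={2: 1.0}, interference_min_gap_bp=5_000_000)
        for _ in range(20):
            bv = simulate_bivalent(cfg, rng)
            for arm in ("2L", "2R"):
                pos = sorted(c.g for c in bv.crossovers if c.arm_label == arm)
                assert all(b - a >= 5_000_000 for a, b in zip(pos, pos[1:]))

    def test_impossible_spacing_is_config_error(self, rng):
        cfg = config(crossover_dist={2: 1.0}, interference_min_gap_bp=60_000_000)
        with pytest.raises(SimConfigError):
            simulate_bivalent(cfg, rng)


class TestDrawGamete:
    def test_normal_gives_one_chromatid(self, rng):
        bv = simulate_bivalent(config(crossover_dist={0: 1.0}), rng)
        assert len(draw_gamete(bv, NDJ_NONE, rng)) == 1

    def test_mi_gives_one_chromatid_per_homolog(self, rng):
        bv = simulate_bivalent(config(crossover_dist={0: 1.0}), rng)
        g = draw_gamete(bv, NDJ_MI, rng)
        assert len(g) == 2
        assert {c.centromere_origin for c in g} == {P1, P2}

    def test_mii_sisters_share_centromere_origin_even_when_recombinant(self, rng):
        cfg = config(crossover_dist={1: 1.0})
        for _ in range(20):
            bv = simulate_bivalent(cfg, rng)
            g = draw_gamete(bv, NDJ_MII, rng)
            assert len(g) == 2
            assert g[0].centromere_origin == g[1].centromere_origin

    def test_mii_reveals_every_single_crossover(self, rng):
        # with at most one crossover per arm, the inherited sister pair always
        # contains exactly one recombinant product of each exchange
        cfg = config(crossover_dist={0: 0.3, 1: 0.7})
        for _ in range(50):
            bv = simulate_bivalent(cfg, rng)
            g = draw_gamete(bv, NDJ_MII, rng)
            assert set(observable_breakpoints(g)) == {c.g for c in bv.crossovers}

    def test_observable_breakpoints_are_odd_parity_positions(self, rng):
        # a position is visible in the pool iff an odd number of inherited
        # chromatids switch origin there (3-strand doubles can cancel)
        cfg = config(crossover_dist={0: 0.2, 1: 0.5, 2: 0.3})
        for _ in range(50):
            bv = simulate_bivalent(cfg, rng)
            g = draw_gamete(bv, NDJ_MII, rng)
            expected = {
                x for x in {c.g for c in bv.crossovers}
                if sum(x in ch.breakpoints for ch in g) % 2 == 1
            }
            assert set(observable_breakpoints(g)) == expected


class TestBackcrossPool:
    def test_true_frequency_states(self, rng):
        cfg = config(crossover_dist={1: 1.0}, seq_error=0.0, n_pool_offspring=0)
        panel = default_panel(cfg.model, 500_000)
        bv = simulate_bivalent(cfg, rng)
        gamete = draw_gamete(bv, NDJ_MI, rng)
        table, truth = simulate_backcross_pool(gamete, panel, cfg, rng)
        assert set(np.unique(truth.ideal_freqs)) <= {0.0, 0.25, 0.5}
        assert np.array_equal(truth.ideal_freqs, np.array([0.0, 0.25, 0.5])[truth.state_counts])

    def test_father_homozygous_p1_yields_zero_frequency(self, rng):
        cfg = config(crossover_dist={0: 1.0}, seq_error=0.0, n_pool_offspring=0,
                     ndj_type=NDJ_MII)
        panel = default_panel(cfg.model, 1_000_000)
        bv = simulate_bivalent(cfg, rng)
        gamete = [bv.chromatids[0], bv.chromatids[1]]  # both P1 sisters
        table, truth = simulate_backcross_pool(gamete, panel, cfg, rng)
        assert np.all(truth.ideal_freqs == 0.0)
        assert table["alt_depth"].sum() == 0

    def test_father_homozygous_p2_yields_half_frequency(self, rng):
        cfg = config(crossover_dist={0: 1.0}, seq_error=0.0, n_pool_offspring=0)
        panel = default_panel(cfg.model, 1_000_000)
        bv = simulate_bivalent(cfg, rng)
        gamete = [bv.chromatids[2], bv.chromatids[3]]
        _, truth = simulate_backcross_pool(gamete, panel, cfg, rng)
        assert np.all(truth.ideal_freqs == 0.5)

    def test_heterozygous_father_converges_to_quarter(self, rng):
        # law of large numbers at depth 10,000
        cfg = config(crossover_dist={0: 1.0}, seq_error=0.0, n_pool_offspring=0,
                     mean_depth=10_000)
        panel = default_panel(cfg.model, 1_000_000)
        bv = simulate_bivalent(cfg, rng)
        gamete = [bv.chromatids[0], bv.chromatids[2]]  # P1 + P2: het everywhere
        table, truth = simulate_backcross_pool(gamete, panel, cfg, rng)
        freq = table["alt_depth"] / (table["ref_depth"] + table["alt_depth"])
        assert np.all(truth.ideal_freqs == 0.25)
        assert freq.mean() == pytest.approx(0.25, abs=0.005)

    def test_single_chromatid_gamete_rejected(self, rng):
        cfg = config()
        panel = default_panel(cfg.model, 1_000_000)
        bv = simulate_bivalent(cfg, rng)
        with pytest.raises(ValueError, match="2 chromosome copies"):
            simulate_backcross_pool([bv.chromatids[0]], panel, cfg, rng)

    def test_empty_panel_rejected(self, rng):
        cfg = config()
        bv = simulate_bivalent(cfg, rng)
        with pytest.raises(ValueError, match="empty"):
            simulate_backcross_pool(list(bv.chromatids[:2]),
                                    default_panel(cfg.model, 500_000).iloc[:0], cfg, rng)


class TestCohort:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = config(marker_spacing_bp=500_000)
        for d in ("a", "b"):
            simulate_cohort(cfg, 3, seed=5, ndj_probs={"MI": 0.7, "MII": 0.3},
                            outdir=tmp_path / d)
        for name in ["event_0000.tsv", "event_0001.tsv", "truth_manifest.json"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_cohort_size_and_manifest(self, tmp_path):
        cfg = config(marker_spacing_bp=500_000)
        out = simulate_cohort(cfg, 63, seed=2, ndj_probs={"MI": 49 / 63, "MII": 14 / 63},
                              outdir=tmp_path)
        assert len(out) == 63
        assert len(list(tmp_path.glob("event_*.tsv"))) == 63
        origins = {t.division_origin for _, t in out}
        assert origins <= {"MI", "MII"} and len(origins) == 2

    def test_empty_cohort(self, tmp_path):
        out = simulate_cohort(config(marker_spacing_bp=500_000), 0, seed=1, outdir=tmp_path)
        assert out == []
        assert (tmp_path / "truth_manifest.json").exists()

    def test_depth_table_round_trip(self, tmp_path, rng):
        cfg = config(marker_spacing_bp=500_000)
        table, _ = simulate_event(cfg, rng)
        from ndjmap.meiosis_sim import write_depth_table
        write_depth_table(table, tmp_path / "t.tsv")
        back = read_depth_table(tmp_path / "t.tsv")
        assert np.array_equal(back["pos"].to_numpy(), table["pos"].to_numpy())
        assert np.array_equal(back["alt_depth"].to_numpy(), table["alt_depth"].to_numpy())


def test_detectability_of_normal_gamete_is_recombination(rng):
    cfg = config(crossover_dist=[{1: 1.0}, {0: 1.0}])
    bv = simulate_bivalent(cfg, rng)
    for ch in bv.chromatids:
        assert is_detectable([ch]) == ch.is_recombinant
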