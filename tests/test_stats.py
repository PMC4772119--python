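import math

import numpy as np
import pytest
from scipy import stats as sps

from tmdscan import (
    ProteinRecord,
    Topology,
    abundance_profile,
    compare_groups,
    detect,
    generate_group,
    group_summary,
    kldm,
    kldm_symmetric,
    length_distribution,
    mean_hydropathy_profile,
    profile_mode_length,
    rms_pm_difference,
    trim_zero_support,
    welch_ttest,
    windowed_profile,
)

# Published per-protein viral TMD lengths (animal-virus entry pathways and
# plant-virus replication sites) with their published group mean +- sd.
VIRAL_GROUPS = {
    "PM": ([30, 28, 30, 25], 28.25, 2.36),
    "CME": ([17, 5, 7, 15, 10], 10.80, 5.12),
    "MPE": ([8, 27, 20, 27, 19, 23], 20.67, 7.06),
    "CAME": ([10, 10, 25, 10], 13.75, 7.50),
    "ER": ([20, 20, 20, 20, 19, 20], 19.83, 0.41),
    "Mitochondria": ([20, 21, 21], 20.67, 0.58),
    "Peroxisome": ([21, 23, 21], 21.67, 1.15),
    "Chloroplast": ([11, 15], 13.00, 2.83),
}


class TestGroupSummary:
    @pytest.mark.parametrize("name", sorted(VIRAL_GROUPS))
    def test_published_viral_group_statistics(self, name):
        lengths, mean, sd = VIRAL_GROUPS[name]
        s = group_summary(lengths)
        assert round(s.mean, 2) == mean
        assert round(s.sd, 2) == sd
        assert s.n == len(lengths)

    def test_singleton_has_no_sd(self):
        s = group_summary([20])
        assert (s.mean, s.sd, s.n, s.mode) == (20.0, None, 1, 20)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            group_summary([])


class TestLengthDistribution:
    def test_counts_and_mode(self):
        d = length_distribution([20, 20, 21])
        assert d.counts == {20: 2, 21: 1}
        assert (d.mode, d.n) == (20, 3)

    def test_mode_tie_breaks_to_smallest(self):
        assert length_distribution([21, 20, 21, 20]).mode == 20

    def test_probabilities_sum_to_one(self, rng):
        sample = rng.integers(15, 30, size=1000).tolist()
        d = length_distribution(sample)
        assert sum(d.probabilities().values()) == pytest.approx(1.0, abs=1e-12)

    def test_counts_match_brute_force_tally(self, rng):
        sample = rng.integers(10, 35, size=1000).tolist()
        d = length_distribution(sample)
        for k in set(sample):
            assert d.counts[k] == sum(1 for v in sample if v == k)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            length_distribution([20.5])


def oracle_welch(x, y):
    """Textbook Welch statistic with Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


class TestWelch:
    def test_identical_samples(self):
        r = welch_ttest([20, 21, 22], [20, 21, 22])
        assert (r.t_stat, r.p_value) == (0.0, pytest.approx(1.0))

    def test_separated_samples_are_significant(self):
        r = welch_ttest([30, 30, 31, 29], [10, 10, 11, 9])
        assert r.p_value < 1e-3

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(24, 3, size=int(rng.integers(5, 40))).tolist()
            y = rng.normal(21, 4, size=int(rng.integers(5, 40))).tolist()
            r = welch_ttest(x, y)
            t, p = oracle_welch(x, y)
            assert r.t_stat == pytest.approx(t, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_swap_invariance(self, rng):
        x = rng.normal(24, 3, size=10).tolist()
        y = rng.normal(20, 2, size=12).tolist()
        a, b = welch_ttest(x, y), welch_ttest(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_zero_variance_equal_means(self):
        r = welch_ttest([20, 20, 20], [20, 20])
        assert (r.t_stat, r.p_value) == (0.0, 1.0)
        assert r.flag == "zero_variance_equal_means"

    def test_undersized_sample_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_ttest([20], [20, 21])


class TestKldm:
    def test_identical_distributions_give_zero(self):
        assert kldm([20, 20, 21], [20, 20, 21]) == 0.0
        assert kldm_symmetric([20, 20, 21], [20, 20, 21]) == 0.0

    def test_hand_evaluated_two_point_case(self):
        p1 = {10: 5, 11: 5}  # (0.5, 0.5)
        p2 = {10: 9, 11: 1}  # (0.9, 0.1)
        expected = 0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
        assert kldm(p1, p2) == pytest.approx(expected, abs=1e-12)
        assert kldm(p1, p2) != kldm(p2, p1)  # stated asymmetry

    def test_symmetric_version_averages_directions(self, rng):
        p1 = dict(zip(range(18, 25), rng.integers(1, 20, size=7).tolist()))
        p2 = dict(zip(range(18, 25), rng.integers(1, 20, size=7).tolist()))
        assert kldm_symmetric(p1, p2) == pytest.approx(
            0.5 * (kldm(p1, p2) + kldm(p2, p1)), abs=1e-12
        )
        assert kldm_symmetric(p1, p2) == pytest.approx(
            kldm_symmetric(p2, p1), abs=1e-12
        )

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(100):
            support = range(15, 15 + int(rng.integers(3, 10)))
            c1 = {k: int(rng.integers(1, 30)) for k in support}
            c2 = {k: int(rng.integers(1, 30)) for k in support}
            n1, n2 = sum(c1.values()), sum(c2.values())
            expected = sum(
                (c1[k] / n1) * math.log((c1[k] / n1) / (c2[k] / n2))
                for k in support
            )
            assert kldm(c1, c2) == pytest.approx(expected, abs=1e-9)

    def test_non_negativity_on_seeded_pairs(self, rng):
        for _ in range(200):
            support = range(10, 10 + int(rng.integers(2, 12)))
            c1 = {k: int(rng.integers(1, 50)) for k in support}
            c2 = {k: int(rng.integers(1, 50)) for k in support}
            assert kldm(c1, c2) >= 0.0

    def test_log_base_conversion(self):
        p1, p2 = {10: 5, 11: 5}, {10: 9, 11: 1}
        assert kldm(p1, p2, log_base=2) == pytest.approx(
            kldm(p1, p2) / math.log(2), abs=1e-12
        )

    def test_non_overlapping_supports_error(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            kldm({10: 3}, {20: 3})


class TestTrimZeroSupport:
    def test_common_support_kept(self):
        t1, t2, support = trim_zero_support(
            {10: 1, 11: 2, 12: 3}, {11: 1, 12: 1, 13: 1}
        )
        assert support == [11, 12]
        assert sum(t1.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(t2.values()) == pytest.approx(1.0, abs=1e-12)

    def test_identical_supports_unchanged(self):
        t1, t2, support = trim_zero_support({10: 2, 11: 2}, {10: 1, 11: 3})
        assert support == [10, 11]
        assert t1 == {10: 0.5, 11: 0.5}

    def test_renormalization_on_seeded_histograms(self, rng):
        for _ in range(50):
            c1 = {int(k): 1 + int(v) for k, v in
                  zip(rng.integers(8, 35, 10), rng.integers(0, 9, 10))}
            c2 = {int(k): 1 + int(v) for k, v in
                  zip(rng.integers(8, 35, 10), rng.integers(0, 9, 10))}
            if not set(c1) & set(c2):
                continue
            t1, t2, _ = trim_zero_support(c1, c2)
            assert sum(t1.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(t2.values()) == pytest.approx(1.0, abs=1e-12)


class TestAlignedProfiles:
    def detect_all(self, records, ges):
        return [detect(r, ges) for r in records]

    def test_single_record_equals_own_profile(self, ges):
        records, _ = generate_group(1, 22, 0, seed=3)
        tmds = self.detect_all(records, ges)
        prof = mean_hydropathy_profile(tmds, ges, window=5)
        own = windowed_profile(tmds[0].oriented_sequence, ges, window=5)
        assert np.allclose(prof.scores, own.scores)
        assert all(prof.coverage == 1)

    def test_identical_records_average_to_one_profile(self, ges):
        seq = "D" * 10 + "L" * 20 + "D" * 10
        recs = [
            ProteinRecord(f"p{i}", seq, "g", Topology.N_CYTO) for i in range(4)
        ]
        tmds = self.detect_all(recs, ges)
        prof = mean_hydropathy_profile(tmds, ges, window=5)
        own = windowed_profile(tmds[0].oriented_sequence, ges, window=5)
        assert np.allclose(prof.scores, own.scores)
        assert all(prof.coverage == 4)

    def test_matches_position_wise_oracle(self, ges):
        records, _ = generate_group(20, 22, 3, seed=11)
        tmds = self.detect_all(records, ges)
        prof = mean_hydropathy_profile(tmds, ges, window=3)
        # independent direct loop with coverage masking
        per_record = [
            windowed_profile(t.oriented_sequence, ges, window=3).scores
            for t in tmds
        ]
        for idx, pos in enumerate(prof.positions):
            vals = [p[pos - 1] for p in per_record if len(p) >= pos]
            assert prof.scores[idx] == pytest.approx(np.mean(vals), abs=1e-9)
            assert prof.coverage[idx] == len(vals)

    def test_mode_length_simple_profiles(self, ges):
        from tmdscan.stats import MeanProfile

        pos = np.arange(1, 31)
        scores = np.where(pos <= 22, 1.0, -1.0)
        prof = MeanProfile(pos, scores, np.ones_like(pos), 1)
        assert profile_mode_length(prof) == 22
        all_neg = MeanProfile(pos, -np.ones(30), np.ones_like(pos), 1)
        assert profile_mode_length(all_neg) == 0

    def test_mode_length_tracks_distribution_mode_not_mean(self, ges):
        # 70% of helices are 20 long; outliers at 15 and 25 pull the mean
        records = []
        for i, length in enumerate([20] * 14 + [15] * 2 + [25] * 4):
            from tmdscan import plant_tmd

            seq, _ = plant_tmd(length, 12, seed=100 + i, record_id=f"p{i}")
            records.append(ProteinRecord(f"p{i}", seq, "g", Topology.N_CYTO))
        tmds = self.detect_all(records, ges)
        prof = mean_hydropathy_profile(tmds, ges, window=1, extent=40)
        lengths = [t.length for t in tmds]
        assert profile_mode_length(prof) == 20
        assert profile_mode_length(prof) == length_distribution(lengths).mode
        assert np.mean(lengths) != 20

    def test_abundance_single_record_is_indicator(self, ges):
        rec = ProteinRecord("p", "D" * 10 + "L" * 18 + "D" * 10, "g", Topology.N_CYTO)
        df = abundance_profile([detect(rec, ges)], ges)
        assert set(df["L"]) == {1.0}
        assert set(df["hydrophobic"]) == {1.0}

    def test_abundance_columns_sum_to_one(self, ges):
        records, _ = generate_group(15, 22, 3, seed=5)
        tmds = self.detect_all(records, ges)
        df = abundance_profile(tmds, ges)
        residue_cols = [c for c in df.columns if c not in ("hydrophobic", "coverage")]
        assert np.allclose(df[residue_cols].sum(axis=1), 1.0, atol=1e-12)

    def test_abundance_matches_counting_oracle(self, ges):
        records, _ = generate_group(10, 20, 2, seed=9)
        tmds = self.detect_all(records, ges)
        df = abundance_profile(tmds, ges)
        seqs = [t.oriented_sequence for t in tmds]
        for pos in df.index[:10]:
            column = [s[pos - 1] for s in seqs if len(s) >= pos]
            for res in set(column):
                assert df.loc[pos, res] == pytest.approx(
                    column.count(res) / len(column), abs=1e-12
                )

    def test_empty_record_set_errors(self, ges):
        with pytest.raises(ValueError, match="no oriented"):
            mean_hydropathy_profile([], ges)


class TestRmsPmDifference:
    def test_zero_when_all_lengths_equal_pm_mean(self):
        pm = [("human", 24), ("human", 26), ("yeast", 22)]
        organelle = [("human", 25), ("yeast", 22)]
        assert rms_pm_difference(organelle, pm) == pytest.approx(0.0)

    def test_single_protein_gives_absolute_difference(self):
        assert rms_pm_difference([("h", 20)], [("h", 24)]) == pytest.approx(4.0)
        assert rms_pm_difference([("h", 28)], [("h", 24)]) == pytest.approx(4.0)

    def test_matches_direct_formula_oracle(self, rng):
        species = ["sp1", "sp2", "sp3"]
        pm = [(s, int(rng.integers(20, 30))) for s in species for _ in range(4)]
        organelle = [
            (species[int(rng.integers(0, 3))], int(rng.integers(15, 30)))
            for _ in range(20)
        ]
        pm_mean = {
            s: np.mean([l for sp, l in pm if sp == s]) for s in species
        }
        expected = math.sqrt(
            np.mean([(l - pm_mean[s]) ** 2 for s, l in organelle])
        )
        assert rms_pm_difference(organelle, pm) == pytest.approx(expected, abs=1e-9)

    def test_sum_variant(self):
        organelle = [("h", 20), ("h", 28)]
        pm = [("h", 24)]
        assert rms_pm_difference(organelle, pm, normalize=False) == pytest.approx(
            math.sqrt(32.0)
        )

    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="mars"):
            rms_pm_difference([("mars", 20)], [("earth", 24)])


class TestCompareGroups:
    def test_viral_pm_vs_cme(self):
        comp = compare_groups(VIRAL_GROUPS["PM"][0], VIRAL_GROUPS["CME"][0], "PM", "CME")
        assert round(comp.mean_x, 2) == 28.25
        assert round(comp.mean_y, 2) == 10.80
        assert comp.p_value < 0.01
        # these tiny groups share no length, so KLDM is undefined
        assert math.isnan(comp.kldm_sym)
        assert "non_overlapping" in comp.flag

    def test_overlapping_groups_report_kldm(self, rng):
        x = rng.integers(18, 26, size=40).tolist()
        y = rng.integers(20, 28, size=40).tolist()
        comp = compare_groups(x, y)
        assert comp.kldm_xy >= 0 and comp.kldm_yx >= 0
        assert comp.kldm_sym == pytest.approx(0.5 * (comp.kldm_xy + comp.kldm_yx))
        assert comp.trimmed_support

    def test_same_group_null_result(self):
        comp = compare_groups([20, 21, 20, 22], [20, 21, 20, 22])
        assert comp.p_value == pytest.approx(1.0)
        assert comp.kldm_sym == 0.0
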