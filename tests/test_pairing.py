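import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from nascent.pairing import (
    classify_ernas,
    closest_pairing,
    mrna_prefix_features,
    pair_correlations,
    pair_within_neighborhoods,
    permutation_test,
    replicate_averaged,
    temporal_profiles,
    tss,
    tss_metaprofile,
    upstream_window,
)
from nascent.simgen import (
    SimConfig,
    simulate_counts,
    simulate_trajectory_cohort,
    simulate_world,
)


def feat(rows):
    df = pd.DataFrame(rows)
    df.index = [r.get("id", f"f{i}") for i, r in enumerate(rows)]
    return df


class TestTssUpstream:
    def test_tss_strand_aware(self):
        f = feat([dict(chrom="chr1", start=100, end=200, strand="+"),
                  dict(chrom="chr1", start=100, end=200, strand="-")])
        assert list(tss(f)) == [100, 199]

    def test_upstream_window(self):
        f = feat([dict(chrom="chr1", start=5000, end=6000, strand="+"),
                  dict(chrom="chr1", start=5000, end=6000, strand="-")])
        u = upstream_window(f, 1000)
        assert (u.iloc[0]["start"], u.iloc[0]["end"]) == (4000, 5000)
        assert (u.iloc[1]["start"], u.iloc[1]["end"]) == (6000, 7000)


class TestClassifyErnas:
    def test_one_bp_upstream_overlap_counts(self):
        nc = feat([dict(chrom="chr1", start=5000, end=6000, strand="+")])
        states = pd.DataFrame([dict(chrom="chr1", start=3000, end=4001)])
        assert classify_ernas(nc, states).iloc[0]

    def test_no_overlap_stays_ncrna(self):
        nc = feat([dict(chrom="chr1", start=5000, end=6000, strand="+")])
        states = pd.DataFrame([dict(chrom="chr1", start=3000, end=4000)])
        assert not classify_ernas(nc, states).iloc[0]

    def test_readthrough_excluded(self):
        nc = feat([dict(chrom="chr1", start=5000, end=6000, strand="+",
                        readthrough=True)])
        states = pd.DataFrame([dict(chrom="chr1", start=5000, end=6000)])
        assert not classify_ernas(nc, states).iloc[0]

    def test_simulated_recovery(self, small_world):
        tx = small_world.truth.transcripts
        nc_like = tx[tx["cls"].isin(["ncRNA", "eRNA"])]
        flags = classify_ernas(nc_like, small_world.enhancer_states)
        planted = nc_like["cls"] == "eRNA"
        recovery = flags[planted].mean()
        assert recovery >= 0.95


class TestPairWithinNeighborhoods:
    NB = pd.DataFrame([dict(chrom="chr1", start=0, end=100_000)],
                      index=pd.Index(["nb0"], name="id"))

    def test_enumeration(self):
        ernas = feat([dict(id="e1", chrom="chr1", start=10_000, end=10_500,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="+"),
                      dict(id="m2", chrom="chr1", start=90_000, end=95_000,
                           strand="+")])
        pairs = pair_within_neighborhoods(ernas, mrnas, self.NB)
        assert len(pairs) == 2

    def test_exclusion_zone(self):
        ernas = feat([dict(id="e1", chrom="chr1", start=50_500, end=51_000,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="+")])
        pairs = pair_within_neighborhoods(ernas, mrnas, self.NB)
        assert len(pairs) == 0

    def test_different_neighborhoods_no_pair(self):
        nb = pd.DataFrame([dict(chrom="chr1", start=0, end=40_000),
                           dict(chrom="chr1", start=40_000, end=100_000)],
                          index=pd.Index(["nb0", "nb1"], name="id"))
        ernas = feat([dict(id="e1", chrom="chr1", start=10_000, end=10_500,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="+")])
        assert len(pair_within_neighborhoods(ernas, mrnas, nb)) == 0

    def test_signed_distance_orientation(self):
        ernas = feat([dict(id="e1", chrom="chr1", start=10_000, end=10_500,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="-")])
        pairs = pair_within_neighborhoods(ernas, mrnas, self.NB)
        # eRNA is upstream of a minus-strand promoter at 59,999 -> positive
        # TSS delta, negated by orientation -> negative means upstream? the
        # eRNA lies 5' of the promoter in mRNA orientation -> sign is +
        assert pairs.iloc[0]["tss_distance"] == -(10_000 - 59_999)

    def test_overlapping_neighborhoods_dedup(self):
        nb = pd.DataFrame([dict(chrom="chr1", start=0, end=100_000),
                           dict(chrom="chr1", start=0, end=90_000)],
                          index=pd.Index(["nbA", "nbB"], name="id"))
        ernas = feat([dict(id="e1", chrom="chr1", start=10_000, end=10_500,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="+")])
        pairs = pair_within_neighborhoods(ernas, mrnas, nb)
        assert len(pairs) == 1

    def test_proximal_flag(self):
        ernas = feat([dict(id="e1", chrom="chr1", start=45_000, end=45_400,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=60_000,
                           strand="+")])
        pairs = pair_within_neighborhoods(ernas, mrnas, self.NB)
        assert pairs.iloc[0]["proximal"]


class TestPairCorrelations:
    def _pairs(self):
        return pd.DataFrame([dict(erna_id="e", mrna_id="m")])

    def test_identical_profiles(self):
        ts = pd.DataFrame({0: [1, 1], 5: [2, 2], 10: [3, 3], 15: [4, 4]},
                          index=["e", "m"]).astype(float)
        out = pair_correlations(self._pairs(), ts)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        ts = pd.DataFrame({0: [1, 4], 5: [2, 3], 10: [3, 2], 15: [4, 1]},
                          index=["e", "m"]).astype(float)
        out = pair_correlations(self._pairs(), ts)
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_constant_flagged(self):
        ts = pd.DataFrame({0: [1, 2], 5: [1, 3], 10: [1, 4], 15: [1, 5]},
                          index=["e", "m"]).astype(float)
        out = pair_correlations(self._pairs(), ts)
        assert np.isnan(out.iloc[0]["r"]) and out.iloc[0]["flags"] == "constant"

    def test_too_few_time_points(self):
        ts = pd.DataFrame({0: [1, 2], 5: [2, 3]}, index=["e", "m"])
        with pytest.raises(ValueError):
            pair_correlations(self._pairs(), ts)

    def test_simulated_rho(self):
        ts, pairs = simulate_trajectory_cohort(300, 0, 0.8, seed=12)
        out = pair_correlations(pairs, ts)
        assert 0.6 <= out["r"].median() <= 0.95


class TestPermutationTest:
    def test_strong_coregulation_min_p(self):
        ts, pairs = simulate_trajectory_cohort(200, 500, 0.8, seed=11)
        obs, null, p = permutation_test(pairs, ts, n_perm=1000, seed=5)
        assert obs > null.max()
        assert p == pytest.approx(1 / 1001)

    def test_shared_profile_p_near_one(self):
        tps = [0, 5, 10, 15]
        base = np.array([1.0, 2.0, 3.0, 4.0])
        rows = {f"e{i}": base for i in range(10)}
        rows.update({f"m{i}": base for i in range(10)})
        ts = pd.DataFrame.from_dict(rows, orient="index", columns=tps)
        pairs = pd.DataFrame([dict(erna_id=f"e{i}", mrna_id=f"m{i}")
                              for i in range(10)])
        obs, null, p = permutation_test(pairs, ts, n_perm=200, seed=1)
        assert p > 0.5

    def test_deterministic_null(self):
        ts, pairs = simulate_trajectory_cohort(50, 50, 0.8, seed=2)
        _, n1, p1 = permutation_test(pairs, ts, n_perm=100, seed=9)
        _, n2, p2 = permutation_test(pairs, ts, n_perm=100, seed=9)
        assert np.array_equal(n1, n2) and p1 == p2

    def test_relabeling_invariance(self):
        ts, pairs = simulate_trajectory_cohort(50, 50, 0.8, seed=2)
        mapping = {fid: f"x_{fid}" for fid in ts.index}
        ts2 = ts.rename(index=mapping)
        pairs2 = pairs.assign(erna_id=pairs["erna_id"].map(mapping),
                              mrna_id=pairs["mrna_id"].map(mapping))
        _, _, p1 = permutation_test(pairs, ts, n_perm=200, seed=3)
        _, _, p2 = permutation_test(pairs2, ts2, n_perm=200, seed=3)
        assert p1 == p2

    def test_bad_args(self):
        ts, pairs = simulate_trajectory_cohort(5, 0, 0.8, seed=2)
        with pytest.raises(ValueError):
            permutation_test(pairs, ts, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(pairs.iloc[:1], ts, n_perm=10)


class TestClosestPairing:
    NB = pd.DataFrame([dict(chrom="chr1", start=0, end=100_000)],
                      index=pd.Index(["nb0"], name="id"))

    def test_single_erna_pairs_all(self):
        ernas = feat([dict(id="e1", chrom="chr1", start=10_000, end=10_400,
                           strand="+")])
        mrnas = feat([dict(id=f"m{i}", chrom="chr1", start=20_000 * (i + 1),
                           end=20_000 * (i + 1) + 5_000, strand="+")
                      for i in range(3)])
        pairs, _ = closest_pairing(ernas, mrnas, self.NB)
        assert set(pairs["erna_id"]) == {"e1"} and len(pairs) == 3

    def test_tie_breaks_to_smaller_coordinate(self):
        ernas = feat([dict(id="eL", chrom="chr1", start=40_000, end=40_400,
                           strand="+"),
                      dict(id="eR", chrom="chr1", start=60_000, end=60_400,
                           strand="+")])
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=55_000,
                           strand="+")])
        # distances: |40000-50000| = 10000, |60000-50000| = 10000 -> tie
        pairs, _ = closest_pairing(ernas, mrnas, self.NB)
        assert pairs.iloc[0]["erna_id"] == "eL"

    def test_empty_ernas_warns(self):
        mrnas = feat([dict(id="m1", chrom="chr1", start=50_000, end=55_000,
                           strand="+")])
        with pytest.warns(UserWarning):
            pairs, diag = closest_pairing(mrnas.iloc[0:0], mrnas, self.NB)
        assert len(pairs) == 0


@pytest.fixture(scope="module")
def world_and_ts():
    cfg = SimConfig.small(distance_decay=60_000.0)
    w = simulate_world(cfg, seed=21)
    sc = simulate_counts(w, seed=22)
    ts = replicate_averaged(sc.counts, sc.samples, assay="TT")
    return w, ts


class TestWorldPairing:
    """Simulation-backed discrimination properties."""

    def test_true_pairs_beat_shuffled(self, world_and_ts):
        w, ts = world_and_ts
        pairs = w.truth.pairs
        rs = pair_correlations(pairs, ts)["r"].dropna()
        rng = np.random.default_rng(0)
        shuffled = pairs.assign(
            mrna_id=rng.permutation(pairs["mrna_id"].to_numpy()))
        rs_null = pair_correlations(shuffled, ts)["r"].dropna()
        assert mannwhitneyu(rs, rs_null, alternative="greater").pvalue < 0.01

    def test_proximal_ge_distal_median_r(self, world_and_ts):
        w, ts = world_and_ts
        pairs = w.truth.pairs.copy()
        out = pair_correlations(pairs, ts)
        prox = out[out["distance"] < 10_000]["r"].dropna()
        dist = out[out["distance"] >= 10_000]["r"].dropna()
        assert len(prox) >= 3 and len(dist) >= 3
        assert prox.median() >= dist.median()

    def test_closest_same_neighborhood_higher_r(self):
        # sparse neighborhoods: many closest pairs cross boundaries, giving a
        # sizable different-neighborhood group
        cfg = SimConfig.small(n_neighborhoods=8,
                              neighborhood_size=(80_000, 120_000),
                              neighborhood_gap=180_000)
        w = simulate_world(cfg, seed=31)
        sc = simulate_counts(w, seed=32)
        ts = replicate_averaged(sc.counts, sc.samples, assay="TT")
        tx = w.truth.transcripts
        ernas = tx[tx["cls"] == "eRNA"]
        mrnas = tx[tx["cls"] == "mRNA"]
        pairs, diag = closest_pairing(ernas, mrnas, w.neighborhoods, ts)
        assert diag["median_r_same"] > diag["median_r_diff"]
        assert diag["same_vs_diff_neighborhood_p"] < 0.05


@pytest.fixture(scope="module")
def up_world():
    cfg = SimConfig.small(
        frac_pairs_up=1.0, frac_pairs_down=0.0, traj_noise_sd=0.15,
        half_life_ranges=(("mRNA", (60.0, 200.0)),
                          ("lincRNA", (20.0, 100.0)),
                          ("ncRNA", (5.0, 60.0)), ("eRNA", (2.0, 10.0))))
    w = simulate_world(cfg, seed=4)
    sc = simulate_counts(w, seed=5)
    return w, sc


class TestTemporalProfiles:

    def _medians(self, w, sc, pairs, assay):
        sf = pd.Series(1.0, index=sc.samples.index)
        prof = temporal_profiles(pairs, sc.tracks, w.truth.transcripts,
                                 sc.samples, sf, assay=assay)
        return {role: prof[prof["role"] == role].set_index("time")["median"]
                for role in ("eRNA", "mRNA")}

    def test_simultaneous_rise_in_tt(self, up_world):
        w, sc = up_world
        pairs = w.truth.pairs[w.truth.pairs["pattern"] == "up"]
        med = self._medians(w, sc, pairs, "TT")
        for role in ("eRNA", "mRNA"):
            m = med[role]
            assert m[5] > m[0] * 1.5  # rise already at the first time point

    def test_downregulated_pairs_fall(self):
        cfg = SimConfig.small(frac_pairs_up=0.0, frac_pairs_down=1.0,
                              traj_noise_sd=0.15)
        w = simulate_world(cfg, seed=6)
        sc = simulate_counts(w, seed=7)
        pairs = w.truth.pairs[w.truth.pairs["pattern"] == "down"]
        sf = pd.Series(1.0, index=sc.samples.index)
        prof = temporal_profiles(pairs, sc.tracks, w.truth.transcripts,
                                 sc.samples, sf, assay="TT")
        for role in ("eRNA", "mRNA"):
            m = prof[prof["role"] == role].set_index("time")["median"]
            assert m[15] < m[0]

    def test_flat_pairs_flat(self):
        cfg = SimConfig.small(frac_pairs_up=0.0, frac_pairs_down=0.0,
                              traj_noise_sd=0.1)
        w = simulate_world(cfg, seed=8)
        sc = simulate_counts(w, seed=9)
        pairs = w.truth.pairs
        sf = pd.Series(1.0, index=sc.samples.index)
        prof = temporal_profiles(pairs, sc.tracks, w.truth.transcripts,
                                 sc.samples, sf, assay="TT")
        med = prof[prof["role"] == "mRNA"].set_index("time")["median"]
        assert med.max() / med.min() < 1.6

    def test_short_mrna_prefix_flagged(self):
        f = feat([dict(id="m1", chrom="chr1", start=0, end=1_000,
                       strand="+")])
        out = mrna_prefix_features(f, 2_200)
        assert out.iloc[0]["prefix_flagged"]
        assert out.iloc[0]["end"] == 1_000


class TestTssMetaprofile:
    def test_constant_signal_flat(self):
        sig = {"chr1": np.full(10_000, 7.0)}
        f = feat([dict(chrom="chr1", start=5_000, end=6_000, strand="+")])
        prof = tss_metaprofile(sig, f, window=100)
        assert np.allclose(prof, 7.0)

    def test_orientation(self):
        sig = {"chr1": np.zeros(10_000)}
        sig["chr1"][4_900:4_950] = 10.0  # peak upstream of a + TSS at 5000
        plus = feat([dict(id="p", chrom="chr1", start=5_000, end=6_000,
                          strand="+")])
        minus = feat([dict(id="m", chrom="chr1", start=4_000, end=5_001,
                           strand="-")])  # TSS at 5000, upstream is right
        prof_p = tss_metaprofile(sig, plus, window=200)
        assert prof_p[:200].sum() > 0 and np.allclose(prof_p[200:], 0)
        sig2 = {"chr1": np.zeros(10_000)}
        sig2["chr1"][5_050:5_100] = 10.0  # genomic right = upstream of minus
        prof_m = tss_metaprofile(sig2, minus, window=200)
        assert prof_m[:200].sum() > 0 and np.allclose(prof_m[200:], 0)

    def test_single_tss_equals_local_signal(self):
        rng = np.random.default_rng(1)
        sig = {"chr1": rng.uniform(0, 1, 10_000)}
        f = feat([dict(chrom="chr1", start=5_000, end=6_000, strand="+")])
        prof = tss_metaprofile(sig, f, window=50)
        assert np.allclose(prof, sig["chr1"][4_950:5_050])

    def test_empty_tss_set_errors(self):
        with pytest.raises(ValueError):
            tss_metaprofile({"chr1": np.zeros(10)}, feat([]).reindex([]),
                            window=5)
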