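"""Forward PRE model, restraint energy, ensemble fitting and scan summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fuzzyfit as ff
from fuzzyfit.ensemble import (EnsembleFitConfig, EnsembleModel, Pose,
                               PREForwardParams, SizeScanResult, _box_stats,
                               back_calculate_pre, place_spin_label,
                               pre_energy, summarize_energies)
from fuzzyfit.nmr_io import Structure
from fuzzyfit.pre import PREProfile, SpinLabelSite
from fuzzyfit.simulate import SyntheticTruth, ideal_helix
from conftest import profiles_for

SITE = SpinLabelSite(label_id="L1", attachment_residue=1)


def _mini_structure(atoms):
    """atoms: list of (name, residue, x, y, z)."""
    rows = [(i + 1, a[0], a[1], "A", "A", a[2], a[3], a[4])
            for i, a in enumerate(atoms)]
    cols = ["serial", "atom_name", "residue_index", "residue_type", "chain",
            "x", "y", "z"]
    return Structure(pd.DataFrame(rows, columns=cols))


class TestSpinLabelPlacement:
    def test_along_ca_cb_direction(self):
        st = _mini_structure([("CA", 1, 0, 0, 0), ("CB", 1, 1.5, 0, 0)])
        np.testing.assert_allclose(place_spin_label(st, SITE), [7.5, 0, 0], atol=1e-12)

    def test_zero_offset_coincides_with_cb(self):
        st = _mini_structure([("CA", 1, 0, 0, 0), ("CB", 1, 1.5, 0, 0)])
        np.testing.assert_allclose(place_spin_label(st, SITE, offset=0.0),
                                   [1.5, 0, 0], atol=1e-12)

    def test_gly_fallback_uses_local_frame(self):
        st = _mini_structure([("N", 1, -1.0, 1.0, 0), ("CA", 1, 0, 0, 0),
                              ("C", 1, 1.0, 1.0, 0)])
        pos = place_spin_label(st, SITE, offset=6.0)
        np.testing.assert_allclose(pos, [0, -6.0, 0], atol=1e-9)

    def test_absent_residue_raises(self):
        st = _mini_structure([("CA", 2, 0, 0, 0), ("CB", 2, 1.5, 0, 0)])
        with pytest.raises(KeyError):
            place_spin_label(st, SITE)


def _partner_line(distances):
    """Partner with one N atom per residue at the given x distances."""
    return _mini_structure([("N", i + 1, d, 0.0, 0.0)
                            for i, d in enumerate(distances)])


LIGAND_AT_ORIGIN = _mini_structure([("CA", 1, -1.5, 0, 0), ("CB", 1, -7.5, 0, 0)])
# label local position: CB + 6 A along CA->CB = (-13.5, 0, 0); identity pose
# below shifts it to the origin for easy distance bookkeeping
IDENTITY = Pose(np.eye(3), np.array([13.5, 0.0, 0.0]))


class TestForwardModel:
    def test_two_member_hand_value(self):
        params = PREForwardParams()  # tau_c 8 ns, 500 MHz, t 10 ms, R2dia 20/s
        partner = _partner_line([12.0])
        prof = back_calculate_pre(partner, LIGAND_AT_ORIGIN,
                                  [IDENTITY, Pose(np.eye(3), [55.5, 0, 0])],
                                  SITE, params)
        # independent hand evaluation of the forward formula
        tau = 8e-9
        omega = 2 * np.pi * 500e6
        j = 4 * tau + 3 * tau / (1 + (omega * tau) ** 2)
        r6 = (12.0 ** -6 + 30.0 ** -6) / 2
        gamma2 = 1.23e16 * j * r6
        expected = 20.0 * np.exp(-gamma2 * 0.010) / (20.0 + gamma2)
        assert prof.data["ratio"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1195, abs=2e-4)

    def test_identical_members_equal_single_state(self):
        partner = _partner_line([10.0, 15.0, 25.0])
        single = back_calculate_pre(partner, LIGAND_AT_ORIGIN, [IDENTITY], SITE)
        triple = back_calculate_pre(partner, LIGAND_AT_ORIGIN, [IDENTITY] * 3, SITE)
        np.testing.assert_allclose(single.data["ratio"], triple.data["ratio"], rtol=1e-12)

    def test_far_atom_ratio_approaches_one(self):
        partner = _partner_line([1e5])
        prof = back_calculate_pre(partner, LIGAND_AT_ORIGIN, [IDENTITY], SITE)
        assert prof.data["ratio"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_ratio_monotone_in_distance(self):
        d = np.linspace(8, 60, 40)
        prof = back_calculate_pre(_partner_line(d), LIGAND_AT_ORIGIN, [IDENTITY], SITE)
        ratios = prof.data.sort_values("residue_index")["ratio"].to_numpy()
        assert np.all(np.diff(ratios) > 0)

    def test_r6_average_matches_brute_force(self, rng):
        members = [Pose(np.eye(3), [13.5 + t, 0, 0]) for t in (0.0, 7.0, 19.0)]
        dists = rng.uniform(9, 40, size=25)
        prof = back_calculate_pre(_partner_line(dists), LIGAND_AT_ORIGIN,
                                  members, SITE)
        params = PREForwardParams()
        for row, d0 in zip(prof.data.sort_values("residue_index").itertuples(),
                           dists):
            r6 = sum(abs(d0 - t) ** -6 for t in (0.0, 7.0, 19.0)) / 3.0
            assert row.ratio == pytest.approx(float(params.ratio_from_r6inv(r6)),
                                              rel=1e-12)

    def test_saturation_mixing(self):
        partner = _partner_line([12.0])
        bound = back_calculate_pre(partner, LIGAND_AT_ORIGIN, [IDENTITY], SITE,
                                   saturation=1.0).data["ratio"].iloc[0]
        mixed = back_calculate_pre(partner, LIGAND_AT_ORIGIN, [IDENTITY], SITE,
                                   saturation=0.6).data["ratio"].iloc[0]
        assert mixed == pytest.approx(0.6 * bound + 0.4, rel=1e-12)


def _obs_profile(r2_values, errs, bleached=None):
    n = len(r2_values)
    df = pd.DataFrame({
        "residue_index": np.arange(1, n + 1),
        "atom_pair": "HN-N",
        "ratio": 1.0 / (np.asarray(r2_values) + 1.0),
        "ratio_err": 0.0,
        "r2_star": r2_values,
        "r2_star_err": errs,
        "bleached": bleached if bleached is not None else [False] * n,
    })
    return PREProfile(data=df, label=SITE)


class TestPREEnergy:
    def test_identity_is_zero_and_nonnegative(self):
        obs = _obs_profile([1.0, 2.0, 0.5, 3.0, 1.5], [0.1] * 5)
        assert pre_energy(obs, obs) == pytest.approx(0.0)

    def test_one_sigma_residual_scores_one(self):
        obs = _obs_profile([1.0, 2.0, 0.5, 3.0, 1.5], [0.1] * 5)
        pred = _obs_profile([1.1, 2.0, 0.5, 3.0, 1.5], [0.0] * 5)
        assert pre_energy(pred, obs) == pytest.approx(1.0)

    def test_matches_brute_force_sum(self, rng):
        r2o = rng.uniform(0, 5, 12)
        r2p = rng.uniform(0, 5, 12)
        errs = rng.uniform(0.05, 0.5, 12)
        got = pre_energy(_obs_profile(r2p, [0.0] * 12), _obs_profile(r2o, errs))
        expected = sum(((a - b) / s) ** 2 for a, b, s in zip(r2p, r2o, errs))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bleached_one_sided(self):
        obs = _obs_profile([2.0] * 5, [0.5] * 5, bleached=[True] + [False] * 4)
        over = _obs_profile([4.0, 2.0, 2.0, 2.0, 2.0], [0.0] * 5)
        under = _obs_profile([1.0, 2.0, 2.0, 2.0, 2.0], [0.0] * 5)
        assert pre_energy(over, obs) == pytest.approx(0.0)  # stronger PRE ok
        assert pre_energy(under, obs) == pytest.approx(4.0)

    def test_requires_five_matches(self):
        obs = _obs_profile([1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            pre_energy(obs, obs)


class TestBoxStats:
    def test_quantiles_one_to_nine(self):
        s = _box_stats(np.arange(1.0, 10.0))
        assert s["median"] == pytest.approx(5.0)
        assert s["q25"] == pytest.approx(3.0)  # linear interpolation rule
        assert s["q75"] == pytest.approx(7.0)
        assert s["n_outliers"] == 0

    def test_all_equal_zero_width_box(self):
        s = _box_stats(np.full(10, 2.5))
        assert s["q25"] == s["median"] == s["q75"] == pytest.approx(2.5)
        assert s["whisker_lo"] == s["whisker_hi"] == pytest.approx(2.5)
        assert s["n_outliers"] == 0

    def test_matches_sorting_oracle(self, rng):
        for _ in range(200):
            v = rng.normal(size=int(rng.integers(5, 60)))
            s = _box_stats(v)
            # independent oracle via numpy sorting + quantile
            q25, med, q75 = np.quantile(np.sort(v), [0.25, 0.5, 0.75])
            iqr = q75 - q25
            assert s["median"] == pytest.approx(med)
            assert s["q25"] == pytest.approx(q25)
            assert s["q75"] == pytest.approx(q75)
            inside = v[(v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)]
            assert s["whisker_lo"] == pytest.approx(inside.min())
            assert s["whisker_hi"] == pytest.approx(inside.max())
            assert s["n_outliers"] == int(
                np.sum((v < med - 1.5 * iqr) | (v > med + 1.5 * iqr)))


class TestFitting:
    def test_same_seed_is_deterministic(self, three_state_model):
        a = three_state_model.fit(2, seed=99)
        b = three_state_model.fit(2, seed=99)
        assert a.pre_energy == b.pre_energy
        for pa, pb in zip(a.members, b.members):
            np.testing.assert_array_equal(pa.rotation, pb.rotation)
            np.testing.assert_array_equal(pa.translation, pb.translation)

    def test_single_state_truth_recovered(self):
        truth = SyntheticTruth(seed=21, true_n_states=1)
        profs = profiles_for(truth)
        model = ff.PREEnsembleModel(profs, truth.partner, truth.ligand,
                                    truth.forward_params)
        fits = [model.fit(1, seed=300 + s) for s in range(4)]
        best = min(fits, key=lambda m: m.pre_energy)
        assert best.pre_energy <= 2.0 * model._ev.n_restraints
        for site, sat in zip(truth.label_sites, truth.saturations):
            true_prof = back_calculate_pre(truth.partner, truth.ligand,
                                           truth.true_poses, site,
                                           truth.forward_params, saturation=sat)
            fit_prof = back_calculate_pre(truth.partner, truth.ligand,
                                          best.members, site,
                                          truth.forward_params, saturation=sat)
            r, _ = stats.pearsonr(true_prof.data["ratio"], fit_prof.data["ratio"])
            assert r > 0.95

    def test_single_state_cannot_satisfy_three_state_truth(self, three_state_model):
        fits = [three_state_model.fit(1, seed=400 + s) for s in range(4)]
        best = min(fits, key=lambda m: m.pre_energy)
        assert best.pre_energy > 2.0 * three_state_model._ev.n_restraints

    def test_two_state_fit_recapitulates_two_state_truth(self):
        """Data-pattern recovery; member coordinates themselves are degenerate."""
        truth = SyntheticTruth(seed=21, true_n_states=2)
        profs = profiles_for(truth)
        model = ff.PREEnsembleModel(profs, truth.partner, truth.ligand,
                                    truth.forward_params)
        fits = [model.fit(2, seed=500 + s) for s in range(5)]
        best = min(fits, key=lambda m: m.pre_energy)
        assert best.pre_energy <= 2.0 * model._ev.n_restraints
        for site, sat in zip(truth.label_sites, truth.saturations):
            true_prof = back_calculate_pre(truth.partner, truth.ligand,
                                           truth.true_poses, site,
                                           truth.forward_params, saturation=sat)
            fit_prof = back_calculate_pre(truth.partner, truth.ligand,
                                          best.members, site,
                                          truth.forward_params, saturation=sat)
            r, _ = stats.pearsonr(true_prof.data["ratio"], fit_prof.data["ratio"])
            assert r > 0.95

    def test_invalid_sizes_rejected(self, three_state_model):
        with pytest.raises(ValueError):
            three_state_model.fit(0, seed=1)
        with pytest.raises(ValueError):
            three_state_model.fit(7, seed=1)


class TestScan:
    def test_energy_medians_non_increasing_with_size(self, three_state_scan):
        med = three_state_scan.summary.query("term == 'pre_ten_lowest'") \
            .set_index("n_states")["median"]
        sizes = sorted(med.index)
        for a, b in zip(sizes, sizes[1:]):
            assert med[b] <= 1.15 * med[a]  # Monte-Carlo tolerance

    def test_summary_table_fields(self, three_state_scan):
        table = summarize_energies(three_state_scan)
        assert set(table["term"]) == {"total", "pre", "pre_ten_lowest"}
        assert set(table.columns) >= {"n_states", "median", "q25", "q75",
                                      "whisker_lo", "whisker_hi", "n_outliers"}
        assert (table.query("term == 'pre'")["n"] == 40).all()

    def test_weights_equal_and_energies_finite(self, three_state_scan):
        for size, fits in three_state_scan.models.items():
            for m in fits:
                np.testing.assert_allclose(m.weights, 1.0 / size)
                assert m.pre_energy >= 0 and m.clash_energy >= 0

    def test_replicate_minimum(self, three_state_model):
        with pytest.raises(ValueError):
            three_state_model.size_scan(sizes=[1], replicates=1)
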