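"""The synthetic study generator: composition, determinism, round trips."""

import json

import numpy as np
import pytest

from iminoex.catalyst import base_form_concentration
from iminoex.core_model import intensity_ratio
from iminoex.fitting import fit_inversion_recovery, monte_carlo_kex
from iminoex.synthetic_data import (
    DEFAULT_DELAYS_ACQ_ORDER,
    GroundTruth,
    ResidueTruth,
    default_hprna20_truth,
    generate_recovery_series,
    generate_study,
    generate_transfer_series,
    saturation_params_from_two_points,
)


def noiseless(truth):
    from dataclasses import replace

    return replace(truth, noise_sd_invitro=0.0, noise_sd_incell=0.0)


class TestTruthConstruction:
    def test_two_point_inversion_reproduces_published_rates(self, truth):
        # the generating (k_open, k_close) must hit the published k_ex at
        # both the 10 mM and 300 mM total-catalyst points
        b10 = base_form_concentration(truth.buffers[0])
        b300 = base_form_concentration(truth.buffers[1])
        rt = truth.residues["U14"]
        assert rt.kex_at(b10) == pytest.approx(6.7, rel=1e-10)
        assert rt.kex_at(b300) == pytest.approx(34.5, rel=1e-10)

    def test_inconsistent_points_rejected(self):
        with pytest.raises(ValueError):
            saturation_params_from_two_points(10.0, 5.0, 100.0, 60.0)


class TestTransferSeries:
    def test_noiseless_series_matches_closed_form_exactly(self, truth):
        t = noiseless(truth)
        buf = t.buffers[1]
        s = generate_transfer_series(t, "G19", buf)
        kex = t.residues["G19"].kex_at(base_form_concentration(buf))
        expected = t.I0 * intensity_ratio(s.delays, kex, t.apparent_rates(kex))
        assert np.array_equal(s.intensities, expected)

    def test_delays_stored_ascending_with_scrambled_acquisition(self, truth):
        s = generate_transfer_series(truth, "G4", truth.buffers[0])
        assert np.all(np.diff(s.delays) > 0)
        # recorded order was 0.1, 0.001, 0.01, 0.06, 0.03
        recorded = s.delays[np.argsort(s.acquisition_order)]
        assert tuple(recorded) == DEFAULT_DELAYS_ACQ_ORDER

    def test_fixed_seed_reproducible(self, truth):
        a = generate_transfer_series(truth, "G4", truth.buffers[0],
                                     rng=np.random.default_rng(5))
        b = generate_transfer_series(truth, "G4", truth.buffers[0],
                                     rng=np.random.default_rng(5))
        assert np.array_equal(a.intensities, b.intensities)

    def test_saturated_top_point_plateaus_at_k_open(self):
        truth = GroundTruth(
            residues={"X": ResidueTruth(k_open=9.0, k_close=2.0, k_B=5.0, kex_incell=1.0)},
            buffers=default_hprna20_truth().buffers,
            noise_sd_invitro=0.0,
        )
        buf = truth.buffers[1]  # k_B*[B] >> k_close here
        s = generate_transfer_series(truth, "X", buf)
        kex = truth.residues["X"].kex_at(base_form_concentration(buf))
        res = monte_carlo_kex(s, truth.apparent_rates(kex), seed=0)
        assert res.kex_point == pytest.approx(kex, rel=1e-6)
        assert kex == pytest.approx(9.0, rel=0.01)

    def test_incell_series_respects_opening_bound(self, truth):
        # fitted in-cell k_ex stays below generating k_open + 3 MC sd
        rng = np.random.default_rng(11)
        violations = 0
        for i in range(50):
            name = list(truth.residues)[i % 5]
            s = generate_transfer_series(truth, name, condition="in_cell", rng=rng)
            kex = truth.residues[name].kex_incell
            res = monte_carlo_kex(s, truth.apparent_rates(kex), n_mc=25, seed=rng)
            bound = truth.residues[name].k_open_incell_effective
            if res.kex_mean > bound + 3 * res.kex_sd:
                violations += 1
        assert violations == 0

    def test_noise_realizations_uncorrelated(self, truth):
        # pooled lag-1 autocorrelation of the noise consistent with zero
        rng = np.random.default_rng(3)
        resid = []
        t0 = noiseless(truth)
        for i in range(200):
            name = list(truth.residues)[i % 5]
            buf = truth.buffers[i % 2]
            noisy = generate_transfer_series(truth, name, buf, rng=rng)
            clean = generate_transfer_series(t0, name, buf)
            resid.extend(noisy.intensities - clean.intensities)
        resid = np.asarray(resid)
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(r1) < 3.0 / np.sqrt(len(resid))


class TestRecoverySeries:
    def test_noiseless_round_trip(self, truth):
        t = noiseless(truth)
        s = generate_recovery_series(t, "inversion", residue="G4", buffer=t.buffers[0])
        kex = t.residues["G4"].kex_at(base_form_concentration(t.buffers[0]))
        fit, _ = fit_inversion_recovery(s)
        assert fit == pytest.approx(t.R1a_intrinsic + kex, rel=1e-6)

    def test_seeded_determinism(self, truth):
        a = generate_recovery_series(truth, "saturation", rng=np.random.default_rng(2))
        b = generate_recovery_series(truth, "saturation", rng=np.random.default_rng(2))
        assert np.array_equal(a.intensities, b.intensities)

    def test_noisy_recovery_covered_by_two_stderr(self, truth):
        # at default noise the fitted R1 should sit within 2 stderr of the
        # generating value for the large majority of noise realisations
        kex = truth.residues["G4"].kex_at(base_form_concentration(truth.buffers[0]))
        r1_true = truth.R1a_intrinsic + kex
        covered = 0
        for seed in range(10):
            s = generate_recovery_series(
                truth, "inversion", residue="G4", buffer=truth.buffers[0],
                rng=np.random.default_rng(seed),
            )
            fit, err = fit_inversion_recovery(s)
            if abs(fit - r1_true) <= 2 * err:
                covered += 1
        assert covered >= 7

    def test_unknown_kind_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_recovery_series(truth, "progressive")


class TestStudyBundle:
    def test_default_bundle_layout(self, truth, tmp_path):
        manifest = generate_study(truth, tmp_path)
        assert set(manifest["residues"]) == {"G4", "U14", "G15", "U18", "G19"}
        for name in ("transfer.tsv", "recovery.tsv", "config.json", "manifest.json"):
            assert (tmp_path / name).exists()
        with open(tmp_path / "config.json") as fh:
            cfg = json.load(fh)
        # two in-vitro titration points plus the in-cell condition
        assert len(cfg["conditions"]) == 3

    def test_empty_truth_yields_valid_empty_bundle(self, tmp_path):
        truth = GroundTruth(residues={}, buffers=())
        generate_study(truth, tmp_path)
        from iminoex.interface import read_intensity_table

        assert read_intensity_table(tmp_path / "transfer.tsv") == []

    def test_bundle_round_trips_losslessly(self, truth, tmp_path):
        from iminoex.interface import read_config, read_intensity_table

        generate_study(truth, tmp_path)
        cfg = read_config(tmp_path / "config.json")
        series = read_intensity_table(tmp_path / "transfer.tsv", cfg)
        assert len(series) == 5 * 3
        # regenerate the first series with the same stream position
        rng = np.random.default_rng(truth.seed)
        first = generate_transfer_series(
            truth, "G4", truth.buffers[0],
            condition="in_vitro@10mM", rng=rng,
        )
        stored = next(
            s for s in series if s.residue == "G4" and s.condition == "in_vitro@10mM"
        )
        assert np.array_equal(stored.intensities, first.intensities)
        assert stored.noise_sd == truth.noise_sd_invitro
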