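"""Generative model: determinism, noise-free fidelity, structure, biases."""

import numpy as np
import pandas as pd
import pytest

from grplate import (
    CapacityError,
    DrugSpec,
    EdgeField,
    NoiseModel,
    SimulationConfig,
    TrueDoseResponse,
    default_config,
    generate_dataset,
    generate_timecourse,
    generate_untreated_plate,
    gr_table,
    fit_groups,
    instantaneous_gr,
    surrogate_signal,
)
from conftest import NO_NOISE


def _single_drug_config(tdr, **kw):
    defaults = dict(
        drugs=(DrugSpec("d", tdr),), n_bio=1, n_plates=1, n_wells=2,
        n_controls=24, n_t0_wells=24, noise=NO_NOISE, edge=EdgeField(0.0), seed=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestEndpointGenerator:
    def test_seeded_determinism(self, noisy_config):
        a = generate_dataset(noisy_config)
        b = generate_dataset(noisy_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, noisy_config):
        a = generate_dataset(noisy_config, seed=1)
        b = generate_dataset(noisy_config, seed=2)
        assert not a["value"].equals(b["value"])

    def test_growth_stasis_at_saturating_dose(self):
        """gr_inf = 0 with a tiny GEC50: top-dose wells sit exactly at x0."""
        cfg = _single_drug_config(TrueDoseResponse(gr_inf=0.0, gec50=1e-6, hill=4.0))
        df = generate_dataset(cfg)
        viable = df[df["readout_type"] == "viable_count"]
        top = viable[viable["concentration"] == viable["concentration"].max()]
        np.testing.assert_allclose(top["value"], cfg.seeding, rtol=1e-9)

    def test_full_design_well_counts(self):
        """8 drugs x 8 doses x 3 wells = 192 treated wells per plate + controls."""
        cfg = default_config(seed=0, n_bio=1, n_plates=1)
        df = generate_dataset(cfg)
        viable = df[df["readout_type"] == "viable_count"]
        plate = viable[viable["plate_id"] == "b1_p1"]
        treated = plate[~plate["drug"].isin(["control", "untreated_t0"])]
        controls = plate[plate["drug"] == "control"]
        assert len(treated) == 192
        assert len(controls) >= 24
        assert len(plate) <= 384

    def test_capacity_error_when_design_overflows_plate(self, two_drug_truth):
        with pytest.raises(CapacityError):
            generate_dataset(
                SimulationConfig(drugs=two_drug_truth, n_wells=30,
                                 doses_per_drug=8, seed=0)
            )

    def test_noise_free_gr_fidelity(self, noiseless_config, noiseless_gr):
        """Noiseless round trip: recomputed GR equals the true curve <= 1e-9."""
        truth = {d.name: d.response for d in noiseless_config.drugs}
        for _, row in noiseless_gr.iterrows():
            expected = float(truth[row["drug"]].gr(row["concentration"]))
            assert abs(row["gr"] - expected) <= 1e-9

    def test_dead_counts_consistent_with_model(self, noiseless_dataset):
        wide = noiseless_dataset.pivot_table(
            index=["plate_id", "row", "col"], columns="readout_type", values="value"
        )
        np.testing.assert_allclose(
            wide["nuclei_count"] - wide["dead_count"], wide["viable_count"], atol=1e-9
        )
        assert (wide["dead_count"] >= 0).all()

    def test_day_and_plate_effects_centered(self):
        """Growth-rate multipliers are mean-1: control endpoint counts average
        to the nominal expectation over many days/plates."""
        cfg = SimulationConfig(
            drugs=(DrugSpec("d", TrueDoseResponse(0.0, 1e9, 1.0)),),
            doses_per_drug=4, n_bio=40, n_plates=2, n_wells=1, n_controls=24,
            n_t0_wells=4,
            noise=NoiseModel(cv_well=0.0, sigma_plate=0.10, sigma_day=0.10,
                             sigma_day_potency=0.0),
            edge=EdgeField(0.0), seed=3, duration_h=24.0,
        )
        df = generate_dataset(cfg)
        ctrl = df[(df["drug"] == "control") & (df["readout_type"] == "viable_count")]
        nominal = cfg.seeding * 2 ** (cfg.k_ctrl * cfg.duration_h)
        # log-normal multiplier on the exponent: mean of counts ~ nominal within a few %
        assert ctrl["value"].mean() == pytest.approx(nominal, rel=0.05)


class TestTimecourse:
    def test_noiseless_time_invariant_is_log_linear(self):
        cfg = _single_drug_config(TrueDoseResponse(-0.4, 0.1, 2.0), n_wells=1)
        tc = generate_timecourse(cfg, interval_h=4.0, duration_h=48.0)
        for _, well in tc.groupby(["plate_id", "row", "col"]):
            log2y = np.log2(well["value"].to_numpy())
            t = well["timepoint_h"].to_numpy()
            resid = log2y - np.polyval(np.polyfit(t, log2y, 1), t)
            assert np.abs(resid).max() < 1e-9

    def test_interval_must_be_positive(self, noiseless_config):
        with pytest.raises(ValueError):
            generate_timecourse(noiseless_config, interval_h=0.0)

    def test_adapting_drug_less_effective_late(self):
        """Strong early effect that decays: windowed GR at 24 h < at 48 h at
        an intermediate dose (neratinib-like adaptation)."""
        tdr = TrueDoseResponse(-0.6, 0.05, 2.0, onset_tau=2.0, adaptation_tau=30.0)
        cfg = _single_drug_config(tdr, n_wells=2, top_dose=3.16)
        tc = generate_timecourse(cfg, interval_h=2.0, duration_h=72.0)
        win = instantaneous_gr(tc, window_h=12.0, step_h=2.0)
        doses = np.sort(win["concentration"].unique())
        mid = win[win["concentration"] == doses[4]]
        gr24 = mid[np.isclose(mid["t_center"], 24.0)]["gr_t"].mean()
        gr48 = mid[np.isclose(mid["t_center"], 48.0)]["gr_t"].mean()
        assert gr24 < gr48

    def test_time_invariant_drug_stable_windows(self):
        """Etoposide-like time-invariant response: 24 h and 48 h windows agree."""
        tdr = TrueDoseResponse(-0.2, 1.0, 1.2)
        cfg = _single_drug_config(tdr, n_wells=2)
        tc = generate_timecourse(cfg, interval_h=2.0, duration_h=72.0)
        win = instantaneous_gr(tc, window_h=12.0, step_h=2.0)
        for _, grp in win.groupby("concentration"):
            gr24 = grp[np.isclose(grp["t_center"], 24.0)]["gr_t"].mean()
            gr48 = grp[np.isclose(grp["t_center"], 48.0)]["gr_t"].mean()
            assert gr24 == pytest.approx(gr48, abs=1e-6)

    def test_seeded_determinism(self, noisy_config):
        a = generate_timecourse(noisy_config, interval_h=12.0, duration_h=48.0)
        b = generate_timecourse(noisy_config, interval_h=12.0, duration_h=48.0)
        pd.testing.assert_frame_equal(a, b)


class TestSurrogate:
    def test_unit_bias_is_identity(self, noiseless_config, noiseless_dataset):
        cfg_unit = SimulationConfig(
            drugs=tuple(
                DrugSpec(d.name, d.response, atp_bias=1.0, top_dose=d.top_dose)
                for d in noiseless_config.drugs
            ),
            **{k: getattr(noiseless_config, k)
               for k in ("doses_per_drug", "top_dose", "n_bio", "n_plates",
                          "n_wells", "n_controls", "n_t0_wells", "noise",
                          "edge", "seed")},
        )
        surr = surrogate_signal(noiseless_dataset, cfg_unit)
        viable = noiseless_dataset[noiseless_dataset["readout_type"] == "viable_count"]
        np.testing.assert_array_equal(surr["value"].to_numpy(), viable["value"].to_numpy())

    def test_inflating_bias_raises_gr_max(self, noiseless_config, noiseless_dataset):
        """atp_bias = 2 (arrest enlarges cells): surrogate GRmax > count GRmax."""
        surr = surrogate_signal(noiseless_dataset, noiseless_config)
        full = pd.concat([noiseless_dataset, surr], ignore_index=True)
        gmax_count = {f.drug: f.gr_max for f in fit_groups(gr_table(full, readout="viable_count"))}
        gmax_surr = {f.drug: f.gr_max for f in fit_groups(gr_table(full, readout="surrogate_signal"))}
        assert gmax_surr["beta"] > gmax_count["beta"]  # atp_bias = 2
        assert gmax_surr["alpha"] == pytest.approx(gmax_count["alpha"], abs=1e-12)

    def test_zero_bias_lowers_saturating_gr(self, noiseless_dataset, two_drug_truth):
        cfg0 = SimulationConfig(
            drugs=tuple(DrugSpec(d.name, d.response, atp_bias=0.0) for d in two_drug_truth),
            noise=NO_NOISE, edge=EdgeField(0.0), seed=11,
            n_bio=2, n_plates=2, n_wells=2, n_controls=24, n_t0_wells=48,
        )
        surr = surrogate_signal(noiseless_dataset, cfg0)
        full = pd.concat([noiseless_dataset, surr], ignore_index=True)
        gc = gr_table(full, readout="viable_count")
        gs = gr_table(full, readout="surrogate_signal")
        top = gc["concentration"].max()
        assert (
            gs[gs["concentration"] == top]["gr"].mean()
            <= gc[gc["concentration"] == top]["gr"].mean()
        )

    def test_unknown_drug_rejected(self, noiseless_dataset, noiseless_config):
        renamed = noiseless_dataset.replace({"drug": {"alpha": "mystery"}})
        with pytest.raises(KeyError, match="mystery"):
            surrogate_signal(renamed, noiseless_config)


class TestParameterRecovery:
    def test_fitted_parameters_recover_truth_under_well_noise(self):
        """5% well CV, 3 days x 3 plates x 3 wells: median log10(GEC50) error
        within +/-0.1 and gr_inf within +/-0.05 over 20 seeds."""
        truth = TrueDoseResponse(gr_inf=-0.5, gec50=0.1, hill=2.0)
        errors = []
        for seed in range(20):
            cfg = SimulationConfig(
                drugs=(DrugSpec("d", truth),), n_bio=3, n_plates=3, n_wells=3,
                n_controls=24, n_t0_wells=48,
                noise=NoiseModel(cv_well=0.05, sigma_plate=0.0, sigma_day=0.0,
                                 sigma_day_potency=0.0),
                edge=EdgeField(0.0), seed=seed,
            )
            fits = fit_groups(gr_table(generate_dataset(cfg)))
            assert len(fits) == 1 and fits[0].fit_kind == "sigmoid"
            errors.append(
                (np.log10(fits[0].gec50 / truth.gec50), fits[0].gr_inf - truth.gr_inf)
            )
        errors = np.asarray(errors)
        assert np.median(np.abs(errors[:, 0])) <= 0.1
        assert np.median(np.abs(errors[:, 1])) <= 0.05


class TestUntreatedPlate:
    def test_edge_field_applied(self):
        cfg = default_config(seed=0, noise=NO_NOISE, edge=EdgeField(edge_frac=0.3))
        plate = generate_untreated_plate(cfg)
        interior = plate[2:-2, 2:-2]
        assert plate[0, 0] == pytest.approx(interior.mean() * 0.7, rel=1e-9)
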