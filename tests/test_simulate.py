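"""Simulator: template sampling, trace rendering, whole-run composition."""

import io as stringio
import math

import numpy as np
import pytest
from scipy import stats

from zfsex.dropout import p_dropout
from zfsex.io import write_sample_sheet, write_trace_table
from zfsex.quantify import cq_from_trace, fit_standard_curve
from zfsex.simulate import (
    SimulationConfig,
    render_trace,
    sample_reaction,
    simulate_run,
)


class TestSampleReaction:
    def test_female_zero_template_never_detected(self):
        rng = np.random.default_rng(0)
        config = SimulationConfig()
        for _ in range(100):
            m_x, m_y, x_det, y_det = sample_reaction("female", 0.0, config, rng)
            assert (m_x, m_y, x_det, y_det) == (0.0, 0.0, False, False)

    def test_females_never_carry_y(self):
        rng = np.random.default_rng(1)
        config = SimulationConfig()
        for _ in range(500):
            _, m_y, _, y_det = sample_reaction("female", 5.0, config, rng)
            assert m_y == 0.0 and not y_det

    def test_modal_positive_count_at_low_template(self):
        """Six reactions at 0.2 mean copies: the modal number of positives
        is 1 — analytically (Binomial(6, 1-e^-0.2)) and by simulation."""
        p_pos = 1 - math.exp(-0.2)
        pmf = [stats.binom.pmf(k, 6, p_pos) for k in range(7)]
        assert int(np.argmax(pmf)) == 1  # analytic oracle
        rng = np.random.default_rng(2)
        config = SimulationConfig()
        counts = np.zeros(7, dtype=int)
        for _ in range(10_000):
            positives = sum(
                sample_reaction("female", 0.2, config, rng)[2] for _ in range(6)
            )
            counts[positives] += 1
        assert int(np.argmax(counts)) == 1

    def test_high_copy_males_always_heterozygous(self):
        rng = np.random.default_rng(3)
        config = SimulationConfig()
        for _ in range(500):
            _, _, x_det, y_det = sample_reaction("male", 1000.0, config, rng)
            assert x_det and y_det

    def test_molecule_model_matches_poisson_dropout_formula(self):
        """Empirical single-allele frequency among positive reactions at
        U=1.6 agrees with the analytic conditional-dropout formula."""
        rng = np.random.default_rng(4)
        config = SimulationConfig(outcome_model="molecule")
        U = 1.6
        n, single, positive = 100_000, 0, 0
        for _ in range(n):
            _, _, x_det, y_det = sample_reaction("male", U, config, rng)
            if x_det or y_det:
                positive += 1
                if x_det != y_det:
                    single += 1
        expected = p_dropout(U, "poisson")
        observed = single / positive
        se = math.sqrt(expected * (1 - expected) / positive)
        assert abs(observed - expected) <= 3 * se

    def test_calibrated_model_matches_calibrated_curve(self):
        """In calibrated outcome mode the Y allele of an X-detected male is
        missing with exactly the calibrated per-reaction probability."""
        rng = np.random.default_rng(5)
        config = SimulationConfig(outcome_model="calibrated")
        U = 1.6
        trials = dropped = 0
        for _ in range(100_000):
            _, _, x_det, y_det = sample_reaction("male", U, config, rng)
            # each detected allele is one trial for its counterpart's dropout
            if x_det:
                trials += 1
                dropped += not y_det
            if y_det:
                trials += 1
                dropped += not x_det
        expected = p_dropout(U, "calibrated")
        observed = dropped / trials
        # within-reaction trials are negatively correlated, so the
        # independent-binomial s.e. is conservative
        se = math.sqrt(expected * (1 - expected) / trials)
        assert abs(observed - expected) <= 3 * se


class TestRenderTrace:
    def test_single_copy_anchor(self):
        rng = np.random.default_rng(6)
        config = SimulationConfig(cq_noise_sd=0.0, baseline_noise_sd=0.0,
                                  plateau_noise_sd=0.0)
        _, y_rec = render_trace("A1", 0.0, 1.0, config, rng)
        cq = cq_from_trace(y_rec.fluorescence(), 0.1 * config.plateau_fam)
        assert cq == pytest.approx(38.0, abs=0.05)

    def test_high_copy_cq_shift(self):
        # 1e5 copies: Cq = 38 - 5 / log10(1.98) = ~21.1
        rng = np.random.default_rng(7)
        config = SimulationConfig(cq_noise_sd=0.0, baseline_noise_sd=0.0,
                                  plateau_noise_sd=0.0)
        _, y_rec = render_trace("A1", 0.0, 1e5, config, rng)
        cq = cq_from_trace(y_rec.fluorescence(), 0.1 * config.plateau_fam)
        expected = 38.0 - 5.0 / math.log10(1.98)
        assert cq == pytest.approx(expected, abs=0.05)

    def test_late_cq_low_final_rfu(self):
        # a crossing within ~half a cycle of the run end leaves the final
        # RFU far below plateau — the inconclusive-call mechanism
        rng = np.random.default_rng(8)
        config = SimulationConfig(cq_noise_sd=0.0, baseline_noise_sd=0.0,
                                  plateau_noise_sd=0.0)
        k = math.log(1.98)
        copies = 10 ** ((38.0 - 39.5) * math.log10(1.98))  # Cq* = 39.5
        _, y_rec = render_trace("A1", 0.0, copies, config, rng)
        assert y_rec.final_rfu < 0.15 * config.plateau_fam

    def test_undetected_channel_is_baseline_noise(self):
        rng = np.random.default_rng(9)
        config = SimulationConfig()
        x_rec, _ = render_trace("A1", 0.0, 100.0, config, rng)
        assert abs(x_rec.final_rfu) < 20.0
        assert max(abs(f) for f in x_rec.fluorescence()) < 20.0


class TestSimulateRun:
    def test_same_seed_byte_identical(self):
        config = SimulationConfig(n_specimens=4, seed=123)
        outputs = []
        for _ in range(2):
            bundle, _ = simulate_run(config)
            traces, sheet = stringio.StringIO(), stringio.StringIO()
            write_trace_table(bundle.records, traces)
            write_sample_sheet(bundle.sheet, sheet)
            outputs.append((traces.getvalue(), sheet.getvalue()))
        assert outputs[0] == outputs[1]

    def test_different_seeds_differ(self):
        b1, _ = simulate_run(SimulationConfig(n_specimens=2, seed=1))
        b2, _ = simulate_run(SimulationConfig(n_specimens=2, seed=2))
        assert b1.records != b2.records

    def test_zero_specimens_standards_and_controls_only(self):
        bundle, truth = simulate_run(SimulationConfig(n_specimens=0, seed=0))
        roles = {row.role for row in bundle.sheet}
        assert roles == {"standard", "ntc", "extraction_blank"}
        assert truth.sexes == {}
        # 2 dyes x (5 singlicate levels + 3 low-level replicates) + 4 controls
        assert len(bundle.sheet) == 20

    def test_standard_series_recovers_configured_efficiency(self):
        """Fitting the simulated dilution series returns the configured
        98% efficiency within 2 points under Cq noise sd 0.15."""
        config = SimulationConfig(n_specimens=0, seed=42, cq_noise_sd=0.15)
        bundle, _ = simulate_run(config)
        points = []
        for row in bundle.sheet:
            if row.role != "standard" or not row.specimen_id.startswith("STD_Y"):
                continue
            rec = bundle.record(row.well, "FAM")
            cq = cq_from_trace(rec.fluorescence(), 0.1 * config.plateau_fam)
            points.append((row.standard_copies, cq))
        assert len(points) == 8
        fit = fit_standard_curve(points, "FAM")
        assert fit.efficiency == pytest.approx(0.98, abs=0.02)
        assert fit.r2 > 0.99

    def test_ground_truth_consistency(self):
        _, truth = simulate_run(SimulationConfig(n_specimens=8, seed=5))
        for r in truth.reactions:
            sex = truth.sexes[r.specimen_id]
            if sex == "female":
                assert r.m_y == 0.0 and not r.y_detected
            assert r.x_detected == (r.m_x >= 1)
            assert r.y_detected == (r.m_y >= 1)

    def test_plate_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_run(SimulationConfig(n_specimens=60, seed=0))

    def test_384_plate_accepts_larger_cohorts(self):
        bundle, _ = simulate_run(SimulationConfig(n_specimens=60, seed=0, plate="384"))
        assert len(bundle.sheet) == 20 + 180
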