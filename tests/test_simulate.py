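import math

import numpy as np
import pytest

from aavcdms.capsid import capsid_mass_moments, capsid_mass_pmf
from aavcdms.genome import PackagingState
from aavcdms.instrument import (
    InstrumentConfig,
    expected_peak_shape,
    mass_sigma,
    mean_charge,
)
from aavcdms.simulate import (
    MixtureComponent,
    accepted_masses,
    apply_incubation,
    read_events,
    simulate_ion_events,
    write_events,
)

from conftest import make_component


class TestSimulateIonEvents:
    def test_zero_ions(self, aav8, instrument, charge_model):
        mix = [make_component(aav8)]
        assert simulate_ion_events(mix, instrument, charge_model, 0, seed=0) == []

    def test_negative_ions_rejected(self, aav8, instrument, charge_model):
        with pytest.raises(ValueError):
            simulate_ion_events([make_component(aav8)], instrument, charge_model, -1, seed=0)

    def test_weights_must_sum_to_one(self, aav8, instrument, charge_model):
        mix = [make_component(aav8, weight=0.4), make_component(aav8, weight=0.4, label="b")]
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_ion_events(mix, instrument, charge_model, 10, seed=0)

    def test_seed_reproducibility(self, aav8, instrument, charge_model):
        mix = [make_component(aav8)]
        a = simulate_ion_events(mix, instrument, charge_model, 500, seed=42)
        b = simulate_ion_events(mix, instrument, charge_model, 500, seed=42)
        assert a == b
        c = simulate_ion_events(mix, instrument, charge_model, 500, seed=43)
        assert a != c

    def test_mass_equals_mz_times_z(self, aav8, instrument, charge_model):
        events = simulate_ion_events(
            [make_component(aav8)], instrument, charge_model, 200, seed=1
        )
        for e in events:
            assert e.mass == pytest.approx(e.mz * e.z, rel=1e-9)

    def test_empty_component_mean_matches_peak_shape(self, aav8, quiet_instrument, charge_model):
        n = 10_000
        events = simulate_ion_events(
            [make_component(aav8)], quiet_instrument, charge_model, n, seed=3
        )
        masses = accepted_masses(events)
        shape = expected_peak_shape(capsid_mass_pmf(aav8), 0.0, quiet_instrument, charge_model)
        se = shape.sd / math.sqrt(n)
        assert abs(masses.mean() - shape.mean) < 4 * se

    def test_empty_component_sd_matches_moments(self, aav8, quiet_instrument, charge_model):
        n = 100_000
        events = simulate_ion_events(
            [make_component(aav8)], quiet_instrument, charge_model, n, seed=4
        )
        masses = accepted_masses(events)
        mean, capsid_sd = capsid_mass_moments(aav8)
        inst_sd = mass_sigma(mean, mean_charge(mean, charge_model), quiet_instrument)
        expected_sd = math.hypot(capsid_sd, inst_sd)
        assert abs(masses.mean() - mean) < 4 * expected_sd / math.sqrt(n)
        assert np.std(masses) == pytest.approx(expected_sd, rel=0.02)

    def test_two_component_split(self, aav8, quiet_instrument, charge_model):
        n = 10_000
        mix = [
            make_component(aav8, weight=0.5),
            make_component(aav8, kind="full_GOI", dna_mass=1.4e6, weight=0.5, label="full"),
        ]
        events = simulate_ion_events(
            mix, quiet_instrument, charge_model, n, seed=5, dna_mass_scale=1.0
        )
        masses = accepted_masses(events)
        cut = 3.732e6 + 0.7e6
        frac_low = np.mean(masses < cut)
        assert abs(frac_low - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_flag_rate_converges(self, aav8, charge_model):
        cfg = InstrumentConfig(multiple_ion_rate=0.05, short_trap_rate=0.02)
        n = 50_000
        events = simulate_ion_events([make_component(aav8)], cfg, charge_model, n, seed=6)
        multi_rate = np.mean([e.multiple_ion for e in events])
        short_rate = np.mean([e.short_trap for e in events])
        assert abs(multi_rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n)
        assert abs(short_rate - 0.02) < 3 * math.sqrt(0.02 * 0.98 / n)

    def test_headful_pinned_at_capacity(self, aav8, quiet_instrument, charge_model):
        mix = [make_component(aav8, kind="headful")]
        events = simulate_ion_events(
            mix,
            quiet_instrument,
            charge_model,
            20_000,
            seed=7,
            capacity=5.33e6,
            capacity_sd=80e3,
        )
        masses = accepted_masses(events)
        assert masses.mean() == pytest.approx(5.33e6, abs=5e3)

    def test_dna_scale_and_offset(self, aav8, quiet_instrument, charge_model):
        mix = [make_component(aav8, kind="full_GOI", dna_mass=1.0e6)]
        events = simulate_ion_events(
            mix,
            quiet_instrument,
            charge_model,
            20_000,
            seed=8,
            dna_mass_scale=1.041,
            dna_mass_offset=-16_000.0,
        )
        expected = 3_732_045.0 + 1.041e6 - 16_000.0
        assert accepted_masses(events).mean() == pytest.approx(expected, abs=3e3)

    def test_multimer_order(self, aav8, quiet_instrument, charge_model):
        mix = [make_component(aav8, kind="multimer", multimer_order=2)]
        events = simulate_ion_events(mix, quiet_instrument, charge_model, 5_000, seed=9)
        assert accepted_masses(events).mean() == pytest.approx(2 * 3_732_045.0, rel=1e-3)

    def test_charge_tracks_mass_two_thirds(self, aav8, quiet_instrument, charge_model):
        mix = [make_component(aav8, kind="full_GOI", dna_mass=1.4e6)]
        events = simulate_ion_events(
            mix, quiet_instrument, charge_model, 5_000, seed=10, dna_mass_scale=1.0
        )
        z = np.array([e.z for e in events])
        m = np.array([e.mass for e in events])
        assert z.mean() == pytest.approx(mean_charge(m.mean(), charge_model), rel=0.01)


class TestApplyIncubation:
    def test_zero_removal_identity(self, aav8):
        mix = [make_component(aav8, extra_dna=(32e3, 10e3))]
        assert apply_incubation(mix, 0.0) == mix

    def test_full_removal_zeroes_extra_dna(self, aav8):
        mix = [make_component(aav8, extra_dna=(32e3, 10e3))]
        (out,) = apply_incubation(mix, 1.0)
        assert out.extra_dna == (0.0, 0.0)

    def test_out_of_range_rejected(self, aav8):
        with pytest.raises(ValueError):
            apply_incubation([make_component(aav8)], 1.5)

    def test_incubation_shifts_empty_peak_down(self, aav8, quiet_instrument, charge_model):
        # calibration scenario: removing a 32 kDa fragment load moves the
        # empty-particle peak down by ~32 kDa (cf. 3.710 -> 3.678 MDa)
        before = [make_component(aav8, extra_dna=(32e3, 5e3))]
        after = apply_incubation(before, 1.0)
        n = 50_000
        m_before = accepted_masses(
            simulate_ion_events(before, quiet_instrument, charge_model, n, seed=11)
        )
        m_after = accepted_masses(
            simulate_ion_events(after, quiet_instrument, charge_model, n, seed=11)
        )
        shift = m_before.mean() - m_after.mean()
        assert shift == pytest.approx(32e3, abs=2e3)
        assert np.std(m_after) < np.std(m_before)


class TestEventIO:
    def test_round_trip(self, aav8, instrument, charge_model, tmp_path):
        events = simulate_ion_events(
            [make_component(aav8)], instrument, charge_model, 100, seed=12
        )
        path = tmp_path / "events.tsv"
        write_events(events, path, seed=12)
        back = read_events(path)
        assert len(back) == len(events)
        assert "# seed=12" in path.read_text().splitlines()[0]
        for a, b in zip(events, back):
            assert b.mz == pytest.approx(a.mz, abs=5e-7)
            assert b.z == pytest.approx(a.z, abs=5e-7)
            assert b.mass == pytest.approx(a.mass, abs=5e-7)
            assert (a.multiple_ion, a.short_trap) == (b.multiple_ion, b.short_trap)


class TestMixtureComponentValidation:
    def test_negative_extra_dna_rejected(self, aav8):
        with pytest.raises(ValueError):
            make_component(aav8, extra_dna=(-1.0, 0.0))

    def test_bad_partial_range_rejected(self, aav8):
        with pytest.raises(ValueError):
            make_component(aav8, kind="partial", dna_mass=1e6, partial_fraction_range=(0.8, 0.2))

    def test_shape_factor_below_one_rejected(self, aav8):
        with pytest.raises(ValueError):
            make_component(aav8, charge_shape_factor=0.9)
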