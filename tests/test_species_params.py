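"""Parameter derivation from gene structure and nuclear geometry."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from segclock.errors import ConfigurationError, DomainError
from segclock.species_params import (
    AMBYSTOMA_MEXICANUM,
    XENOPUS_LAEVIS,
    GeneModel,
    NuclearGeometry,
    SpeciesConfig,
    assemble_parameters,
    critical_threshold,
    round_reported,
    species_parameter_table,
    splicing_delay,
    transcription_delay,
    translation_delay,
)


class TestCriticalThreshold:
    @pytest.mark.parametrize(
        "radius, expected",
        [(4.0, 161), (5.5, 420)],
        ids=["frog_nucleus", "axolotl_nucleus"],
    )
    def test_published_molecule_counts(self, radius, expected):
        value = critical_threshold(NuclearGeometry(radius), 1e-9)
        assert round_reported(value, 0) == expected

    @given(radius=st.floats(0.5, 20.0), concentration=st.floats(1e-12, 1e-6))
    def test_linear_in_concentration_cubic_in_radius(self, radius, concentration):
        base = critical_threshold(NuclearGeometry(radius), concentration)
        assert critical_threshold(NuclearGeometry(radius), 3 * concentration) == pytest.approx(3 * base)
        assert critical_threshold(NuclearGeometry(2 * radius), concentration) == pytest.approx(8 * base)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(DomainError):
            NuclearGeometry(-1.0)
        with pytest.raises(DomainError):
            critical_threshold(NuclearGeometry(4.0), 0.0)


class TestDelays:
    def test_translation_delay_published_values(self):
        assert round_reported(translation_delay(XENOPUS_LAEVIS.gene, 6.0)) == 1.29
        assert round_reported(translation_delay(AMBYSTOMA_MEXICANUM.gene, 6.0)) == 2.18

    def test_transcription_delay_published_values(self):
        assert round_reported(transcription_delay(XENOPUS_LAEVIS.gene, 20.0)) == 1.34
        assert round_reported(transcription_delay(AMBYSTOMA_MEXICANUM.gene, 20.0)) == 6.89
        # plain arithmetic: 1200 nt at 20 nt/s is exactly a minute
        gene = GeneModel("g", primary_length=1200, coding_length=300)
        assert transcription_delay(gene, 20.0) == pytest.approx(1.0)

    def test_splicing_delay_published_values(self):
        assert round_reported(splicing_delay(56.0, 0.083)) == 4.65
        assert round_reported(splicing_delay(154.0, 0.083)) == 12.78
        assert splicing_delay(0.0, 0.083) == 0.0

    @pytest.mark.parametrize("bad_rate", [0.0, -6.0])
    def test_rejects_nonpositive_rates(self, bad_rate):
        with pytest.raises(DomainError):
            translation_delay(XENOPUS_LAEVIS.gene, bad_rate)
        with pytest.raises(DomainError):
            transcription_delay(XENOPUS_LAEVIS.gene, bad_rate)

    def test_splicing_fraction_domain(self):
        with pytest.raises(DomainError):
            splicing_delay(56.0, 1.5)


class TestAssembleParameters:
    @pytest.mark.parametrize(
        "config, diffusion, expected_tm",
        [
            (XENOPUS_LAEVIS, "normal", 12.38),
            (XENOPUS_LAEVIS, "fractional", 14.35),
            (AMBYSTOMA_MEXICANUM, "normal", 31.64),
            (AMBYSTOMA_MEXICANUM, "fractional", 45.94),
        ],
    )
    def test_mrna_delay_totals(self, config, diffusion, expected_tm):
        params = assemble_parameters(config, diffusion)
        assert round_reported(params.delays.T_m) == expected_tm

    def test_tm_is_sum_of_parts(self):
        d = assemble_parameters(AMBYSTOMA_MEXICANUM, "normal").delays
        assert d.T_m == d.T_tx + d.T_in + d.T_exp

    def test_deterministic(self):
        a = assemble_parameters(XENOPUS_LAEVIS, "normal")
        b = assemble_parameters(XENOPUS_LAEVIS, "normal")
        assert a == b

    def test_halflife_rate_identity(self):
        params = assemble_parameters(AMBYSTOMA_MEXICANUM, "normal")
        assert params.b * params.h_p == pytest.approx(math.log(2), abs=1e-15)
        assert params.c * params.h_m == pytest.approx(math.log(2), abs=1e-15)

    def test_missing_config_field_is_named(self):
        with pytest.raises(ConfigurationError, match="clock_period_min"):
            SpeciesConfig.from_dict(
                {
                    "name": "x",
                    "gene": {"name": "g", "primary_length": 100, "coding_length": 60},
                    "nuclear_radius_um": 4.0,
                    "export_delay_min": {"normal": 1.0, "fractional": 2.0},
                }
            )

    def test_total_delay_redistribution_preserves_sum(self, amex_bm_baseline):
        for total in (16.91, 33.82, 50.73):
            adjusted = amex_bm_baseline.with_total_delay(total)
            assert adjusted.total_delay == pytest.approx(total)
            assert adjusted.delays.T_p == amex_bm_baseline.delays.T_p
        with pytest.raises(ConfigurationError):
            amex_bm_baseline.with_total_delay(1.0)


class TestGeneModelInvariants:
    def test_primary_must_cover_parts(self):
        with pytest.raises(DomainError):
            GeneModel("bad", primary_length=500, coding_length=465, intron_lengths=(166, 113))

    @given(st.integers(1, 500), st.lists(st.integers(1, 300), max_size=4))
    def test_consistent_models_always_valid(self, cds, introns):
        gene = GeneModel("g", cds + sum(introns) + 10, cds, tuple(introns))
        assert gene.primary_length >= gene.coding_length + gene.total_intron_length


def test_parameter_table_reports_published_values():
    table = species_parameter_table()
    xl = table["Xenopus laevis"]
    am = table["Ambystoma mexicanum"]
    assert xl["p_crit"] == 161 and am["p_crit"] == 420
    assert xl["T_p"] == 1.29 and am["T_p"] == 2.18
    assert xl["T_tx"] == 1.34 and am["T_tx"] == 6.89
    assert xl["T_in"] == 4.65 and am["T_in"] == 12.78
    assert xl["T_m (normal)"] == 12.38 and am["T_m (fractional)"] == 45.94


def test_round_reported_half_away_from_zero():
    assert round_reported(2.175) == 2.18  # 783/360 lands exactly on a tie
    assert round_reported(-2.175) == -2.18
    assert round_reported(161.44, 0) == 161
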