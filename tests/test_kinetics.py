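"""Reaction-network parsing, mass-action fluxes and stiff integration."""

import numpy as np
import pytest
from scipy.linalg import expm

from coagclass.kinetics import (
    ModelParseError,
    Reaction,
    ReactionNetwork,
    SimulationError,
    Species,
    mass_action_rates,
    parse_model_text,
    simulate,
)
from conftest import CHAIN_A0, CHAIN_K1, CHAIN_K2

TOY_TEXT = """
# three-species toy
[species]
A = 1.0e-9
B = 0.0
C = 0.0
[reactions]
A -> B, k=1.0e-2
B -> C, k=5.0e-3
"""


class TestModelParsing:
    def test_toy_file_counts(self):
        net = parse_model_text(TOY_TEXT)
        assert net.species_names == ["A", "B", "C"]
        assert len(net.reactions) == 2
        assert net.reactions[0].rate_constant == 1.0e-2

    def test_reversible_expands_to_two_records(self):
        net = parse_model_text(
            "[species]\nA = 1e-9\nB = 0\n[reactions]\nA <-> B, kf=2.0, kr=0.5\n"
        )
        assert len(net.reactions) == 2
        assert net.reactions[0].rate_constant == 2.0
        assert net.reactions[1].reactants == {"B": 1}

    def test_stoichiometric_multipliers(self):
        net = parse_model_text(
            "[species]\nX = 1e-9\nY = 0\n[reactions]\n2*X -> Y, k=1.0\n"
        )
        assert net.reactions[0].reactants == {"X": 2}
        assert net.reactions[0].order == 2

    def test_undeclared_species_named_in_error(self):
        with pytest.raises(ModelParseError, match="'D'"):
            parse_model_text("[species]\nA = 1e-9\n[reactions]\nA -> D, k=1.0\n")

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ModelParseError, match="negative rate"):
            parse_model_text("[species]\nA = 1e-9\n[reactions]\nA -> A, k=-1.0\n")

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelParseError, match="duplicate"):
            parse_model_text("[species]\nA = 1e-9\nA = 2e-9\n[reactions]\n")

    def test_hyphenated_species_names(self):
        net = parse_model_text(
            "[species]\nTf-fVIIa = 0\nfX = 1e-7\nfXa = 0\n[reactions]\n"
            "Tf-fVIIa + fX -> Tf-fVIIa + fXa, k=1e7\n"
        )
        assert "Tf-fVIIa" in net.index
        assert net.reactions[0].reactants == {"Tf-fVIIa": 1, "fX": 1}

    def test_bundled_model_parses(self, toy_network):
        assert toy_network.n_species == 21
        assert len(toy_network.reactions) == 14


class TestMassActionRates:
    def test_first_order_law(self):
        net = parse_model_text("[species]\nA = 0\nB = 0\n[reactions]\nA -> B, k=1.0\n")
        assert mass_action_rates(net, [2.0, 0.0]) == pytest.approx([2.0])

    def test_bimolecular_law(self):
        net = parse_model_text(
            "[species]\nA = 0\nB = 0\nC = 0\n[reactions]\nA + B -> C, k=0.5\n"
        )
        assert mass_action_rates(net, [2.0, 3.0, 0.0]) == pytest.approx([3.0])

    def test_zero_reactant_gives_zero_flux(self):
        net = parse_model_text(
            "[species]\nA = 0\nB = 0\nC = 0\n[reactions]\nA + B -> C, k=7.0\n"
        )
        assert mass_action_rates(net, [0.0, 5.0, 0.0]) == pytest.approx([0.0])

    def test_second_order_same_species(self):
        net = parse_model_text("[species]\nX = 0\nY = 0\n[reactions]\n2*X -> Y, k=3.0\n")
        assert mass_action_rates(net, [2.0, 0.0]) == pytest.approx([12.0])

    def test_flux_homogeneous_in_rate_constants(self, chain_network):
        state = np.array([1.5e-9, 2.5e-10, 1e-11])
        base = mass_action_rates(chain_network, state)
        scaled = ReactionNetwork(
            chain_network.species,
            [
                Reaction(r.reactants, r.products, 7.0 * r.rate_constant)
                for r in chain_network.reactions
            ],
        )
        np.testing.assert_allclose(
            mass_action_rates(scaled, state), 7.0 * base, rtol=1e-15, atol=0)

    def test_shape_mismatch_rejected(self, chain_network):
        with pytest.raises(ValueError, match="shape"):
            mass_action_rates(chain_network, [1.0, 2.0])


class TestSimulate:
    def test_exponential_decay_closed_form(self, chain_network):
        # atol tightened below the nanomolar state scale so the comparison
        # is relative-error limited
        prof = simulate(chain_network, t_end=100.0, n_out=101, atol=1e-20)
        expected = CHAIN_A0 * np.exp(-CHAIN_K1 * prof.times)
        np.testing.assert_allclose(prof.trajectory("A"), expected, rtol=1e-6)

    def test_matrix_exponential_oracle_full_grid(self, chain_network):
        """Linear chain matches x(t) = expm(K t) x0 at every output time."""
        K = np.array([
            [-CHAIN_K1, 0.0, 0.0],
            [CHAIN_K1, -CHAIN_K2, 0.0],
            [0.0, CHAIN_K2, 0.0],
        ])
        x0 = np.array([CHAIN_A0, 0.0, 0.0])
        prof = simulate(chain_network, t_end=600.0, n_out=61, atol=1e-20)
        for j, t in enumerate(prof.times):
            exact = expm(K * t) @ x0
            np.testing.assert_allclose(
                prof.concentrations[:, j], exact, rtol=1e-6, atol=1e-18)

    def test_mass_conservation(self, chain_network):
        prof = simulate(chain_network, t_end=3600.0, n_out=361)
        total = prof.concentrations.sum(axis=0)
        np.testing.assert_allclose(total, CHAIN_A0, rtol=1e-9)

    def test_output_grid_independence(self, chain_network):
        coarse = simulate(chain_network, t_end=200.0, n_out=11)
        fine = simulate(chain_network, t_end=200.0, n_out=21)
        np.testing.assert_allclose(
            fine.concentrations[:, ::2], coarse.concentrations,
            rtol=1e-6, atol=1e-20)

    def test_weighted_conservation_in_toy_cascade(self, toy_network):
        """Every factor-X atom ends up in fX, fXa or an fXa complex."""
        prof = simulate(toy_network, t_end=3600.0, n_out=361)
        idx = toy_network.index
        total = sum(
            prof.concentrations[idx[name]]
            for name in ("fX", "fXa", "fXa-fVa", "TFPI-fXa", "AT-fXa")
        )
        np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_toy_cascade_thrombin_peaks_then_declines(self, toy_network):
        prof = simulate(toy_network)
        iia = prof.trajectory("IIa")
        peak_idx = int(np.argmax(iia))
        assert iia.max() > 1e-8
        assert 0 < peak_idx < len(iia) - 1
        # termination: thrombin inhibited to well below a thousandth of peak
        assert abs(iia[-1]) < 1e-3 * iia.max()

    def test_validation_errors(self, chain_network):
        with pytest.raises(ValueError, match="t_end"):
            simulate(chain_network, t_end=0.0)
        with pytest.raises(ValueError, match="n_out"):
            simulate(chain_network, n_out=1)
        with pytest.raises(ValueError, match="initial"):
            simulate(chain_network, initial=[1e-9, 0.0])

    def test_blowup_reported_as_simulation_error(self):
        # autocatalytic 2X -> 3X diverges in finite time
        net = parse_model_text(
            "[species]\nX = 1.0\n[reactions]\n2*X -> 3*X, k=1.0\n"
        )
        with pytest.raises(SimulationError):
            simulate(net, t_end=10.0, n_out=11)


class TestInvariantsAndTypes:
    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ValueError):
            Species("A", -1.0)

    def test_profile_requires_zero_start(self):
        with pytest.raises(ValueError, match="start at 0"):
            from coagclass.kinetics import SimulationProfile

            SimulationProfile(
                np.array([1.0, 2.0]), np.zeros((1, 2)), ["A"])

    def test_tidy_export_layout(self, chain_network):
        prof = simulate(chain_network, t_end=10.0, n_out=3)
        df = prof.to_frame()
        assert list(df.columns) == ["time_s", "species", "concentration_M"]
        assert len(df) == 3 * 3
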