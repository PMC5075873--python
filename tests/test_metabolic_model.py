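import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statevar.metabolic_model import (
    BLEND,
    CONTROL,
    STRESSED,
    MetaboliteSpec,
    MetabolicModel,
    ModelError,
    ReactionSpec,
    interpolate,
    load_model,
    model_from_dict,
    model_to_dict,
    overexpress,
    reaction_rate,
    save_model,
)


def _rxn(**kwargs):
    defaults = dict(
        id="R1",
        substrates=(("A", 1.0),),
        products=(("B", 1.0),),
        km={"A": 1.0},
        vmax_by_condition={CONTROL: 1.0, STRESSED: 2.0},
    )
    defaults.update(kwargs)
    return ReactionSpec(**defaults)


class TestValidation:
    def test_negative_initial_amount(self):
        with pytest.raises(ModelError, match="initial_amount"):
            MetaboliteSpec(id="A", initial_amount=-1.0)

    def test_km_zero_names_reaction(self):
        with pytest.raises(ModelError, match="R1"):
            _rxn(km={"A": 0.0})

    def test_missing_km(self):
        with pytest.raises(ModelError, match="Km"):
            _rxn(km={})

    def test_negative_vmax(self):
        with pytest.raises(ModelError, match="Vmax"):
            _rxn(vmax_by_condition={CONTROL: -1.0, STRESSED: 1.0})

    def test_undeclared_product_named(self):
        mets = (MetaboliteSpec(id="A", initial_amount=1.0),)
        with pytest.raises(ModelError, match="B"):
            MetabolicModel(metabolites=mets, reactions=(_rxn(),))

    def test_duplicate_metabolite(self):
        mets = (
            MetaboliteSpec(id="A", initial_amount=1.0),
            MetaboliteSpec(id="A", initial_amount=2.0),
        )
        with pytest.raises(ModelError, match="duplicate"):
            MetabolicModel(metabolites=mets, reactions=())

    def test_duplicate_reaction(self):
        mets = (
            MetaboliteSpec(id="A", initial_amount=1.0),
            MetaboliteSpec(id="B", initial_amount=0.0),
        )
        with pytest.raises(ModelError, match="duplicate"):
            MetabolicModel(metabolites=mets, reactions=(_rxn(), _rxn()))


class TestIO:
    def test_fixture_roundtrip(self, fig1_model, tmp_path):
        path = tmp_path / "model.yaml"
        save_model(fig1_model, path)
        loaded = load_model(path)
        assert len(loaded.reactions) == 33
        assert loaded.conditions == (CONTROL, STRESSED)
        assert loaded == fig1_model

    def test_json_roundtrip(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(small_model, path)
        assert load_model(path) == small_model

    def test_schema_version_mismatch(self, small_model, tmp_path):
        data = model_to_dict(small_model)
        data["schema_version"] = 99
        with pytest.raises(ModelError, match="schema_version"):
            model_from_dict(data)

    def test_parse_error_reports_path(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("metabolites: [unclosed\n")
        with pytest.raises(ModelError, match="bad.yaml"):
            load_model(bad)

    def test_missing_key(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("schema_version: 1\nmetabolites: []\nreactions: []\n")
        with pytest.raises(ModelError, match="conditions"):
            load_model(bad)


class TestReactionRate:
    def test_half_saturation(self):
        r = _rxn()
        assert reaction_rate(r, {"A": 1.0}, 2.0) == pytest.approx(1.0)

    def test_zero_substrate(self):
        assert reaction_rate(_rxn(), {"A": 0.0}, 2.0) == 0.0

    def test_saturation_two_substrates(self):
        r = _rxn(substrates=(("A", 1.0), ("B", 1.0)), km={"A": 1.0, "B": 2.0})
        rate = reaction_rate(r, {"A": 1e9, "B": 1e9}, 5.0)
        assert rate == pytest.approx(5.0, rel=1e-6)

    def test_negative_amount_errors(self):
        with pytest.raises(ValueError, match="negative"):
            reaction_rate(_rxn(), {"A": -0.1}, 1.0)

    def test_noncompetitive_inhibitor(self):
        r = _rxn(inhibitor=("B", 1.0))
        # I = Ki halves the uninhibited rate
        assert reaction_rate(r, {"A": 1.0, "B": 1.0}, 2.0) == pytest.approx(0.5)

    @given(
        s=st.floats(0.0, 1e6),
        delta=st.floats(0.0, 1e6),
        km=st.floats(1e-3, 1e3),
        vmax=st.floats(0.0, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, s, delta, km, vmax):
        r = _rxn(km={"A": km})
        lo = reaction_rate(r, {"A": s}, vmax)
        hi = reaction_rate(r, {"A": s + delta}, vmax)
        assert 0.0 <= lo <= hi <= vmax + 1e-12


class TestInterpolate:
    def test_endpoints_exact(self, fig1_model):
        for lam, cond in ((0.0, CONTROL), (1.0, STRESSED)):
            blended = interpolate(fig1_model, lam)
            assert blended.conditions == (BLEND,)
            for r in fig1_model.reactions:
                assert blended.reaction(r.id).vmax(BLEND) == r.vmax(cond)

    def test_midpoint(self, small_model):
        blended = interpolate(small_model, 0.5)
        assert blended.reaction("R1").vmax(BLEND) == pytest.approx(1.65)

    def test_known_midpoint_values(self):
        mets = (
            MetaboliteSpec(id="A", initial_amount=1.0),
            MetaboliteSpec(id="B", initial_amount=0.0),
        )
        m = MetabolicModel(
            metabolites=mets,
            reactions=(_rxn(vmax_by_condition={CONTROL: 2.0, STRESSED: 6.0}),),
        )
        assert interpolate(m, 0.5).reaction("R1").vmax(BLEND) == pytest.approx(4.0)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_affine(self, small_model, a, b):
        mid = interpolate(small_model, (a + b) / 2)
        va = interpolate(small_model, a)
        vb = interpolate(small_model, b)
        for r in small_model.reactions:
            expected = (va.reaction(r.id).vmax(BLEND) + vb.reaction(r.id).vmax(BLEND)) / 2
            assert mid.reaction(r.id).vmax(BLEND) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lam", [-0.1, 1.1, 2.0])
    def test_out_of_range(self, small_model, lam):
        with pytest.raises(ValueError, match="lam"):
            interpolate(small_model, lam)


class TestOverexpress:
    def test_four_fold_only_changes_target(self, fig1_model):
        edited = overexpress(fig1_model, "R19", 4.0)
        for r in fig1_model.reactions:
            e = edited.reaction(r.id)
            if r.id == "R19":
                assert e.vmax(CONTROL) == pytest.approx(4.0 * r.vmax(CONTROL))
            else:
                assert e.vmax(CONTROL) == r.vmax(CONTROL)
            assert e.vmax(STRESSED) == r.vmax(STRESSED)

    def test_identity_factor(self, fig1_model):
        assert overexpress(fig1_model, "R19", 1.0) == fig1_model

    def test_unknown_reaction(self, fig1_model):
        with pytest.raises(ModelError, match="R99"):
            overexpress(fig1_model, "R99", 4.0)

    def test_nonpositive_factor(self, fig1_model):
        with pytest.raises(ValueError, match="factor"):
            overexpress(fig1_model, "R19", 0.0)

    @given(f=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip(self, small_model, f):
        back = overexpress(overexpress(small_model, "R2", f), "R2", 1.0 / f)
        assert back.reaction("R2").vmax(CONTROL) == pytest.approx(
            small_model.reaction("R2").vmax(CONTROL)
        )
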