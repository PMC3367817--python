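import pytest
from hypothesis import given, settings, strategies as st

from dsdmc.dsd_core import (
    Domain,
    DSDSyntaxError,
    Species,
    canonicalize,
    check_well_formed,
    expand_modules,
    format_system,
    parse_species,
    parse_system,
)
from dsdmc import gate_library as gl


class TestDomain:
    def test_complement_involution(self):
        d = Domain("x", False, False)
        assert d.comp.comp == d
        t = Domain("t", True, True)
        assert t.comp.comp == t

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            Domain("")

    def test_str(self):
        assert str(Domain("t", True, True)) == "t^*"
        assert str(Domain("x")) == "x"


class TestParser:
    def test_single_strand(self):
        sp = parse_species("<t^ x>")
        assert sp.is_strand
        assert sp.strand == (Domain("t", True, False), Domain("x"))

    def test_lower_strand_is_reversed(self):
        # {S} is drawn right-to-left; 5'->3' order is the reverse of the text
        assert parse_species("{x t^}") == parse_species("<t^ x>")

    def test_two_species_example(self):
        spec = parse_system("<t^ x u^> | {t^*}[x]{u^*}")
        species = spec.species()
        assert len(species) == 2
        kinds = sorted(sp.kind for sp in species)
        assert kinds == ["gate", "strand"]
        gate = next(sp for sp in species if sp.is_gate)
        assert str(gate) == "{t^*}[x]{u^*}"

    @pytest.mark.parametrize(
        "text",
        [
            "<t^ x>",
            "{t^*}[x]{u^*}",
            "{t^*}[x t^]:[c]:[a t^]:[a]",
            "[x]:[t^ y]:[c]:[t^ a]{t^*}",
            "[a]::[b]",
            "{x*}<y>[z]<w>{v^*}",
            "[x y]<z>:[w]{p^*}",
        ],
    )
    def test_print_parse_identity(self, text):
        sp = parse_species(text)
        assert parse_species(str(sp)) == sp

    def test_syntax_error_has_position(self):
        with pytest.raises(DSDSyntaxError) as err:
            parse_system("<t^ x> | <?>")
        assert err.value.line == 1

    def test_unknown_module(self):
        with pytest.raises(ValueError, match="unknown module"):
            parse_system("Q(1,x)")

    def test_recursive_module(self):
        with pytest.raises(ValueError, match="recursive"):
            parse_system("def A(x) = A(x)\nA(y)")

    def test_mutually_recursive_modules(self):
        with pytest.raises(ValueError, match="recursive"):
            parse_system("def A(x) = B(x)\ndef B(x) = A(x)\nA(y)")

    def test_counts_and_constant(self):
        spec = parse_system("3 * <t^ x> | constant 2 * <t^ y>")
        x = parse_species("<t^ x>")
        y = parse_species("<t^ y>")
        assert spec.species_counts[x] == 3
        assert spec.species_counts[y] == 2
        assert spec.constant_species == {y}

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 500))
    def test_roundtrip_on_random_fixtures(self, seed):
        spec = gl.generate_fixture(seed)
        text = format_system(spec)
        again = parse_system(text)
        assert sorted(again.species_counts.items()) == sorted(spec.species_counts.items())
        assert again.constant_species == spec.constant_species


class TestExpansion:
    def test_zero_parameter_module(self):
        spec = parse_system("def M() = <t^ x> | <t^ y>\nM()")
        spec = expand_modules(spec)
        assert len(spec.species_counts) == 2

    def test_arity_mismatch(self):
        with pytest.raises(ValueError, match="argument"):
            expand_modules(parse_system("def M(a, b) = <t^ a>\nM(x)"))

    def test_fresh_names_distinct_per_instantiation(self):
        src = "def M(x) = new c ( <t^ c> | <t^ x> )\nM(u) | M(v)"
        spec = expand_modules(parse_system(src))
        fresh = sorted(spec.bound_domains)
        assert len(fresh) == 2 and len(set(fresh)) == 2
        assert all(name.startswith("c.") for name in fresh)

    def test_shared_vs_private_domains(self):
        # two originals share 'a' but have distinct 'c'; two corrected
        # instances share neither
        def domains_of(spec):
            out = set()
            for sp in spec.species_counts:
                out |= {d.name for d in sp.domains()}
            return out

        t_pair = gl.transducer_pair(1, "T")
        doms = domains_of(t_pair)
        assert "a" in doms
        assert sum(1 for d in doms if d.startswith("c.")) == 2

        t2_pair = gl.transducer_pair(1, "T2")
        doms2 = domains_of(t2_pair)
        assert "a" not in doms2
        assert sum(1 for d in doms2 if d.startswith("a.")) == 2

    def test_expand_idempotent_on_module_free(self):
        spec = expand_modules(parse_system("<t^ x> | {t^*}[x]"))
        again = expand_modules(spec)
        assert again.species_counts == spec.species_counts

    def test_population_zero(self):
        spec = expand_modules(parse_system("def S(N, x) = N * <t^ x>\nS(0,x)"))
        sp = parse_species("<t^ x>")
        assert spec.species_counts[sp] == 0


class TestCanonicalization:
    def test_idempotent(self):
        sp = parse_species("{t^*}[x t^]:[a t^]:[c]")
        assert canonicalize(sp) == sp

    def test_rotation_invariance(self):
        g = parse_species("{t^*}[x t^]:[a t^]:[c]").gate
        assert canonicalize(g.rotate()) == canonicalize(g)

    def test_branch_migration_equivalence(self):
        # migration that displaces nothing relates equal species
        pre = parse_species("[t^ x]<y u^>:[y u^]")
        post = parse_species("[t^ x y]<u^>:<y>[u^]")
        assert pre == post

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 300))
    def test_random_orbit(self, seed):
        spec = gl.generate_fixture(seed)
        for sp in spec.species_counts:
            if sp.is_gate:
                assert canonicalize(sp.gate.rotate()) == sp
                assert canonicalize(canonicalize(sp)) == sp


class TestWellFormedness:
    def test_exposed_complement_pair(self):
        spec = expand_modules(parse_system("<t^ x> | {x* t^*}"))
        violations = check_well_formed(spec)
        assert len(violations) == 1
        assert violations[0].domain.name == "x"

    def test_empty_system(self):
        spec = expand_modules(parse_system("def Z() = 0 * <t^ x>\nZ()"))
        assert check_well_formed(spec) == []

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: gl.transducer_pair(1, "T"),
            lambda: gl.transducer_pair(1, "T2"),
            lambda: gl.catalyst_system(1, True),
            lambda: gl.catalyst_system(1, False),
            lambda: gl.approx_majority_system(1, 1),
        ],
    )
    def test_case_study_systems(self, builder):
        assert check_well_formed(builder()) == []

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 500))
    def test_fixtures_well_formed(self, seed):
        assert check_well_formed(gl.generate_fixture(seed)) == []
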