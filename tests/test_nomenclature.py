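"""Lipid shorthand parsing, classification, and composition profiles."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidyn.nomenclature import (
    AcylChain,
    AnnotationLevel,
    ChainLength,
    ClassRegistry,
    LipidParseError,
    LipidValidationError,
    Unsaturation,
    acyl_composition_profile,
    classify_chain_length,
    classify_unsaturation,
    default_registry,
    parse_lipid_name,
)


class TestParse:
    @pytest.mark.parametrize(
        "name,cls,tc,tdb,n_acyls,level",
        [
            ("CL76:12(16:1)", "CL", 76, 12, 1, AnnotationLevel.partial_acyl),
            ("CL70:8(16:1)", "CL", 70, 8, 1, AnnotationLevel.partial_acyl),
            ("DAG36:3(18:2/18:1)", "DAG", 36, 3, 2, AnnotationLevel.full_acyl),
            ("SM d18:1/12:0", "SM", 30, 1, 2, AnnotationLevel.full_acyl),
            ("PE36:1p(18:0p/18:1)", "PE", 36, 1, 2, AnnotationLevel.full_acyl),
            ("PC32:0", "PC", 32, 0, 0, AnnotationLevel.sum_composition),
            ("TAG 54:2(18:2)", "TAG", 54, 2, 1, AnnotationLevel.partial_acyl),
            ("BMP 14:0/14:0", "LBPA", 28, 0, 2, AnnotationLevel.full_acyl),
            ("Cho", "Cho", 0, 0, 0, AnnotationLevel.class_only),
            ("FFA 16:0", "FFA", 16, 0, 1, AnnotationLevel.full_acyl),
        ],
    )
    def test_examples(self, name, cls, tc, tdb, n_acyls, level):
        sp = parse_lipid_name(name)
        assert sp.lipid_class == cls
        assert sp.total_carbons == tc
        assert sp.total_double_bonds == tdb
        assert len(sp.acyls) == n_acyls
        assert sp.annotation_level is level

    def test_ether_flag_and_sphingoid(self):
        sp = parse_lipid_name("PE36:1p(18:0p/18:1)")
        assert sp.ether and sp.acyls[0].ether and not sp.acyls[1].ether
        sm = parse_lipid_name("SM d18:1/12:0")
        assert sm.acyls[0].sphingoid == "d" and sm.acyls[1].sphingoid == ""

    def test_isotope_label_prefix_is_tag_not_composition(self):
        sp = parse_lipid_name("d5-CL 72:8(18:2)")
        assert sp.label == "d5"
        assert sp.lipid_class == "CL" and sp.total_carbons == 72
        sp2 = parse_lipid_name("d9-PC36:1p(18:0p/18:1)")
        assert sp2.label == "d9" and sp2.ether

    def test_polar_flags(self):
        assert parse_lipid_name("PC32:0").is_polar
        assert parse_lipid_name("SM d18:1/12:0").is_polar
        assert not parse_lipid_name("TAG 54:2(18:2)").is_polar
        assert not parse_lipid_name("Cho").is_polar

    def test_whitespace_optional(self):
        assert parse_lipid_name("TAG 54:2(18:2)") == parse_lipid_name("TAG54:2(18:2)")

    @pytest.mark.parametrize("bad", ["", "  ", "XYZ34:1", "PC32", "PC32:0(18:0", "QQ 16:0"])
    def test_unparseable(self, bad):
        with pytest.raises(LipidParseError):
            parse_lipid_name(bad)

    def test_full_acyl_sum_mismatch_raises(self):
        with pytest.raises(LipidValidationError):
            parse_lipid_name("DAG36:3(18:2/18:2)")
        with pytest.raises(LipidValidationError):
            parse_lipid_name("DAG36:3(17:2/18:1)")

    def test_acyl_chain_invariants(self):
        with pytest.raises(LipidValidationError):
            AcylChain(0, 0)
        with pytest.raises(LipidValidationError):
            AcylChain(16, 17)


# grammar generator for the round-trip property
_classes2 = st.sampled_from(["PC", "PE", "PS", "PI", "PG", "DAG", "LBPA"])


@st.composite
def canonical_names(draw):
    form = draw(st.integers(0, 3))
    if form == 0:  # sum composition
        cls = draw(_classes2)
        c = draw(st.integers(28, 44))
        d = draw(st.integers(0, 8))
        return f"{cls}{c}:{d}"
    if form == 1:  # full acyl glycerophospholipid
        cls = draw(_classes2)
        c1, c2 = draw(st.integers(12, 22)), draw(st.integers(12, 22))
        d1, d2 = draw(st.integers(0, 4)), draw(st.integers(0, 4))
        return f"{cls}{c1 + c2}:{d1 + d2}({c1}:{d1}/{c2}:{d2})"
    if form == 2:  # partially annotated cardiolipin
        c = draw(st.integers(68, 80))
        d = draw(st.integers(4, 12))
        ac = draw(st.sampled_from([16, 18, 20]))
        ad = draw(st.integers(1, 4))
        return f"CL{c}:{d}({ac}:{ad})"
    # sphingolipid with totals and chains
    cls = draw(st.sampled_from(["SM", "Cer", "GM3"]))
    nc = draw(st.integers(12, 26))
    nd = draw(st.integers(0, 2))
    return f"{cls}{18 + nc}:{1 + nd}(d18:1/{nc}:{nd})"


class TestRoundTrip:
    @settings(max_examples=200, deadline=None)
    @given(canonical_names())
    def test_parse_format_parse_identity(self, name):
        sp = parse_lipid_name(name)
        assert sp.canonical() == name
        assert parse_lipid_name(sp.canonical()) == sp

    def test_noncanonical_names_normalize(self):
        assert parse_lipid_name("TAG 54:2(18:2)").canonical() == "TAG54:2(18:2)"
        assert parse_lipid_name("SM d18:1/12:0").canonical() == "SM30:1(d18:1/12:0)"

    @settings(max_examples=50, deadline=None)
    @given(canonical_names())
    def test_corrupting_full_acyl_carbon_raises(self, name):
        sp = parse_lipid_name(name)
        if sp.annotation_level is not AnnotationLevel.full_acyl or not sp.acyls:
            return
        a = sp.acyls[0]
        bad = name.replace(f"{a.carbons}:{a.double_bonds}", f"{a.carbons + 1}:{a.double_bonds}", 1)
        with pytest.raises((LipidValidationError, LipidParseError)):
            parse_lipid_name(bad)


class TestClassifiers:
    @pytest.mark.parametrize(
        "c,expected",
        [(14, ChainLength.short), (18, ChainLength.long), (24, ChainLength.very_long),
         (15, ChainLength.short), (16, ChainLength.long), (21, ChainLength.long),
         (22, ChainLength.very_long)],
    )
    def test_chain_length(self, c, expected):
        assert classify_chain_length(c) is expected

    @pytest.mark.parametrize(
        "d,expected",
        [(0, Unsaturation.saturated), (1, Unsaturation.mono_di), (2, Unsaturation.mono_di),
         (3, Unsaturation.poly), (6, Unsaturation.poly)],
    )
    def test_unsaturation(self, d, expected):
        assert classify_unsaturation(d) is expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            classify_chain_length(0)
        with pytest.raises(ValueError):
            classify_unsaturation(-1)

    @given(st.integers(1, 120))
    def test_chain_partition_total(self, c):
        assert classify_chain_length(c) in list(ChainLength)

    @given(st.integers(0, 40))
    def test_unsaturation_partition_total(self, d):
        assert classify_unsaturation(d) in list(Unsaturation)


class TestCompositionProfile:
    CORPUS = [
        ("PC32:0", 1.0),
        ("PC38:4(18:0/20:4)", 2.0),
        ("CL72:8(18:2)", 3.0),
        ("SM30:1(d18:1/12:0)", 0.5),
        ("PE36:1p(18:0p/18:1)", 1.5),
    ]

    def test_empty(self):
        prof = acyl_composition_profile([], [])
        assert prof.empty

    def test_length_mismatch(self):
        sp = parse_lipid_name("PC32:0")
        with pytest.raises(ValueError):
            acyl_composition_profile([sp], [1.0, 2.0])

    def test_sum_composition_species_by_totals_vs_by_acyl(self):
        sp = parse_lipid_name("PC32:0")
        by_tot = acyl_composition_profile([sp], [1.0], mode="by_totals")
        # 32 carbons total -> very_long, 0 double bonds -> saturated
        assert by_tot.loc["PC", ("very_long", "saturated")] == 1.0
        by_acyl = acyl_composition_profile([sp], [1.0], mode="by_acyl")
        assert by_acyl.to_numpy().sum() == 0.0  # no annotated acyls: skipped

    def test_profile_matches_brute_force_tally(self):
        species = [parse_lipid_name(n) for n, _ in self.CORPUS]
        abund = [a for _, a in self.CORPUS]
        prof = acyl_composition_profile(species, abund, mode="by_acyl")
        # independent brute-force tally over (species, acyl) pairs
        expected: dict = {}
        for sp, ab in zip(species, abund):
            for a in sp.acyls:
                lc = classify_chain_length(a.carbons).value
                uc = classify_unsaturation(a.double_bonds).value
                key = (sp.lipid_class, lc, uc)
                expected[key] = expected.get(key, 0.0) + ab / len(sp.acyls)
        for (cls, lc, uc), v in expected.items():
            assert prof.loc[cls, (lc, uc)] == pytest.approx(v)
        assert prof.to_numpy().sum() == pytest.approx(sum(v for v in expected.values()))

    def test_rows_sum_to_contributing_class_abundance(self):
        species = [parse_lipid_name(n) for n, _ in self.CORPUS]
        abund = [a for _, a in self.CORPUS]
        prof = acyl_composition_profile(species, abund, mode="by_totals")
        totals = pd.Series(abund, index=[s.lipid_class for s in species]).groupby(level=0).sum()
        for cls in prof.index:
            assert prof.loc[cls].sum() == pytest.approx(totals[cls])


class TestRegistry:
    def test_aliases_resolve_to_one_class(self):
        reg = default_registry()
        assert reg.resolve("BMP").code == "LBPA"
        assert reg.resolve("LBPA").code == "LBPA"

    def test_csv_round_trip(self, tmp_path):
        reg = default_registry()
        p = tmp_path / "registry.csv"
        reg.to_csv(p)
        reg2 = ClassRegistry.from_csv(p)
        assert reg2.resolve("BMP").code == "LBPA"
        assert reg2.resolve("PC").polar and not reg2.resolve("TAG").polar

    def test_new_class_without_code_change(self, tmp_path):
        p = tmp_path / "registry.csv"
        default_registry().to_csv(p)
        with open(p, "a") as fh:
            fh.write("PGP,pl,2,\n")
        reg = ClassRegistry.from_csv(p)
        sp = parse_lipid_name("PGP34:1", registry=reg)
        assert sp.lipid_class == "PGP" and sp.is_polar
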