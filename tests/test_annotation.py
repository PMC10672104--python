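"""Region delimitation, VNAR type rules and CDR3 descriptors."""
from __future__ import annotations

import json
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vnarpan import annotation as ann
from vnarpan.simulate import FR1, FR2, FR2_CYS, FR3A, FR3B, FR4, FR4_CYS, FrameworkTemplate

TEMPLATE = FrameworkTemplate("t0", cdr1="SNGALSST", hv2="RYVETVNS", hv4="SGSKV")
TEMPLATE_CDR1_CYS = FrameworkTemplate("t1", cdr1="SNCALSST", hv2="RYVETVNS", hv4="SGSKV")
TEMPLATE_TYPE_I = FrameworkTemplate(
    "t2", cdr1="SNGALSST", hv2="RYVETVNS", hv4="SGSKV", fr2=FR2_CYS, fr4=FR4_CYS
)

AA_NO_C = "".join(a for a in ann.STANDARD_AA if a != "C")


def test_planted_cdr3_recovered_exactly():
    protein = TEMPLATE.protein("ARSDTYAGCGYDC")
    domain = ann.annotate(protein)
    assert domain.cdr3 == "ARSDTYAGCGYDC"
    assert domain.region_seq("CDR1") == "SNGALSST"
    assert domain.region_seq("HV2") == "RYVETVNS"
    assert domain.region_seq("HV4") == "SGSKV"


def test_empty_cdr3_is_degenerate_but_valid():
    domain = ann.annotate(TEMPLATE.protein(""))
    assert domain.cdr3 == ""
    start, end = domain.regions["CDR3"]
    assert start == end


def test_regions_tile_protein_without_gaps():
    domain = ann.annotate(TEMPLATE.protein("ARSDTYAGYDV"))
    span_start, span_end = domain.span
    pos = span_start
    for name in ann.REGION_NAMES:
        start, end = domain.regions[name]
        assert start == pos
        pos = end
    assert pos == span_end == len(domain.protein)


def test_missing_anchor_rejected_as_non_vnar():
    with pytest.raises(ann.NotVnarError, match="FR3a"):
        ann.annotate(FR1 + "SNGALSST" + FR2 + "NOANCHORHERE")
    with pytest.raises(ValueError):
        ann.annotate("")


def test_multiple_anchor_matches_use_leftmost_and_warn():
    protein = TEMPLATE.protein("ARS" + FR3B + "DV")  # second FR3b inside CDR3
    domain = ann.annotate(protein)
    assert any("FR3b" in w for w in domain.warnings)
    assert domain.cdr3.startswith("ARS")


def test_annotation_matches_bruteforce_regex_oracle(small_scenario):
    """Motif-anchored extraction equals a one-shot lazy-regex scan."""
    oracle = re.compile(r"EDSGTYYC(.*?)[DE]GAGT[AK]VTV[NC]")
    for i in range(len(small_scenario.clones)):
        protein = small_scenario.clone_protein(i)
        m = oracle.search(protein)
        assert ann.annotate(protein).cdr3 == m.group(1)
        assert ann.extract_cdr3(protein) == m.group(1)


def test_planted_types_recovered(small_scenario):
    for i, clone in enumerate(small_scenario.clones):
        domain = ann.annotate(small_scenario.clone_protein(i))
        assert domain.vnar_type == clone.vnar_type, clone.clone_id


@pytest.mark.parametrize(
    "template,cdr3,expected",
    [
        (TEMPLATE, "ARSDCTYCGYDV", "V"),  # two CDR3 Cys, no CDR1 Cys
        (TEMPLATE_CDR1_CYS, "ARSDCTYAGYDV", "II"),  # CDR1 Cys + one CDR3 Cys
        (TEMPLATE, "ARSDTTYAGYDV", "IV"),  # no noncanonical Cys at all
        (TEMPLATE_TYPE_I, "ARSDTTYAGYDV", "I"),  # FR2+FR4 Cys, even (0) CDR3 Cys
        (TEMPLATE_TYPE_I, "ARCDTTYACYDV", "I"),  # FR2+FR4 Cys, even (2) CDR3 Cys
    ],
)
def test_default_type_rule_table(template, cdr3, expected):
    assert ann.annotate(template.protein(cdr3)).vnar_type == expected


def test_type_iii_requires_trp_adjacent_to_cdr1_cys():
    with_trp = FrameworkTemplate("t3", cdr1="SNCWLSST", hv2="RYVETVNS", hv4="SGSKV")
    assert ann.annotate(with_trp.protein("ARSDCTYAGYDV")).vnar_type == "III"
    assert ann.annotate(TEMPLATE_CDR1_CYS.protein("ARSDCTYAGYDV")).vnar_type == "II"


@given(st.text(alphabet=AA_NO_C, min_size=5, max_size=30))
@settings(deadline=None, max_examples=60)
def test_type_is_pure_function_of_cysteines_and_cdr3(cdr3_tail):
    """Permuting non-Cys CDR3 residues never changes the type call."""
    cdr3 = "C" + cdr3_tail + "C"
    base = ann.annotate(TEMPLATE.protein(cdr3)).vnar_type
    scrambled = "C" + cdr3_tail[::-1] + "C"
    assert ann.annotate(TEMPLATE.protein(scrambled)).vnar_type == base == "V"


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def test_descriptor_examples():
    d = ann.cdr3_descriptors("AYIRW")
    assert (d.aromatic_count, d.net_charge) == (3, 1)
    empty = ann.cdr3_descriptors("")
    assert (empty.length, empty.net_charge, empty.aromatic_count, empty.cys_count) == (
        0,
        0,
        0,
        0,
    )
    with pytest.raises(ValueError):
        ann.cdr3_descriptors("AXB")


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=20))
@settings(deadline=None, max_examples=150)
def test_descriptors_equal_bruteforce_tally(cdr3):
    d = ann.cdr3_descriptors(cdr3)
    assert d.length == len(cdr3)
    assert d.aromatic_count == sum(c in "IYFW" for c in cdr3)
    assert d.net_charge == sum(+1 for c in cdr3 if c in "RK") - sum(
        1 for c in cdr3 if c in "DE"
    )
    assert d.cys_count == cdr3.count("C")
    assert 0 <= d.aromatic_count <= d.length


def test_chemical_aromatic_set_excludes_ile():
    d = ann.cdr3_descriptors("AYIRW", aromatic_set=ann.AROMATIC_CHEMICAL)
    assert d.aromatic_count == 2


# ---------------------------------------------------------------------------
# residue differences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected", [("AAAA", "AAAA", 0), ("AAAA", "ABBA", 2), ("AA", "AAA", None)]
)
def test_residue_differences(a, b, expected):
    assert ann.residue_differences(a, b) == expected


@given(
    st.integers(5, 20).flatmap(
        lambda n: st.tuples(
            st.text(alphabet="ACDEFG", min_size=n, max_size=n),
            st.text(alphabet="ACDEFG", min_size=n, max_size=n),
        )
    )
)
@settings(deadline=None, max_examples=100)
def test_residue_differences_is_hamming(pair):
    a, b = pair
    assert ann.residue_differences(a, b) == sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_anchor_config_validation():
    with pytest.raises(ValueError, match="Cys"):
        ann.AnchorConfig(fr1="A", fr2="B", fr3a="D", cdr3_n_anchor="EDSGTYYE", cdr3_c_anchor="F")
    with pytest.raises(ValueError, match="Cys"):
        ann.AnchorConfig(fr1="A", fr2="B", fr3a="D", cdr3_n_anchor="CEDSGTYYC", cdr3_c_anchor="F")
    with pytest.raises(ValueError, match="empty"):
        ann.AnchorConfig(fr1="", fr2="B", fr3a="D", cdr3_n_anchor="C", cdr3_c_anchor="F")


def test_anchor_and_rule_configs_roundtrip_json(tmp_path):
    path = tmp_path / "anchors.json"
    ann.DEFAULT_ANCHORS.to_json(path)
    assert ann.AnchorConfig.from_json(path) == ann.DEFAULT_ANCHORS

    rules_path = tmp_path / "rules.json"
    rules_path.write_text(
        json.dumps(
            [
                {"label": "V", "cdr3_cys": ">=2", "cys_not_in": ["CDR1"]},
                {"label": "IV", "no_noncanonical": True},
            ]
        )
    )
    rules = ann.type_rules_from_json(rules_path)
    domain = ann.annotate(TEMPLATE.protein("ARSDCTYCGYDV"), type_rules=rules)
    assert domain.vnar_type == "V"
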