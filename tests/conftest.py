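import hypothesis
import pytest
from hypothesis import strategies as st

from caffmr import AssociationTable, VariantAssociation

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def va(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-9, **kw):
    """Shorthand VariantAssociation factory for tests."""
    return VariantAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=p, **kw
    )


@pytest.fixture
def make_variant():
    return va


# -- hypothesis strategies -------------------------------------------------

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

finite_beta = st.floats(-2.0, 2.0, allow_nan=False, allow_infinity=False)
positive_se = st.floats(1e-4, 1.0, allow_nan=False, allow_infinity=False)


@st.composite
def variant_associations(draw, rsid=None, palindromic_ok=False):
    pairs = list(_ALLELE_PAIRS)
    if palindromic_ok:
        pairs += [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    ea, oa = draw(st.sampled_from(pairs))
    return VariantAssociation(
        rsid=rsid or draw(st.from_regex(r"rs[0-9]{1,7}", fullmatch=True)),
        effect_allele=ea,
        other_allele=oa,
        beta=draw(finite_beta),
        se=draw(positive_se),
        pvalue=draw(st.floats(1e-300, 1.0, allow_nan=False)),
        eaf=draw(st.one_of(st.none(), st.floats(0.01, 0.99))),
        n=draw(st.one_of(st.none(), st.integers(100, 10**6).map(float))),
        gene_label=draw(st.one_of(st.none(), st.sampled_from(["AHR", "CYP1A2"]))),
    )


@st.composite
def association_tables(draw, min_size=1, max_size=6):
    k = draw(st.integers(min_size, max_size))
    records = [
        draw(variant_associations(rsid=f"rs{i + 1}")) for i in range(k)
    ]
    return AssociationTable(records, trait_id="t", provenance="hypothesis")
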