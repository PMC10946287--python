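import hypothesis
import pytest
from hypothesis import strategies as st

from ribodb.taxio import TaxonomyString

hypothesis.settings.register_profile(
    "ribodb",
    derandomize=True,
    max_examples=50,
    deadline=None,
)
hypothesis.settings.load_profile("ribodb")

LINEAGE = (
    "Bacteria",
    "Firmicutes",
    "Bacilli",
    "Lactobacillales",
    "Lactobacillaceae",
)


def make_lineage(genus: str, species: str) -> TaxonomyString:
    """A Lactobacillaceae lineage with the given genus and species labels."""
    return TaxonomyString((*LINEAGE, genus, species))


# simple taxon-name alphabet: no separators used by the clustering grammar,
# and never the "Unknown" placeholder itself
name_st = (
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=8)
    .map(str.capitalize)
    .filter(lambda n: n != "Unknown")
)

label_st = st.one_of(st.just(""), name_st)

taxonomy_st = st.tuples(*([label_st] * 7)).map(TaxonomyString)

dna_st = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.fixture
def lactobacillaceae_lineages():
    """The three member lineages of the worked clustering example."""
    return [
        make_lineage("Limosilactobacillus", "Limosilactobacillus_fermentum"),
        make_lineage("Limosilactobacillus", "Limosilactobacillus_oris"),
        make_lineage("Lactobacillus", "Lactobacillus_crispatus"),
    ]
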