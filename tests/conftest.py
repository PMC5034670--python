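import pytest
from hypothesis import HealthCheck, settings

from gbdmap.lexicon import Concept, EnrichmentTable, Lexicon
from gbdmap.taxonomy import GBDCategory, GBDGrouping, packaged_grouping, parse_icd10

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gbd28():
    """The shipped 28-class grouping."""
    return packaged_grouping()


@pytest.fixture(scope="session")
def mini_grouping():
    """Tiny grouping with the classic P37-style split across categories."""
    return GBDGrouping(
        "mini",
        [
            GBDCategory("tuberculosis", "Tuberculosis"),
            GBDCategory("neglected_tropical", "Neglected tropical diseases excluding malaria"),
            GBDCategory("mental", "Mental and behavioral disorders"),
            GBDCategory("musculoskeletal", "Musculoskeletal disorders"),
            GBDCategory("other", "Other causes", residual=True),
        ],
        {
            "tuberculosis": [parse_icd10("A15-A19.9"), parse_icd10("P37.0")],
            "neglected_tropical": [parse_icd10("P37.3")],
            "mental": [parse_icd10("F04-F99.9")],
            "musculoskeletal": [parse_icd10("M00-M99.9")],
            "other": [parse_icd10("Z00-Z99.9")],
        },
    )


def _concept(cui, name, types=("T047",)):
    return Concept(cui, name, frozenset(types))


@pytest.fixture(scope="session")
def oa_lexicon():
    """Worked-example mini-lexicon: knee/hip osteoarthritis plus a parent.

    Hip osteoarthritis carries the M16/M16.9 crosswalk pair; the generic
    arthritis parent maps to a block, exercising hierarchy fallback.
    """
    concepts = {
        "C0409959": _concept("C0409959", "Osteoarthritis, Knee"),
        "C0029410": _concept("C0029410", "Osteoarthritis of hip"),
        "C0003864": _concept("C0003864", "Arthritis"),
        "C0029408": _concept("C0029408", "Degenerative polyarthritis"),
        # non-disorder concept sharing a term, to exercise the semantic filter
        "C0999999": _concept("C0999999", "Knee region", types=("T029",)),
    }
    terms = {
        "knee osteoarthritis": {"C0409959"},
        "osteoarthritis of knee": {"C0409959"},
        "hip osteoarthritis": {"C0029410"},
        "osteoarthritis of hip": {"C0029410", "C0003864"},
        "arthritis": {"C0003864"},
        "osteoarthritis": {"C0029408"},
        "knee": {"C0999999"},
    }
    parents = {"C0409959": {"C0003864"}, "C0029410": {"C0003864"}, "C0029408": {"C0003864"}}
    crosswalk = {
        "C0409959": (parse_icd10("M17"), parse_icd10("M17.9")),
        "C0029410": (parse_icd10("M16"), parse_icd10("M16.9")),
        "C0003864": (parse_icd10("M00-M25.9"),),
    }
    return Lexicon(
        concepts=concepts,
        terms=terms,
        parents=parents,
        crosswalk=crosswalk,
        disorder_types=frozenset({"T047"}),
    )


@pytest.fixture(scope="session")
def empty_enrichment():
    return EnrichmentTable({})


@pytest.fixture
def lexicon_bundle_dir(tmp_path):
    """Write a small, valid lexicon bundle to disk and return its directory."""
    d = tmp_path / "lex"
    d.mkdir()
    (d / "concepts.tsv").write_text(
        "cui\tpreferred_name\tsemantic_types\n"
        "C0000001\tAsthma\tT047\n"
        "C0000002\tRespiratory disorder\tT047\n"
        "C0000003\tWheeze\tT184\n",
        encoding="utf-8",
    )
    (d / "terms.tsv").write_text(
        "cui\tterm\nC0000001\tasthma\nC0000001\tbronchial asthma\nC0000003\twheeze\n",
        encoding="utf-8",
    )
    (d / "hierarchy.tsv").write_text(
        "child_cui\tparent_cui\nC0000001\tC0000002\n", encoding="utf-8"
    )
    (d / "crosswalk.tsv").write_text(
        "cui\ticd10_spec\nC0000002\tJ45\nC0000002\tJ45.9\n", encoding="utf-8"
    )
    return d
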