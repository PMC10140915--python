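"""Lectin-domain retention profiles, A/B/C family categorization (checked
exhaustively against a brute-force rule coding), and architecture
comparison."""

import itertools

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_hit
from ctlkit import categories, workflows
from ctlkit.io import Taxonomy


@pytest.fixture
def six_species_taxonomy():
    rows = [
        {"species_id": "biv1", "family": "Mytilidae", "class": "Bivalvia",
         "phylum": "Mollusca"},
        {"species_id": "biv2", "family": "Ostreidae", "class": "Bivalvia",
         "phylum": "Mollusca"},
        {"species_id": "biv3", "family": "Pectinidae", "class": "Bivalvia",
         "phylum": "Mollusca"},
        {"species_id": "ceph1", "family": "Octopodidae", "class": "Cephalopoda",
         "phylum": "Mollusca"},
        {"species_id": "chor1", "family": "Hominidae", "class": "Mammalia",
         "phylum": "Chordata"},
        {"species_id": "chor2", "family": "Salmonidae", "class": "Actinopteri",
         "phylum": "Chordata"},
    ]
    return Taxonomy(pd.DataFrame(rows))


def profile(status, og="OG1"):
    return categories.RetentionProfile(orthogroup_id=og, status=status)


def brute_force_category(status, bivalves, chordates, rho, epsilon):
    """Independent plain-python coding of the A/B/C rule."""
    outside = [sp for sp in status if sp not in bivalves]
    out_pres = (
        sum(status[sp] != "ABSENT" for sp in outside) / len(outside)
        if outside else 0.0
    )
    pres_biv = [sp for sp in bivalves if status.get(sp, "ABSENT") != "ABSENT"]
    biv_ret = (
        sum(status[sp] == "PRESENT_WITH_CTL" for sp in pres_biv) / len(pres_biv)
        if pres_biv else 0.0
    )
    pres_cho = [sp for sp in chordates if status.get(sp, "ABSENT") != "ABSENT"]
    cho_ret = (
        sum(status[sp] == "PRESENT_WITH_CTL" for sp in pres_cho) / len(pres_cho)
        if pres_cho else 0.0
    )
    if out_pres <= epsilon:
        return "C"
    if not pres_cho:
        return "UNCLASSIFIED"
    if cho_ret == 0 and biv_ret >= rho:
        return "B"
    if cho_ret >= rho:
        return "A"
    return "UNCLASSIFIED"


class TestRetentionProfile:
    def test_statuses(self):
        members = {"sp1": ["p1"], "sp2": ["p2"], "sp3": []}
        hits = {
            "p1": [make_hit("p1"), make_hit("p1", accession="PF00431",
                                            start=150, end=200)],
            "p2": [make_hit("p2", accession="PF00431")],
        }
        prof = categories.retention_profile("OG1", members, hits)
        assert prof.status == {
            "sp1": categories.PRESENT_WITH_CTL,
            "sp2": categories.PRESENT_WITHOUT_CTL,
            "sp3": categories.ABSENT,
        }

    def test_alternate_lectin_accession_counts_as_retention(self):
        members = {"sp1": ["p1"]}
        hits = {"p1": [make_hit("p1", accession="PF02140")]}  # Gal-lectin
        prof = categories.retention_profile(
            "OG1", members, hits, lectin_accessions=("PF00059", "PF02140")
        )
        assert prof.status["sp1"] == categories.PRESENT_WITH_CTL


class TestCategorize:
    def test_retained_everywhere_is_a(self, six_species_taxonomy):
        status = {sp: "PRESENT_WITH_CTL" for sp in six_species_taxonomy.species}
        call = categories.categorize(profile(status), six_species_taxonomy)
        assert call.category == "A"

    def test_chordate_loss_with_bivalve_retention_is_b(self, six_species_taxonomy):
        status = {
            "biv1": "PRESENT_WITH_CTL", "biv2": "PRESENT_WITH_CTL",
            "biv3": "PRESENT_WITH_CTL", "ceph1": "ABSENT",
            "chor1": "PRESENT_WITHOUT_CTL", "chor2": "PRESENT_WITHOUT_CTL",
        }
        call = categories.categorize(profile(status), six_species_taxonomy)
        assert call.category == "B"
        assert call.chordate_retention == 0.0
        assert call.bivalve_retention == 1.0

    def test_bivalve_only_is_c(self, six_species_taxonomy):
        status = {sp: "ABSENT" for sp in six_species_taxonomy.species}
        status.update(biv1="PRESENT_WITH_CTL", biv2="PRESENT_WITH_CTL")
        call = categories.categorize(profile(status), six_species_taxonomy)
        assert call.category == "C"
        assert call.outside_bivalvia_presence == 0.0

    def test_no_present_chordate_warns_unclassified(self, six_species_taxonomy):
        status = {sp: "ABSENT" for sp in six_species_taxonomy.species}
        status.update(biv1="PRESENT_WITH_CTL", ceph1="PRESENT_WITH_CTL")
        call = categories.categorize(profile(status), six_species_taxonomy)
        assert call.category == "UNCLASSIFIED"
        assert call.no_chordates_warning

    def test_exhaustive_against_brute_force(self, six_species_taxonomy):
        species = six_species_taxonomy.species
        bivalves = set(six_species_taxonomy.species_in("Bivalvia"))
        chordates = set(six_species_taxonomy.species_in("Chordata"))
        for combo in itertools.product(categories.STATUSES, repeat=6):
            status = dict(zip(species, combo))
            call = categories.categorize(
                profile(status), six_species_taxonomy, rho=0.5, epsilon=0.0
            )
            expected = brute_force_category(status, bivalves, chordates, 0.5, 0.0)
            assert call.category == expected, status

    def test_species_order_and_duplication_invariant(self, six_species_taxonomy):
        status = {
            "biv1": "PRESENT_WITH_CTL", "biv2": "PRESENT_WITH_CTL",
            "biv3": "ABSENT", "ceph1": "ABSENT",
            "chor1": "PRESENT_WITHOUT_CTL", "chor2": "ABSENT",
        }
        a = categories.categorize(profile(status), six_species_taxonomy)
        b = categories.categorize(
            profile(dict(reversed(list(status.items())))), six_species_taxonomy
        )
        assert a == b

    @given(st.integers(0, 3**6 - 1), st.floats(0, 1), st.floats(0, 1))
    def test_epsilon_monotone_toward_c(self, six_species_taxonomy, code, eps1, eps2):
        """Raising ε can only move calls into C, never out of it."""
        lo, hi = sorted((eps1, eps2))
        species = six_species_taxonomy.species
        status = {}
        for sp in species:
            status[sp] = categories.STATUSES[code % 3]
            code //= 3
        call_lo = categories.categorize(
            profile(status), six_species_taxonomy, epsilon=lo
        )
        call_hi = categories.categorize(
            profile(status), six_species_taxonomy, epsilon=hi
        )
        if call_lo.category == "C":
            assert call_hi.category == "C"


class TestCompareArchitectures:
    def test_category_b_shape(self):
        members = {"mussel": ["m1"], "human": ["h1"]}
        hits = {
            "m1": [make_hit("m1", start=10, end=120),
                   make_hit("m1", accession="PF00431", start=150, end=200)],
            "h1": [make_hit("h1", accession="PF00431", start=30, end=90)],
        }
        comp = categories.compare_architectures(
            "OG1", members, hits,
            representatives={"Bivalvia": "mussel", "Chordata": "human"},
            protein_lengths={"m1": 230, "h1": 120},
        )
        assert comp.architectures["mussel"] == ("PF00059", "PF00431")
        assert comp.architectures["human"] == ("PF00431",)

    def test_identical_architectures_match(self):
        hits = {
            p: [make_hit(p, start=10, end=120),
                make_hit(p, accession="PF00084", start=140, end=200)]
            for p in ("m1", "h1")
        }
        comp = categories.compare_architectures(
            "OG1", {"mussel": ["m1"], "human": ["h1"]}, hits,
            {"Bivalvia": "mussel", "Chordata": "human"},
            {"m1": 230, "h1": 230},
        )
        assert comp.architectures["mussel"] == comp.architectures["human"]

    def test_absent_representative_flagged(self):
        comp = categories.compare_architectures(
            "OG1", {"mussel": ["m1"]}, {"m1": [make_hit("m1")]},
            {"Bivalvia": "mussel", "Chordata": "human"}, {"m1": 160},
        )
        assert comp.missing_representatives == ("Chordata",)
        assert "human" not in comp.architectures

    def test_longest_member_chosen_ties_lexicographic(self):
        members = {"mussel": ["mB", "mA"]}
        hits = {
            "mA": [make_hit("mA")],
            "mB": [make_hit("mB", accession="PF00431")],
        }
        comp = categories.compare_architectures(
            "OG1", members, hits, {"Bivalvia": "mussel"},
            {"mA": 200, "mB": 200},
        )
        assert comp.architectures["mussel"] == ("PF00059",)

    def test_planted_architectures_reproduced(self, tiny_bundle):
        inputs = workflows.inputs_from_bundle(tiny_bundle)
        hbp = inputs.hits_by_protein
        truth_arch = tiny_bundle.truth["architecture"]
        lengths = dict(
            zip(inputs.isoform_map["protein_id"], inputs.isoform_map["length"])
        )
        checked = 0
        for og, cat in tiny_bundle.truth["ctldcp_category"].items():
            members = inputs.orthogroups.members_of(og)
            reps = {}
            for sp in sorted(members):
                if members[sp]:
                    reps[sp] = sp
            comp = categories.compare_architectures(
                og, members, hbp, reps, lengths
            )
            for sp, accs in comp.architectures.items():
                chosen = max(sorted(members[sp]), key=lambda p: lengths.get(p, 0))
                assert list(accs) == truth_arch[chosen]
                checked += 1
        assert checked > 0
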