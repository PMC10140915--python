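"""Presence/absence matrices, PCA and heatmap ordering, and the
conservation-level rule (checked exhaustively against a brute-force
evaluator on a toy taxonomy)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_hit
from ctlkit import conservation, repertoire, workflows
from ctlkit.io import OrthogroupTable, Taxonomy


def pam(matrix: dict, taxonomy: Taxonomy) -> conservation.PresenceAbsenceMatrix:
    df = pd.DataFrame.from_dict(
        matrix, orient="index", columns=taxonomy.species
    )
    return conservation.PresenceAbsenceMatrix(matrix=df, taxonomy=taxonomy)


def brute_force_level(present, taxonomy, theta):
    """Independent re-statement of the conservation rule with plain loops."""
    def cov(spp):
        return sum(1 for s in spp if s in present) / len(spp)

    for rank in ("phylum", "class"):
        for taxon in sorted(taxonomy.groups(rank)):
            if cov(taxonomy.groups(rank)[taxon]) >= theta:
                return {"phylum": "PHYLUM", "class": "CLASS"}[rank], taxon
    fams = [
        f for f in sorted(taxonomy.groups("family"))
        if cov(taxonomy.groups("family")[f]) >= theta
    ]
    for cls in sorted(taxonomy.groups("class")):
        in_class = [f for f in fams if taxonomy.class_of_family(f) == cls]
        if len(in_class) >= 2:
            return "MULTI_FAMILY", cls
    if len(fams) == 1:
        return "FAMILY", fams[0]
    return "RESTRICTED", None


class TestBuildMatrix:
    def _setup(self, toy_taxonomy8):
        calls = {
            "a1": repertoire.ArchitectureCall("a1", repertoire.CTL, 1, ()),
            "b1": repertoire.ArchitectureCall("b1", repertoire.CTL, 1, ()),
            "c1": repertoire.ArchitectureCall("c1", repertoire.OTHER, 0, ()),
        }
        members = {
            "OG1": {sp: [] for sp in toy_taxonomy8.species},
            "OG2": {sp: [] for sp in toy_taxonomy8.species},
        }
        members["OG1"]["f1s1"] = ["a1"]
        members["OG1"]["f1s2"] = ["b1"]
        members["OG2"]["f2s1"] = ["c1"]
        og = OrthogroupTable(species=list(toy_taxonomy8.species), members=members)
        return og, calls

    def test_presence_row_and_other_exclusion(self, toy_taxonomy8):
        og, calls = self._setup(toy_taxonomy8)
        M = conservation.build_presence_matrix(og, calls, toy_taxonomy8)
        assert M.orthogroups == ["OG1"]  # OTHER-only orthogroup excluded
        row = M.matrix.loc["OG1"]
        assert row["f1s1"] == 1 and row["f1s2"] == 1 and row["f2s1"] == 0

    def test_unknown_species_errors(self, toy_taxonomy8):
        og, calls = self._setup(toy_taxonomy8)
        og.species[0] = "mystery"
        og.members["OG1"]["mystery"] = og.members["OG1"].pop("f1s1")
        og.members["OG2"]["mystery"] = og.members["OG2"].pop("f1s1")
        with pytest.raises(ValueError, match="mystery"):
            conservation.build_presence_matrix(og, calls, toy_taxonomy8)

    def test_planted_row_count(self, default_bundle):
        inputs = workflows.inputs_from_bundle(default_bundle)
        calls, _, _ = workflows.classify_and_census(inputs)
        M = conservation.build_presence_matrix(
            inputs.orthogroups, calls, inputs.taxonomy, repertoire.CTL
        )
        assert M.matrix.shape[0] == len(default_bundle.truth["conservation"])


class TestPCA:
    def test_identical_species_identical_coordinates(self, toy_taxonomy8):
        M = pam(
            {"OG1": [1, 1, 0, 0, 0, 0, 1, 1], "OG2": [0, 0, 1, 1, 1, 1, 0, 0]},
            toy_taxonomy8,
        )
        res = conservation.pca_species(M)
        c = res.coordinates
        np.testing.assert_allclose(c.loc["f1s1"], c.loc["f1s2"], atol=1e-12)

    def test_total_variance_equals_eigenvalue_sum(self, toy_taxonomy8):
        rng = np.random.default_rng(5)
        M = pam(
            {f"OG{i}": list(rng.integers(0, 2, 8)) for i in range(1, 8)},
            toy_taxonomy8,
        )
        res = conservation.pca_species(M, n_components=7)
        coord_var = res.coordinates.to_numpy().var(axis=0, ddof=1).sum()
        assert coord_var == pytest.approx(res.explained_variance.sum())

    def test_degenerate_matrix_errors(self, toy_taxonomy8):
        M = pam({"OG1": [1] * 8, "OG2": [1] * 8}, toy_taxonomy8)
        with pytest.raises(ValueError, match="variance"):
            conservation.pca_species(M)

    def test_family_exclusive_orthogroups_cluster_in_pc_space(self, default_bundle):
        """Species sharing family-specific orthogroups sit closer in PC
        space than species of different families."""
        inputs = workflows.inputs_from_bundle(default_bundle)
        calls, _, _ = workflows.classify_and_census(inputs)
        M, _ = workflows.conservation_calls(inputs, calls)
        res = conservation.pca_species(M, n_components=2)
        tax = inputs.taxonomy.table.set_index("species_id")
        coords = res.coordinates
        within, between = [], []
        species = [s for s in coords.index if tax.loc[s, "phylum"] == "Mollusca"]
        for a, b in itertools.combinations(species, 2):
            d = np.linalg.norm(coords.loc[a] - coords.loc[b])
            (within if tax.loc[a, "family"] == tax.loc[b, "family"] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self, toy_taxonomy8):
        M = pam(
            {"OGa": [1, 1, 0, 0, 0, 0, 0, 1],
             "OGz": [1, 1, 0, 0, 0, 0, 0, 1],
             "OGm": [0, 0, 1, 1, 1, 0, 0, 0]},
            toy_taxonomy8,
        )
        rows, _ = conservation.cluster_heatmap_order(M)
        assert abs(rows.index("OGa") - rows.index("OGz")) == 1

    def test_block_structure_keeps_blocks_contiguous(self, toy_taxonomy8):
        M = pam(
            {f"OGa{i}": [1, 1, 1, 1, 0, 0, 0, 0] for i in range(3)}
            | {f"OGb{i}": [0, 0, 0, 0, 1, 1, 1, 1] for i in range(3)},
            toy_taxonomy8,
        )
        _, cols = conservation.cluster_heatmap_order(M)
        block1 = {c: cols.index(c) for c in ["f1s1", "f1s2", "f2s1", "f2s2"]}
        idx = sorted(block1.values())
        assert idx == list(range(idx[0], idx[0] + 4))

    def test_row_order_invariant_to_input_permutation(self, toy_taxonomy8):
        rows = {
            "OG1": [1, 1, 0, 0, 0, 0, 0, 1],
            "OG2": [0, 0, 1, 1, 1, 0, 0, 0],
            "OG3": [1, 0, 1, 0, 1, 0, 1, 0],
        }
        orders = []
        for perm in itertools.permutations(rows):
            M = pam({k: rows[k] for k in perm}, toy_taxonomy8)
            orders.append(conservation.cluster_heatmap_order(M))
        assert all(o == orders[0] for o in orders)


class TestConservationRule:
    def test_full_presence_is_phylum(self, toy_taxonomy8):
        M = pam({"OG1": [1] * 8}, toy_taxonomy8)
        call = conservation.assign_conservation_level(M, "OG1")
        assert (call.level, call.anchor_taxon) == ("PHYLUM", "p1")

    def test_one_class_full_other_empty_is_class(self, toy_taxonomy8):
        M = pam({"OG1": [1, 1, 1, 1, 0, 0, 0, 0]}, toy_taxonomy8)
        call = conservation.assign_conservation_level(M, "OG1", theta=0.9)
        assert (call.level, call.anchor_taxon) == ("CLASS", "c1")
        assert call.coverage_by_taxon["c1"] == 1.0

    def test_two_families_in_one_class_is_multi_family(self):
        # classes of 4 families so two full families stay below class θ
        rows = []
        for cls in ("c1", "c2"):
            for f in range(4):
                fam = f"{cls}f{f}"
                for i in (1, 2):
                    rows.append({"species_id": f"{fam}s{i}", "family": fam,
                                 "class": cls, "phylum": "p1"})
        tax = Taxonomy(pd.DataFrame(rows))
        present = {f"c1f0s{i}" for i in (1, 2)} | {f"c1f1s{i}" for i in (1, 2)}
        M = pam({"OG1": [1 if s in present else 0 for s in tax.species]}, tax)
        call = conservation.assign_conservation_level(M, "OG1", theta=0.9)
        assert (call.level, call.anchor_taxon) == ("MULTI_FAMILY", "c1")

    def test_missing_orthogroup_errors(self, toy_taxonomy8):
        M = pam({"OG1": [1] * 8}, toy_taxonomy8)
        with pytest.raises(ValueError, match="OG9"):
            conservation.assign_conservation_level(M, "OG9")

    def test_exhaustive_against_brute_force(self, toy_taxonomy8):
        species = toy_taxonomy8.species
        for bits in itertools.product((0, 1), repeat=8):
            if not any(bits):
                continue
            M = pam({"OG1": list(bits)}, toy_taxonomy8)
            call = conservation.assign_conservation_level(M, "OG1", theta=0.9)
            present = {s for s, b in zip(species, bits) if b}
            level, anchor = brute_force_level(present, toy_taxonomy8, 0.9)
            assert (call.level, call.anchor_taxon) == (level, anchor), bits

    def test_monotone_within_single_class(self):
        """Adding a presence never demotes the call when all families share
        one class (the regime the rule is designed for)."""
        rows = [
            {"species_id": f"f{f}s{i}", "family": f"f{f}", "class": "c1",
             "phylum": "p1"}
            for f in range(3) for i in range(3)
        ]
        tax = Taxonomy(pd.DataFrame(rows))
        order = {lvl: i for i, lvl in enumerate(conservation.LEVELS)}
        rng = np.random.default_rng(2)
        for _ in range(200):
            bits = rng.integers(0, 2, 9)
            if not bits.any():
                bits[0] = 1
            M0 = pam({"OG1": list(bits)}, tax)
            lvl0 = conservation.assign_conservation_level(M0, "OG1").level
            zeros = np.flatnonzero(bits == 0)
            if not zeros.size:
                continue
            bits2 = bits.copy()
            bits2[rng.choice(zeros)] = 1
            M1 = pam({"OG1": list(bits2)}, tax)
            lvl1 = conservation.assign_conservation_level(M1, "OG1").level
            assert order[lvl1] <= order[lvl0]

    def test_strictness_at_theta_one(self, toy_taxonomy8):
        M = pam({"OG1": [1, 1, 1, 0, 0, 0, 0, 0]}, toy_taxonomy8)
        call = conservation.assign_conservation_level(M, "OG1", theta=1.0)
        assert call.level == "FAMILY"  # f1 complete; c1 is not


class TestTolerantClassCall:
    def _matrix(self, n_present, n_total):
        rows = [
            {"species_id": f"s{i:02d}", "family": "fam", "class": "Bivalvia",
             "phylum": "Mollusca"}
            for i in range(n_total)
        ]
        tax = Taxonomy(pd.DataFrame(rows))
        bits = [1] * n_present + [0] * (n_total - n_present)
        return pam({"OG1": bits}, tax)

    def test_single_exception_tolerated(self):
        M = self._matrix(11, 12)
        assert conservation.tolerant_class_call(M, "OG1", "Bivalvia") is True

    def test_two_exceptions_rejected(self):
        M = self._matrix(10, 12)
        assert conservation.tolerant_class_call(M, "OG1", "Bivalvia") is False

    @pytest.mark.parametrize("n", range(2, 21))
    def test_equivalent_to_theta_rule(self, n):
        for n_present in range(1, n + 1):
            M = self._matrix(n_present, n)
            tol = conservation.tolerant_class_call(
                M, "OG1", "Bivalvia", max_exceptions=1
            )
            theta = (n - 1) / n
            assert tol == (n_present / n >= theta)
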