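"""Seed groups, cutoff derivation, single-linkage clone calling and
nomenclature classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonekit import njtree, synonymy
from clonekit.core import DistanceMatrix, EmptyInputError, ParameterError
from clonekit.synonymy import CloneGrouping, SeedGroup


def meta_frame(rows):
    """rows: (sample_id, cultivar_name, synonym_group). Builds the
    normalised table the metadata reader would produce."""
    from clonekit.core import is_unknown_name, normalise_name

    df = pd.DataFrame(rows, columns=["sample_id", "cultivar_name",
                                     "synonym_group"])
    df["is_unknown"] = df["cultivar_name"].map(is_unknown_name)
    df["name_key"] = df["cultivar_name"].map(normalise_name)
    df.loc[df["is_unknown"], "name_key"] = ""
    return df


@pytest.fixture
def named_tree():
    # cherries: (KM_a, KM_b) same name; (OH, HKP7) known synonyms;
    # (NMT1, WC) different names; KM_c same-named but not a sister
    nwk = ("(((KM_a:0.01,KM_b:0.01):0.1,(OH:0.02,HKP7:0.02):0.1):0.05,"
           "(NMT1:0.03,WC:0.03):0.1,KM_c:0.2);")
    tree = njtree.parse_newick(nwk)
    samples = meta_frame([
        ("KM_a", "Kwai Mi", ""),
        ("KM_b", "Kwai Mi", ""),
        ("KM_c", "Kwai Mi", ""),
        ("OH", "O-Hia", "syn1"),
        ("HKP7", "Hak Ip", "syn1"),
        ("NMT1", "No Mai Tsze", ""),
        ("WC", "Wai Chee", ""),
    ])
    return tree, samples


class TestSisterPairs:
    def test_same_name_and_synonym_cherries_found(self, named_tree):
        tree, samples = named_tree
        pairs = synonymy.find_same_name_sister_pairs(tree, samples)
        assert ("KM_a", "KM_b") in pairs
        assert ("HKP7", "OH") in pairs       # via synonym group
        assert ("NMT1", "WC") not in pairs   # sisters, different names
        assert all("KM_c" not in p for p in pairs)  # same name, not sister


class TestSeedGroups:
    def _dist(self, labels, close=0.02, far=0.3):
        n = len(labels)
        v = np.full((n, n), far)
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(values=v, labels=labels), v

    def test_sister_pairs_become_size2_groups(self, named_tree):
        tree, samples = named_tree
        labels = sorted(s for s in samples["sample_id"])
        D, v = self._dist(labels)
        groups = synonymy.find_seed_groups(tree, samples, D)
        members = {g.members for g in groups}
        assert ("KM_a", "KM_b") in members
        assert ("HKP7", "OH") in members

    def test_max_extra_limits_group(self):
        # two same-named tips separated by two others: the minimal
        # clade spanning them carries 2 extras, so it qualifies at
        # max_extra=2 but not at max_extra=1
        nwk = ("(((HK1:0.01,(o1:0.01,o2:0.01):0.01):0.01,HK2:0.02):0.1,"
               "far1:0.3,far2:0.3);")
        tree = njtree.parse_newick(nwk)
        samples = meta_frame([
            ("HK1", "Hak Ip", ""), ("HK2", "Hak Ip", ""),
            ("o1", "Other1", ""), ("o2", "Other2", ""),
            ("far1", "Far1", ""), ("far2", "Far2", ""),
        ])
        labels = sorted(samples["sample_id"])
        n = len(labels)
        v = np.full((n, n), 0.04)
        for far in ("far1", "far2"):  # the outliers are genuinely far
            i = labels.index(far)
            v[i, :] = v[:, i] = 0.25
        v[labels.index("far1"), labels.index("far2")] = 0.25
        np.fill_diagonal(v, 0)
        D = DistanceMatrix(values=v, labels=labels)
        g2 = synonymy.find_seed_groups(tree, samples, D, max_extra=2)
        assert {"HK1", "HK2", "o1", "o2"} in [set(g.members) for g in g2]
        with pytest.raises(EmptyInputError):
            synonymy.find_seed_groups(tree, samples, D, max_extra=1)

    def test_expansion_prefers_most_same_named_members(self, small_cohort,
                                                       meta):
        from clonekit import distance

        G, samples, truth, _ = small_cohort
        table = meta(samples)
        D = distance.distance_matrix(G)
        tree = njtree.nj(D)
        groups = synonymy.find_seed_groups(tree, table, D)
        got = {g.members for g in groups}
        # every true clone group sharing a name appears as a seed group
        for g in truth.groups():
            assert tuple(sorted(g)) in got

    def test_no_seed_groups_is_explicit_error(self):
        nwk = "((A:0.1,B:0.1):0.1,C:0.1,D:0.1);"
        tree = njtree.parse_newick(nwk)
        samples = meta_frame([(s, f"name{s}", "") for s in "ABCD"])
        v = np.full((4, 4), 0.2)
        np.fill_diagonal(v, 0)
        D = DistanceMatrix(values=v, labels=list("ABCD"))
        with pytest.raises(EmptyInputError, match="cutoff"):
            synonymy.find_seed_groups(tree, samples, D)


class TestDeriveCutoff:
    def test_printed_group_maxima(self):
        # the six within-group distance maxima printed for the
        # collection's seed groups
        maxima = [0.0651, 0.0442, 0.0413, 0.0564, 0.0482, 0.0482]
        assert synonymy.derive_cutoff(maxima) == 0.0651

    def test_single_group_and_zero_distance(self):
        g = SeedGroup(members=("a", "b"), anchor="x", max_distance=0.02)
        assert synonymy.derive_cutoff([g]) == 0.02
        z = SeedGroup(members=("a", "b"), anchor="x", max_distance=0.0)
        assert synonymy.derive_cutoff([z]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            synonymy.derive_cutoff([])


def brute_force_components(values, cutoff):
    n = values.shape[0]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(
                v for v in range(n)
                if v != u and values[u, v] <= cutoff and v not in comp
            )
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestCloneGroups:
    def test_single_link_chaining(self):
        v = np.array([[0, 0.03, 0.09], [0.03, 0, 0.05], [0.09, 0.05, 0]])
        D = DistanceMatrix(values=v, labels=["1", "2", "3"])
        g = synonymy.clone_groups(D, 0.0651)
        assert g.groups == [["1", "2", "3"]]

    def test_cutoff_below_everything_all_singletons(self):
        v = np.array([[0, 0.2], [0.2, 0]])
        D = DistanceMatrix(values=v, labels=["a", "b"])
        g = synonymy.clone_groups(D, 0.1)
        assert g.groups == [] and g.singletons == ["a", "b"]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20),
           st.floats(0.0, 0.3))
    def test_matches_reachability_oracle(self, seed, n, cutoff):
        rng = np.random.default_rng(seed)
        v = np.triu(rng.uniform(0, 0.4, size=(n, n)), 1)
        v = v + v.T
        labels = [f"s{i}" for i in range(n)]
        D = DistanceMatrix(values=v, labels=labels)
        g = synonymy.clone_groups(D, cutoff)
        got = {frozenset(labels.index(s) for s in grp) for grp in g.groups}
        got |= {frozenset([labels.index(s)]) for s in g.singletons}
        assert got == brute_force_components(v, cutoff)

    def test_sample_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(11)
        n = 12
        v = np.triu(rng.uniform(0, 0.2, size=(n, n)), 1)
        v = v + v.T
        labels = [f"s{i}" for i in range(n)]
        D = DistanceMatrix(values=v, labels=labels)
        g1 = synonymy.clone_groups(D, 0.05)
        perm = rng.permutation(n)
        D2 = DistanceMatrix(values=v[np.ix_(perm, perm)],
                            labels=[labels[i] for i in perm])
        g2 = synonymy.clone_groups(D2, 0.05)
        assert sorted(map(tuple, g1.groups)) == sorted(map(tuple, g2.groups))
        # raising the cutoff never splits a group
        g_hi = synonymy.clone_groups(D, 0.1)
        merged = {s: i for i, grp in enumerate(g_hi.groups) for s in grp}
        for grp in g1.groups:
            assert len({merged.get(s, -1) for s in grp}) == 1

    def test_negative_cutoff_rejected(self):
        v = np.zeros((2, 2))
        D = DistanceMatrix(values=v, labels=["a", "b"])
        with pytest.raises(ParameterError):
            synonymy.clone_groups(D, -0.1)


class TestNomenclature:
    def _report(self):
        grouping = CloneGrouping(
            cutoff=0.05,
            groups=[
                ["UNK9", "ITO"],                # unknown + one name
                ["NMT1", "UNK1", "UNK2"],       # unknown(s) + one name
                ["SAL1", "WC"],                 # two names: synonym set
                ["NMT5", "UNK12"],
            ],
            singletons=["NMT3", "KMN", "UNK5"],
        )
        samples = meta_frame([
            ("UNK9", "UNKNOWN", ""), ("ITO", "Ito", ""),
            ("NMT1", "No Mai Tsze", ""), ("UNK1", "UNKNOWN", ""),
            ("UNK2", "UNKNOWN", ""),
            ("SAL1", "Salathiel", ""), ("WC", "Wai Chee", ""),
            ("NMT5", "No Mai Tsze", ""), ("UNK12", "UNKNOWN", ""),
            ("NMT3", "No Mai Tsze", ""), ("KMN", "Kaimana", ""),
            ("UNK5", "UNKNOWN", ""),
        ])
        return synonymy.classify_nomenclature(grouping, samples), grouping

    def test_unknown_suggestions(self):
        report, _ = self._report()
        assert report.unknown_suggestions["UNK9"] == "Ito"
        assert report.unknown_suggestions["UNK1"] == "No Mai Tsze"
        assert report.unknown_suggestions["UNK5"] is None

    def test_synonym_sets_and_homonyms(self):
        report, grouping = self._report()
        assert any(names == ["Salathiel", "Wai Chee"]
                   for _, names in report.synonym_sets)
        # No Mai Tsze sits in two groups and one singleton: homonym
        assert report.homonyms["No Mai Tsze"] == 3
        assert "Kaimana" not in report.homonyms

    def test_consistent_single_name_group_not_reported(self):
        grouping = CloneGrouping(cutoff=0.01, groups=[["a", "b"]],
                                 singletons=[])
        samples = meta_frame([("a", "Same", ""), ("b", "Same", "")])
        report = synonymy.classify_nomenclature(grouping, samples)
        assert not report.synonym_sets and not report.homonyms


class TestGroupingIo:
    def test_tsv_round_trip(self, tmp_path):
        grouping = CloneGrouping(
            cutoff=0.05, groups=[["a", "b", "c"], ["d", "e"]],
            singletons=["f"],
        )
        path = tmp_path / "g.tsv"
        synonymy.write_clone_groups_tsv(grouping, path)
        back = synonymy.read_clone_groups_tsv(path)
        assert back.groups == grouping.groups
        assert back.singletons == grouping.singletons

    def test_duplicate_membership_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("group_id\tsample_id\nG1\ta\nG2\ta\n")
        with pytest.raises(ParameterError):
            synonymy.read_clone_groups_tsv(p)
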