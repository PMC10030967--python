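"""Profile matrices, correlations, sharing counts, clade mining."""

import itertools

import numpy as np
import pandas as pd
import pytest

from synnetflow.profiling import (
    CladeDefinition,
    PhyloProfile,
    build_profile,
    clade_specific_clusters,
    sharing_counts,
    species_correlation,
)

from conftest import ranked_genome


@pytest.fixture
def small_profile():
    counts = pd.DataFrame(
        [[2, 1, 0], [0, 1, 1], [1, 1, 1], [3, 0, 0]],
        index=[0, 1, 2, 3], columns=["spA", "spB", "spC"])
    return PhyloProfile(counts)


class TestBuildProfile:
    def test_counts_and_binary(self):
        ga = ranked_genome("A", {"chr1": 4})
        gb = ranked_genome("B", {"chr1": 4})
        clusters = [(0, frozenset({"A_chr1_0", "A_chr1_1", "B_chr1_0"})),
                    (1, frozenset({"B_chr1_1", "B_chr1_2"}))]
        p = build_profile(clusters, {"A": ga, "B": gb})
        assert p.counts.loc[0].tolist() == [2, 1]
        assert p.binary.loc[0].tolist() == [1, 1]
        assert p.binary.loc[1].tolist() == [0, 1]
        assert set(np.unique(p.binary)) <= {0, 1}

    def test_gene_conservation(self, zero_noise_run):
        p = zero_noise_run["profile"]
        g = zero_noise_run["graph"]
        by_species: dict = {}
        for node in g.nodes:
            sp = node.split("_", 1)[0]
            by_species[sp] = by_species.get(sp, 0) + 1
        for sp, n in by_species.items():
            assert p.counts[sp].sum() == n

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            PhyloProfile(pd.DataFrame([[1, 0], [0, 0]], columns=["a", "b"]))


class TestSpeciesCorrelation:
    def test_identical_profiles_correlate_fully(self):
        counts = pd.DataFrame([[1, 1, 0], [0, 0, 1], [2, 3, 0]],
                              columns=["spA", "spB", "spC"])
        corr = species_correlation(PhyloProfile(counts), on="binary")
        assert corr.loc["spA", "spB"] == pytest.approx(1.0)

    def test_opposite_profiles_anticorrelate(self):
        counts = pd.DataFrame({"spA": [1, 1, 0, 0], "spB": [0, 0, 1, 1]})
        corr = species_correlation(PhyloProfile(counts), on="binary")
        assert corr.loc["spA", "spB"] == pytest.approx(-1.0)

    def test_matrix_is_valid_correlation(self, small_profile):
        corr = species_correlation(small_profile, on="counts")
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert ((corr.to_numpy() >= -1 - 1e-12) & (corr.to_numpy() <= 1 + 1e-12)).all()

    def test_zero_variance_column_warns_and_is_nan(self):
        counts = pd.DataFrame({"spA": [1, 1], "spB": [1, 0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = species_correlation(PhyloProfile(counts), on="binary")
        assert np.isnan(corr.loc["spA", "spB"])
        assert corr.loc["spA", "spA"] == 1.0

    def test_within_clade_exceeds_between_clade(self, zero_noise_run):
        """Planted structure: species of one clade share more clusters."""
        from synnetflow.simulate import DEMO_CLADES
        corr = species_correlation(zero_noise_run["profile"], on="binary")
        within, between = [], []
        for a in corr.index:
            for b in corr.columns:
                if a >= b:
                    continue
                ca = next(k for k, v in DEMO_CLADES.items() if a in v)
                cb = next(k for k, v in DEMO_CLADES.items() if b in v)
                (within if ca == cb else between).append(corr.loc[a, b])
        assert np.mean(within) > np.mean(between)


def brute_sharing(binary, clades, min_presence):
    """Oracle: enumerate clusters, assign each to its exact clade set."""
    table: dict = {}
    for c in binary.index:
        quals = []
        for name, species in clades.items():
            present = sum(binary.loc[c, s] for s in species if s in binary.columns)
            if present >= min_presence[name]:
                quals.append(name)
        if quals:
            key = tuple(sorted(quals))
            table[key] = table.get(key, 0) + 1
    return table


class TestSharingCounts:
    clades = CladeDefinition(
        {"X": ["spA", "spB", "spC", "spD", "spE", "spF"], "Y": ["spG", "spH"]},
        {"X": 4, "Y": 2})

    def _profile(self, x_present, elsewhere=0):
        row = {s: 1 if i < x_present else 0
               for i, s in enumerate(self.clades.clades["X"])}
        row.update({s: 1 if i < elsewhere else 0
                    for i, s in enumerate(self.clades.clades["Y"])})
        extra = {s: 1 for s in row}  # second, universal cluster
        return PhyloProfile(pd.DataFrame([row, extra], index=[0, 1]))

    def test_cluster_meeting_threshold_counts_as_specific(self):
        table = sharing_counts(self._profile(x_present=4), self.clades)
        as_dict = dict(zip(table["clades"], table["n_clusters"]))
        assert as_dict[("X",)] == 1

    def test_cluster_below_threshold_counts_nowhere(self):
        table = sharing_counts(self._profile(x_present=3), self.clades)
        as_dict = dict(zip(table["clades"], table["n_clusters"]))
        assert ("X",) not in as_dict

    def test_matches_brute_force_enumeration(self, rng):
        species = [f"sp{i}" for i in range(10)]
        clades = CladeDefinition(
            {"X": species[:4], "Y": species[4:7], "Z": species[7:]},
            {"X": 3, "Y": 2, "Z": 2})
        binary = pd.DataFrame(rng.integers(0, 2, (50, 10)), columns=species)
        binary = binary[binary.sum(axis=1) > 0]
        profile = PhyloProfile(binary)
        table = sharing_counts(profile, clades)
        got = dict(zip(table["clades"], table["n_clusters"]))
        want = brute_sharing(profile.binary, clades.clades, clades.min_presence)
        assert got == want
        # partition property: counts sum to number of qualifying clusters
        assert sum(got.values()) == sum(want.values())

    def test_drop_species_specific(self):
        counts = pd.DataFrame({"spA": [1, 1], "spB": [0, 1]},
                              index=[0, 1])
        clades = CladeDefinition({"X": ["spA", "spB"]}, {"X": 1})
        with_drop = sharing_counts(PhyloProfile(counts), clades,
                                   drop_species_specific=True)
        assert with_drop["n_clusters"].sum() == 1


class TestCladeSpecific:
    clades = CladeDefinition({"X": ["spA", "spB"], "Y": ["spC"]}, {"X": 2, "Y": 1})

    def test_outside_presence_excludes(self):
        counts = pd.DataFrame({"spA": [1, 1], "spB": [1, 1], "spC": [0, 1]})
        p = PhyloProfile(counts)
        assert clade_specific_clusters(p, "X", self.clades) == {0}
        assert clade_specific_clusters(p, "X", self.clades, max_outside=1) == {0, 1}

    def test_vacuous_filter_returns_all_touching(self):
        counts = pd.DataFrame({"spA": [1, 0], "spB": [0, 1], "spC": [1, 1]})
        p = PhyloProfile(counts)
        got = clade_specific_clusters(p, "X", self.clades, min_presence=1,
                                      max_outside=1)
        assert got == {0, 1}

    def test_unknown_clade_errors(self, small_profile):
        with pytest.raises(ValueError, match="unknown clade"):
            clade_specific_clusters(small_profile, "nope", self.clades)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="share species"):
            CladeDefinition({"X": ["a", "b"], "Y": ["b"]}, {"X": 1, "Y": 1})
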