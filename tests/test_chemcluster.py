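"""Fingerprints, Tanimoto similarity, cluster formation and KS enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oatnp import chemcluster, synthdata
from oatnp.chemcluster import (
    ChemCluster,
    Fingerprint,
    cluster_compounds,
    cluster_enrichment,
    cluster_summary,
    fingerprint,
    ks_uniform_pvalue,
    ks_uniform_statistic,
    tanimoto,
)


class TestFingerprint:
    def test_identical_smiles_identical_bits(self):
        a = fingerprint("a", "O=c1cc(-c2ccccc2)oc2ccccc12")
        b = fingerprint("b", "O=c1cc(-c2ccccc2)oc2ccccc12")
        assert a.bits == b.bits

    def test_spelling_invariance(self):
        a = fingerprint("a", "OC(=O)c1ccccc1")
        b = fingerprint("b", "c1ccccc1C(O)=O")
        assert a.bits == b.bits

    def test_shared_substructure_bits(self):
        ethane = fingerprint("e", "CC")
        hexane = fingerprint("h", "CCCCCC")
        assert ethane.bits & hexane.bits  # C-C path bit shared
        assert ethane.bits <= hexane.bits

    def test_parse_failure_returns_none(self):
        assert fingerprint("bad", "((((") is None


class TestTanimoto:
    def _fp(self, bits, length=2048):
        return Fingerprint("x", frozenset(bits), length)

    def test_self_similarity_one(self):
        f = self._fp({1, 5, 9})
        assert tanimoto(f, f) == 1.0

    def test_disjoint_zero(self):
        assert tanimoto(self._fp({1, 2}), self._fp({3, 4})) == 0.0

    def test_set_arithmetic(self):
        assert tanimoto(self._fp({1, 2}), self._fp({1, 3})) == pytest.approx(1 / 3)

    def test_both_empty_defined_zero(self):
        assert tanimoto(self._fp(set()), self._fp(set())) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(self._fp({1}), self._fp({1}, length=1024))

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = self._fp(set(rng.integers(0, 100, 20).tolist()))
            b = self._fp(set(rng.integers(0, 100, 20).tolist()))
            s = tanimoto(a, b)
            assert s == tanimoto(b, a)
            assert 0.0 <= s <= 1.0
            assert (s == 1.0) == (a.bits == b.bits and len(a.bits) > 0)

    def test_agrees_with_rdkit(self, compound_pool):
        from rdkit import Chem, DataStructs

        sub = compound_pool.head(8)
        smiles = list(sub["smiles"])
        fps = [fingerprint(str(i), s) for i, s in enumerate(smiles)]
        rds = [Chem.RDKFingerprint(Chem.MolFromSmiles(s), fpSize=2048) for s in smiles]
        for i in range(len(smiles)):
            for j in range(i + 1, len(smiles)):
                assert tanimoto(fps[i], fps[j]) == pytest.approx(
                    DataStructs.TanimotoSimilarity(rds[i], rds[j]), abs=1e-12
                )


class TestClusterFormation:
    def test_planted_flavonoids_form_one_cluster(self, compound_pool):
        """15 flavonoid structures cluster; 5 dissimilar compounds do not."""
        flav = compound_pool[compound_pool["chem_class"] == "flavonoid"].head(15)
        other = ["biotin", "citric acid", "arabinose", "elaidic acid", "saccharin"]
        ids = list(flav["name"]) + other
        fps = [
            fingerprint(n, compound_pool.loc[n, "smiles"])
            for n in ids
        ]
        labels = {n: "flavonoid" for n in flav["name"]}
        clusters, unclustered = cluster_compounds(fps, class_labels=labels)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 15
        assert set(unclustered) == set(other)

    def test_all_dissimilar_unlabeled_gives_no_clusters(self, compound_pool):
        names = ["biotin", "elaidic acid", "arabinose", "saccharin"]
        fps = [fingerprint(n, compound_pool.loc[n, "smiles"]) for n in names]
        clusters, unclustered = cluster_compounds(fps, class_labels=None)
        assert clusters == []
        assert set(unclustered) == set(names)

    def test_label_precedence_over_similarity(self, compound_pool):
        """Two labeled groups always give two clusters, whatever the cut."""
        flav = list(compound_pool[compound_pool["chem_class"] == "flavone"]["name"])[:4]
        acid = list(compound_pool[compound_pool["chem_class"] == "carboxylic acid"]["name"])[:4]
        fps = [fingerprint(n, compound_pool.loc[n, "smiles"]) for n in flav + acid]
        labels = {n: "flavone" for n in flav} | {n: "acid" for n in acid}
        for cut in (0.1, 0.9):
            clusters, _ = cluster_compounds(fps, class_labels=labels, similarity_cut=cut)
            assert sorted(c.label for c in clusters) == ["acid", "flavone"]

    def test_clusters_disjoint_and_small_ones_dissolve(self, compound_pool):
        sub = compound_pool.head(30)
        fps = [fingerprint(n, s) for n, s in zip(sub["name"], sub["smiles"])]
        labels = dict(zip(sub["name"], sub["chem_class"]))
        clusters, unclustered = cluster_compounds(fps, class_labels=labels, min_size=3)
        seen = []
        for c in clusters:
            assert len(c.members) >= 3
            seen.extend(c.members)
        assert len(seen) == len(set(seen))  # disjoint
        assert len(seen) + len(unclustered) == len(fps)


class TestKSEnrichment:
    def test_d_statistic_brute_force_two_points(self):
        # sample {0.1, 0.2}: D = max over the ECDF sweep = 0.8
        assert ks_uniform_statistic([0.1, 0.2]) == pytest.approx(0.8)

    def test_small_concentrated_pvalues_significant(self):
        p = cluster_enrichment([0.001] * 6)
        assert p < 0.01

    def test_agrees_with_scipy_kstest(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            sample = rng.uniform(size=n)
            d = ks_uniform_statistic(sample)
            p = ks_uniform_pvalue(d, n, exact_max_n=10**9)  # force exact
            ref = sps.kstest(sample, "uniform", mode="exact")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_asymptotic_branch_reasonable(self, rng):
        sample = rng.uniform(size=100)
        d = ks_uniform_statistic(sample)
        p = ks_uniform_pvalue(d, 100)
        ref = sps.kstest(sample, "uniform", mode="asymp")
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_enrichment([])

    def test_type_I_calibration_uniform_null(self, rng):
        """KS enrichment p-values are themselves uniform under the null."""
        pvals = [cluster_enrichment(rng.uniform(size=10)) for _ in range(2000)]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestClusterSummary:
    def _clusters(self, sizes):
        out, n = [], 0
        for i, s in enumerate(sizes):
            out.append(
                ChemCluster(
                    cluster_id=f"c{i}", label=f"class{i}",
                    members=[f"m{n + j}" for j in range(s)],
                )
            )
            n += s
        return out, n

    def test_planted_sizes_give_expected_coverage(self, rng):
        """Clusters of 9, 6, 5, 4, 3 all enriched: coverage = 27."""
        clusters, n = self._clusters([9, 6, 5, 4, 3])
        ids = [m for c in clusters for m in c.members]
        diff = pd.DataFrame(
            {"p_value": rng.uniform(0.0005, 0.005, n), "fold_change": 2.0},
            index=pd.Index(ids),
        )
        xlogp = pd.Series(rng.normal(2, 1, n), index=pd.Index(ids))
        table, coverage = cluster_summary(clusters, diff, xlogp)
        assert coverage == 27
        assert table["significant"].all()

    def test_null_clusters_give_zero_coverage(self, rng):
        clusters, n = self._clusters([6, 5])
        ids = [m for c in clusters for m in c.members]
        # per-cluster uniform quantiles: KS cannot call these enriched
        pv = np.concatenate(
            [(np.arange(len(c.members)) + 0.5) / len(c.members) for c in clusters]
        )
        diff = pd.DataFrame(
            {"p_value": pv, "fold_change": 1.0}, index=pd.Index(ids)
        )
        xlogp = pd.Series(np.zeros(n), index=pd.Index(ids))
        table, coverage = cluster_summary(clusters, diff, xlogp)
        assert coverage == 0
        assert not table["significant"].any()

    def test_median_xlogp_is_exact_median(self):
        clusters, _ = self._clusters([3])
        diff = pd.DataFrame(
            {"p_value": [0.5, 0.5, 0.5]}, index=pd.Index(["m0", "m1", "m2"])
        )
        xlogp = {"m0": 1.0, "m1": 2.0, "m2": 10.0}
        table, _ = cluster_summary(clusters, diff, xlogp)
        assert table.loc[0, "median_xlogp"] == 2.0

    def test_key_compound_is_min_p_with_tiebreaks(self):
        clusters, _ = self._clusters([3])
        diff = pd.DataFrame(
            {"p_value": [0.01, 0.01, 0.5], "fold_change": [1.2, 4.0, 1.0]},
            index=pd.Index(["m0", "m1", "m2"]),
        )
        xlogp = {m: 0.0 for m in ["m0", "m1", "m2"]}
        table, _ = cluster_summary(clusters, diff, xlogp)
        assert table.loc[0, "key_compound"] == "m1"  # tie on p, larger |log FC|

    def test_missing_descriptor_warns_and_excludes(self):
        clusters, _ = self._clusters([3])
        diff = pd.DataFrame(
            {"p_value": [0.001, 0.001, 0.001]}, index=pd.Index(["m0", "m1", "m2"])
        )
        with pytest.warns(UserWarning, match="XLogP"):
            table, _ = cluster_summary(clusters, diff, {"m0": 1.0, "m1": 3.0})
        assert table.loc[0, "median_xlogp"] == 2.0

    def test_coverage_bounded_by_input(self, rng):
        clusters, n = self._clusters([4, 3])
        ids = [m for c in clusters for m in c.members]
        diff = pd.DataFrame({"p_value": rng.uniform(size=n)}, index=pd.Index(ids))
        xlogp = {m: 0.0 for m in ids}
        _, coverage = cluster_summary(clusters, diff, xlogp)
        assert 0 <= coverage <= n
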