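"""Beta computation, normalization, filtering, calling, clustering, density."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidrift.infinium import (
    BetaMatrix,
    beta_matrix_from_probe_table,
    beta_density_profile,
    call_differential,
    cluster_samples,
    compute_beta,
    filter_probes,
    normalize_intensities,
)
from epidrift.synthdata import (
    default_methylation_config,
    design_for,
    gen_methylation_dataset,
)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "M,U,expected",
        [(0, 0, 0.0), (-50, 200, 0.0), (900, 0, 0.9)],
    )
    def test_formula_cases(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(np.nan, 1.0)
        with pytest.raises(ValueError):
            compute_beta(1.0, np.inf)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(-1e4, 1e6), st.floats(-1e4, 1e6),
        st.floats(0.1, 1e4), st.floats(0.1, 1e4),
    )
    def test_monotone_in_m_antimonotone_in_u(self, M, U, dm, du):
        b = compute_beta(M, U)
        assert 0 <= b < 1
        assert compute_beta(M + dm, U) >= b
        assert compute_beta(M, U + du) <= b


def _mu_frames(rng, n=300, samples=4):
    cols = [f"s{i}" for i in range(samples)]
    M = pd.DataFrame(rng.gamma(2, 500, (n, samples)), columns=cols)
    U = pd.DataFrame(rng.gamma(2, 700, (n, samples)), columns=cols)
    return M, U


class TestNormalization:
    def test_identical_distributions_unchanged_by_quantile_step(self):
        rng = np.random.default_rng(0)
        base = np.sort(rng.gamma(2, 500, 200))
        M = pd.DataFrame({
            "a": base, "b": rng.permutation(base), "c": rng.permutation(base)
        })
        Mn, _ = normalize_intensities(M, M.copy())
        # all samples share one empirical distribution: quantile step is
        # identity (after the shared color/background shifts)
        for c in "abc":
            np.testing.assert_allclose(
                np.sort(Mn[c].to_numpy()), np.sort(Mn["a"].to_numpy()),
                rtol=1e-9,
            )

    def test_sorted_vectors_identical_after_normalization(self):
        rng = np.random.default_rng(1)
        M, U = _mu_frames(rng)
        Mn, Un = normalize_intensities(M, U)
        for df in (Mn, Un):
            ref = np.sort(df.iloc[:, 0].to_numpy())
            for c in df.columns[1:]:
                np.testing.assert_allclose(np.sort(df[c].to_numpy()), ref, rtol=1e-9)

    def test_ranks_preserved_by_quantile_step(self):
        from epidrift.infinium import quantile_normalize

        rng = np.random.default_rng(2)
        M, _ = _mu_frames(rng)
        Mn = quantile_normalize(M)
        for c in M.columns:
            before = M[c].rank(method="average")
            after = Mn[c].rank(method="average")
            pd.testing.assert_series_equal(before, after)

    def test_single_sample_skips_quantile_step(self):
        rng = np.random.default_rng(3)
        M, U = _mu_frames(rng, samples=1)
        with pytest.warns(UserWarning, match="quantile"):
            normalize_intensities(M, U)

    def test_misaligned_frames_rejected(self):
        rng = np.random.default_rng(4)
        M, U = _mu_frames(rng)
        with pytest.raises(ValueError):
            normalize_intensities(M, U.iloc[:, :2])


@pytest.fixture(scope="module")
def small_study():
    cfg = default_methylation_config(seed=51, n_genes=500)
    table, truth = gen_methylation_dataset(cfg)
    bm = beta_matrix_from_probe_table(table, design_for(cfg), normalize=False)
    return cfg, table, truth, bm


class TestFilterProbes:
    def test_failure_in_one_sample_discards_probe(self, small_study):
        cfg, table, _, bm = small_study
        filtered = filter_probes(bm, alpha=0.01)
        n_fail = (bm.detection_p > 0.01).any(axis=1)
        on_allosome = bm.annotation.chrom.isin(("chrX", "chrY"))
        expected = bm.betas.index[~n_fail & ~on_allosome]
        assert filtered.betas.index.equals(expected)
        assert filtered.filtered

    def test_allosomal_probe_discarded_even_if_detected(self, small_study):
        _, _, _, bm = small_study
        filtered = filter_probes(bm, alpha=1.0)  # detection always passes
        assert not filtered.annotation.chrom.isin(("chrX", "chrY")).any()
        assert bm.annotation.chrom.isin(("chrX", "chrY")).any()

    def test_all_removed_is_an_error_with_counts(self, small_study):
        _, _, _, bm = small_study
        with pytest.raises(ValueError, match="failed detection"):
            filter_probes(bm, alpha=-1.0)


class TestCallDifferential:
    def _bm_from_medians(self, med_a, med_b):
        """Two-group, one-probe-per-gene matrix with given medians."""
        genes = [f"g{i}" for i in range(len(med_a))]
        betas = pd.DataFrame({
            "a1": med_a, "a2": med_a, "b1": med_b, "b2": med_b,
        }, index=genes)
        ann = pd.DataFrame({
            "gene": genes, "chrom": "chr1",
            "pos": np.arange(1, len(genes) + 1) * 1000,
        }, index=genes)
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        return BetaMatrix(betas=betas, annotation=ann, design=design)

    def test_inclusive_boundary_at_20_percent(self):
        bm = self._bm_from_medians([0.10, 0.10], [0.30, 0.29])
        cs = call_differential(bm, "A", "B", delta=0.20)
        assert cs.gained == {"g0"}
        assert cs.lost == set()

    def test_antisymmetric_under_group_swap(self, small_study):
        _, _, _, bm = small_study
        fwd = call_differential(bm, "1", "4")
        rev = call_differential(bm, "4", "1")
        assert fwd.gained == rev.lost
        assert fwd.lost == rev.gained

    def test_conflicting_probe_directions_flagged(self):
        genes = ["g0", "g0"]
        betas = pd.DataFrame(
            {"a1": [0.1, 0.8], "a2": [0.1, 0.8],
             "b1": [0.5, 0.3], "b2": [0.5, 0.3]},
            index=["p0", "p1"],
        )
        ann = pd.DataFrame(
            {"gene": genes, "chrom": "chr1", "pos": [100, 600]},
            index=["p0", "p1"],
        )
        bm = BetaMatrix(betas=betas, annotation=ann,
                        design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        cs = call_differential(bm, "A", "B")
        # |+0.4| < |-0.5|: assigned to loss, flagged
        assert cs.lost == {"g0"} and cs.gained == set()
        assert cs.table.flagged.all()

    def test_unknown_group_rejected(self, small_study):
        _, _, _, bm = small_study
        with pytest.raises(ValueError, match="unknown group"):
            call_differential(bm, "1", "nope")

    def test_recovers_planted_truth_at_default_noise(self, small_study):
        """sigma_beta=0.05: near-perfect recall on surviving genes, no FPs."""
        cfg, _, truth, bm = small_study
        filtered = filter_probes(bm)
        cs = call_differential(filtered, "1", "4")
        planted = set(truth[(truth.group_a == 1) & (truth.group_b == 4)].gene)
        # genes whose probes all failed detection cannot be recovered
        observable = planted & set(filtered.annotation.gene)
        assert not cs.called - planted               # no false positives
        recall = len(cs.called & observable) / len(observable)
        assert recall >= 0.9


class TestClustering:
    def test_identical_samples_merge_at_height_zero(self):
        betas = pd.DataFrame({
            "x": [0.1, 0.5, 0.9], "y": [0.1, 0.5, 0.9], "z": [0.3, 0.3, 0.3],
        }, index=["p0", "p1", "p2"])
        ann = pd.DataFrame({"gene": ["g"] * 3, "chrom": "chr1",
                            "pos": [1, 2, 3]}, index=betas.index)
        bm = BetaMatrix(betas=betas, annotation=ann,
                        design={"x": "A", "y": "A", "z": "B"})
        cr = cluster_samples(bm)
        assert cr.linkage[0, 2] == 0.0
        assert cr.cophenetic.loc["x", "y"] == 0.0

    def test_transduced_group_forms_exclusive_clade(self, filtered_betas):
        cs = call_differential(filtered_betas, "1", "4")
        probes = cs.probe_deltas[cs.probe_deltas.abs() >= 0.2].index
        cr = cluster_samples(filtered_betas, probe_ids=probes)
        from scipy.cluster import hierarchy

        names = list(filtered_betas.betas.columns)
        tree = hierarchy.to_tree(cr.linkage)
        clades = []

        def walk(node):
            if node.is_leaf():
                return {names[node.id]}
            s = walk(node.get_left()) | walk(node.get_right())
            clades.append(s)
            return s

        walk(tree)
        g4 = {s for s in names if filtered_betas.design[s] == "4"}
        assert g4 in clades

    def test_newick_is_parseable_and_leaf_order_deterministic(self, filtered_betas):
        import dendropy

        a = cluster_samples(filtered_betas)
        b = cluster_samples(filtered_betas)
        assert a.leaves == b.leaves
        assert a.newick == b.newick
        tree = dendropy.Tree.get(
            data=a.newick, schema="newick", preserve_underscores=True
        )
        taxa = {t.label for t in tree.taxon_namespace}
        assert taxa == set(filtered_betas.betas.columns)

    def test_zero_probes_rejected(self, filtered_betas):
        with pytest.raises(ValueError):
            cluster_samples(filtered_betas, probe_ids=[])


class TestDensityProfile:
    def test_constant_betas_give_single_spike(self):
        betas = pd.DataFrame({"x": [0.5] * 10, "y": [0.5] * 10},
                             index=[f"p{i}" for i in range(10)])
        ann = pd.DataFrame({"gene": "g", "chrom": "chr1",
                            "pos": range(10)}, index=betas.index)
        bm = BetaMatrix(betas=betas, annotation=ann,
                        design={"x": "A", "y": "A"})
        edges, density = beta_density_profile(bm, "A", bins=50)
        assert (density > 0).sum() == 1

    def test_density_integrates_to_one(self, filtered_betas):
        edges, density = beta_density_profile(filtered_betas, "1")
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-6)

    def test_transduced_group_enriched_at_intermediate_methylation(
        self, filtered_betas
    ):
        masses = {}
        for g in ("1", "4"):
            edges, density = beta_density_profile(filtered_betas, g)
            w = np.diff(edges)
            mid = (edges[:-1] >= 0.2) & (edges[1:] <= 0.8)
            masses[g] = float(np.sum(density[mid] * w[mid]))
        assert masses["4"] > masses["1"]
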