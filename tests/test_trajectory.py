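"""Diffusion maps, pseudotime, loess DE, Stouffer meta, consensus modules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibroscape.containers import CellMatrix
from fibroscape.trajectory import (
    PROFILE_GRID,
    PseudotimeAssignment,
    consensus_modules,
    diffusion_map,
    diffusion_pseudotime,
    loess_smoother_matrix,
    pseudotime_de,
    quintile_module_comparison,
    stouffer_meta,
    transition_matrix,
)


def line_points(n=200, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n)
    return np.column_stack([x, noise * rng.normal(size=n), noise * rng.normal(size=n)])


class TestDiffusionMap:
    def test_first_component_orders_a_line(self):
        X = line_points()
        emb = diffusion_map(X, k=15, n_comps=5)
        rho = stats.spearmanr(emb.components[:, 0], X[:, 0])[0]
        assert abs(rho) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        """Components/eigenvalues agree with a brute-force eigendecomposition
        of the same transition matrix."""
        X = line_points(50)
        emb = diffusion_map(X, k=10, n_comps=4)
        P = transition_matrix(X, k=10)
        evals, evecs = np.linalg.eig(P)
        order = np.argsort(evals.real)[::-1]
        evals, evecs = evals.real[order], evecs.real[:, order]
        assert np.allclose(emb.eigenvalues, evals[1:5], atol=1e-8)
        for i in range(4):
            v = evecs[:, i + 1] / np.linalg.norm(evecs[:, i + 1])
            u = emb.eigenvectors[:, i]
            assert min(np.abs(u - v).max(), np.abs(u + v).max()) < 1e-8

    def test_duplicated_cells_get_equal_components(self):
        X = np.vstack([line_points(60), line_points(60)])
        emb = diffusion_map(X, k=10, n_comps=3)
        assert np.abs(emb.eigenvectors[:60] - emb.eigenvectors[60:]).max() < 1e-6

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            diffusion_map(line_points(5), n_comps=10)

    def test_eigenvalues_in_unit_interval(self):
        emb = diffusion_map(line_points(80, noise=0.05, seed=3), k=10)
        assert (emb.eigenvalues > 0).all() and (emb.eigenvalues <= 1).all()


class TestDiffusionPseudotime:
    def test_root_has_zero_dpt(self):
        emb = diffusion_map(line_points(), k=15)
        pt = diffusion_pseudotime(emb, root=0, n_branches=1)
        assert pt.dpt[0] == 0.0
        assert pt.dpt.min() >= 0 and pt.dpt.max() == pytest.approx(1.0)

    def test_orders_noiseless_line(self):
        X = line_points()
        emb = diffusion_map(X, k=15)
        pt = diffusion_pseudotime(emb, root=0, n_branches=1)
        assert stats.spearmanr(pt.dpt, X[:, 0])[0] == pytest.approx(1.0)

    def test_three_branch_assignment_on_geometric_y(self):
        """A clean Y-shape: two arms merging into a stem."""
        t = np.linspace(0, 1, 100)
        armA = np.column_stack([1 - t, 1 - t])  # tip (1,1) -> junction (0,0)
        armB = np.column_stack([t - 1, 1 - t])  # tip (-1,1) -> junction (0,0)
        stem = np.column_stack([np.zeros(100), -t])  # junction -> (0,-1)
        X = np.vstack([armA, armB, stem]) + 0.005 * np.random.default_rng(0).normal(size=(300, 2))
        emb = diffusion_map(X, k=15)
        pt = diffusion_pseudotime(emb, root=0, n_branches=3)
        truth = np.array(["A"] * 100 + ["B"] * 100 + ["T"] * 100)
        table = pd.crosstab(truth, pt.branch)
        # each predicted branch is dominated by one true segment
        assert (table.max(axis=0) / table.sum(axis=0)).min() > 0.8

    def test_invalid_root_rejected(self):
        emb = diffusion_map(line_points(), k=15)
        with pytest.raises(ValueError):
            diffusion_pseudotime(emb, root=10_000)


class TestLoessDE:
    def test_strong_linear_signal_detected(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.uniform(0, 1, n)
        counts = np.vstack(
            [
                (50 * x + rng.normal(0, 0.5, n)).clip(0).astype(int),
                np.full(n, 1000),  # housekeeping gene carries the library
            ]
        )
        cm = CellMatrix(
            counts=counts, genes=["sig", "hk"],
            cell_meta=pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)]}),
        )
        pt = PseudotimeAssignment(dpt=x, branch=np.full(n, "b"), root=0)
        tab = pseudotime_de(cm, pt).set_index("gene")
        assert tab.loc["sig", "p"] < 1e-10
        prof = tab.filter(like="fit_").loc["sig"].to_numpy()
        assert stats.spearmanr(prof, PROFILE_GRID)[0] > 0.99  # rises with dpt

    def test_constant_gene_flat_profile_p_one(self):
        n = 120
        cm = CellMatrix(
            counts=np.full((1, n), 7), genes=["flat"],
            cell_meta=pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)]}),
        )
        x = np.linspace(0, 1, n)
        tab = pseudotime_de(cm, PseudotimeAssignment(dpt=x, branch=np.full(n, "b"), root=0))
        assert tab["p"].iloc[0] == 1.0
        assert tab.filter(like="fit_").std(axis=1).iloc[0] < 1e-12

    def test_planted_bump_profile_peaks_in_window(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.uniform(0, 1, n)
        bump = np.exp(-(((x - 0.45) / 0.08) ** 2))
        counts = rng.poisson(3 + 30 * bump)[None, :]
        cm = CellMatrix(
            counts=counts, genes=["bump"],
            cell_meta=pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)]}),
        )
        tab = pseudotime_de(cm, PseudotimeAssignment(dpt=x, branch=np.full(n, "b"), root=0))
        peak = PROFILE_GRID[np.argmax(tab.filter(like="fit_").to_numpy().ravel())]
        assert 0.3 <= peak <= 0.6

    def test_too_few_cells_rejected(self):
        cm = CellMatrix(
            counts=np.ones((2, 20), int), genes=["a", "b"],
            cell_meta=pd.DataFrame({"cell_id": [f"c{i}" for i in range(20)]}),
        )
        with pytest.raises(ValueError, match="50"):
            pseudotime_de(cm, PseudotimeAssignment(dpt=np.linspace(0, 1, 20),
                                                   branch=np.full(20, "b"), root=0))

    def test_smoother_reproduces_polynomial_exactly(self):
        """A degree-2 local smoother interpolates a quadratic exactly."""
        x = np.linspace(0, 1, 60)
        S, L = loess_smoother_matrix(x, span=0.5, degree=2)
        y = 3 * x**2 - 2 * x + 1
        assert np.allclose(S @ y, y, atol=1e-10)
        grid_y = 3 * PROFILE_GRID**2 - 2 * PROFILE_GRID + 1
        assert np.allclose(L @ y, grid_y, atol=1e-10)


class TestStouffer:
    def test_single_dataset_identity(self):
        tab = stouffer_meta(pd.DataFrame({"d1": [0.05]}, index=["g"]), min_nominal=1)
        assert tab["meta_p"].iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_two_dataset_closed_form(self):
        p = 0.01
        tab = stouffer_meta(pd.DataFrame({"d1": [p], "d2": [p]}, index=["g"]))
        z = 2 * stats.norm.isf(p) / np.sqrt(2)
        assert abs(tab["meta_p"].iloc[0] - stats.norm.sf(z)) < 1e-12

    def test_nominal_counting_and_missing_columns(self):
        P = pd.DataFrame(
            {"d1": [0.01, 0.01], "d2": [0.01, 0.01], "d3": [0.01, np.nan], "d4": [0.9, 0.9]},
            index=["g1", "g2"],
        )
        tab = stouffer_meta(P, min_nominal=3)
        assert tab.loc["g1", "n_nominal"] == 3
        assert tab.loc["g2", "n_nominal"] == 2
        assert tab.loc["g2", "n_datasets"] == 3  # missing column excluded from D

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            tab = stouffer_meta(pd.DataFrame({"d1": [0.0]}, index=["g"]))
        assert np.isfinite(tab["meta_p"]).all()

    def test_monotone_in_each_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.001, 0.999, 3)
            better = p.copy()
            better[rng.integers(3)] *= 0.5
            m1 = stouffer_meta(pd.DataFrame([p], index=["g"]))["meta_p"].iloc[0]
            m2 = stouffer_meta(pd.DataFrame([better], index=["g"]))["meta_p"].iloc[0]
            assert m2 <= m1


def _ward_bruteforce(dist: np.ndarray, k: int) -> np.ndarray:
    """Naive Ward agglomeration via the Lance-Williams recurrence."""
    n = dist.shape[0]
    d = dist.astype(float).copy() ** 2  # work on squared distances
    active = {i: [i] for i in range(n)}
    keys = list(active)
    while len(active) > k:
        best = None
        for i in active:
            for j in active:
                if j <= i:
                    continue
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        _, a, b = best
        na, nb = len(active[a]), len(active[b])
        for c in list(active):
            if c in (a, b):
                continue
            nc = len(active[c])
            d_new = (
                (na + nc) * d[a, c] + (nb + nc) * d[b, c] - nc * d[a, b]
            ) / (na + nb + nc)
            d[a, c] = d[c, a] = d_new
        active[a] = active[a] + active[b]
        del active[b]
    labels = np.empty(n, int)
    for ci, members in enumerate(active.values()):
        labels[members] = ci
    return labels


class TestConsensusModules:
    @staticmethod
    def _fits_from_profiles(profiles: np.ndarray, genes: list) -> pd.DataFrame:
        tab = pd.DataFrame({"gene": genes, "p": 1e-20, "span": 0.5})
        prof = pd.DataFrame(profiles, columns=[f"fit_{i:03d}" for i in range(100)])
        return pd.concat([tab, prof], axis=1)

    def test_recovers_planted_profile_groups(self):
        rng = np.random.default_rng(0)
        g = PROFILE_GRID
        shapes = [np.exp(-(((g - c) / 0.12) ** 2)) for c in (0.1, 0.4, 0.6, 0.9)]
        genes, profiles, truth = [], [], []
        for mi, s in enumerate(shapes):
            for r in range(10):
                genes.append(f"m{mi}_{r}")
                profiles.append(s + 0.02 * rng.normal(size=100))
                truth.append(mi)
        fits = [self._fits_from_profiles(np.array(profiles), genes)]
        out = consensus_modules(fits, genes, k_modules=4)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, out["module_index"].tolist()) == 1.0
        # naming follows peak order
        assert out.loc["m0_0", "module"] == "progenitor"
        assert out.loc["m3_0", "module"] == "differentiation"

    def test_matches_bruteforce_ward_partition(self):
        """scipy Ward on 1-r equals a Lance-Williams re-implementation."""
        rng = np.random.default_rng(1)
        profiles = rng.normal(size=(20, 100)).cumsum(axis=1)
        genes = [f"g{i}" for i in range(20)]
        fits = [self._fits_from_profiles(profiles, genes)]
        out = consensus_modules(fits, genes, k_modules=4)

        z = (profiles - profiles.mean(1, keepdims=True)) / profiles.std(1, keepdims=True)
        r = np.clip(z @ z.T / 100, -1, 1)
        dist = 1 - r
        np.fill_diagonal(dist, 0)
        brute = _ward_bruteforce(dist, 4)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(brute, out["module_index"].tolist()) == 1.0

    def test_identical_profiles_warn(self):
        profiles = np.tile(np.sin(PROFILE_GRID * 3), (5, 1))
        genes = [f"g{i}" for i in range(5)]
        fits = [self._fits_from_profiles(profiles, genes)]
        with pytest.warns(UserWarning, match="identical"):
            consensus_modules(fits, genes, k_modules=2)

    def test_more_modules_than_genes_rejected(self):
        fits = [self._fits_from_profiles(np.random.rand(2, 100), ["a", "b"])]
        with pytest.raises(ValueError):
            consensus_modules(fits, ["a", "b"], k_modules=4)

    def test_naming_stable_under_dataset_permutation(self):
        rng = np.random.default_rng(2)
        g = PROFILE_GRID
        genes = [f"g{i}" for i in range(12)]
        truth_profiles = np.array(
            [np.exp(-(((g - c) / 0.15) ** 2)) for c in (0.2, 0.5, 0.8) for _ in range(4)]
        )
        d1 = truth_profiles + 0.05 * rng.normal(size=truth_profiles.shape)
        d2 = truth_profiles + 0.05 * rng.normal(size=truth_profiles.shape)
        f1 = self._fits_from_profiles(d1, genes)
        f2 = self._fits_from_profiles(d2, genes)
        out_a = consensus_modules([f1, f2], genes, k_modules=3)
        out_b = consensus_modules([f2, f1], genes, k_modules=3)
        assert (out_a["module"] == out_b["module"]).all()


class TestQuintiles:
    def test_even_spread_gives_equal_bins(self):
        n = 10
        pt = PseudotimeAssignment(
            dpt=np.linspace(0, 1, n), branch=np.full(n, "b"), root=0
        )
        scores = pd.DataFrame({"m": np.zeros(n)})
        tissue = np.array(["control", "LUAD"] * 5)
        sample = np.array([f"s{i}" for i in range(n)])
        out = quintile_module_comparison(scores, pt, tissue, sample)
        tab = out["m"]
        assert (tab.groupby("quintile")["n_cells"].sum() == 2).all()

    def test_planted_shift_detected_in_right_bin(self):
        rng = np.random.default_rng(3)
        n = 2000
        dpt = rng.uniform(0, 1, n)
        sample = rng.choice([f"s{i}" for i in range(16)], n)
        tissue = np.where(pd.Series(sample).str[1:].astype(int) < 8, "control", "LUAD")
        score = rng.normal(0, 0.3, n)
        in_q3 = (dpt >= 0.4) & (dpt < 0.6) & (tissue == "LUAD")
        score[in_q3] += 2.0
        out = quintile_module_comparison(pd.DataFrame({"m": score}),
                                         PseudotimeAssignment(dpt=dpt, branch=np.full(n, "b"), root=0),
                                         tissue, sample)
        p = out["p_values"].loc["m"]
        assert p["q3"] < 0.01
        assert (p.drop("q3") > 0.01).all()
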