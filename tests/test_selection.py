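import itertools
import math

import numpy as np
import pytest

from nbsig import (
    CountMatrix,
    SignatureMatrix,
    information_criteria,
    match_signatures,
    select_rank_ic,
    sigmos,
    synthetic_catalog,
)
from nbsig.containers import ExposureMatrix, FactorizationFit
from nbsig.selection import cosine_similarity_matrix, n_parameters


def _sig(values, ids=None):
    values = np.asarray(values, float)
    values = values / values.sum(axis=1, keepdims=True)
    K, M = values.shape
    ids = ids or [f"S{k}" for k in range(K)]
    return SignatureMatrix(values, ids, [f"M{m}" for m in range(M)])


class TestMatchSignatures:
    def test_identity(self):
        H = _sig(np.random.default_rng(0).uniform(0.1, 1, (4, 8)))
        perm, sims = match_signatures(H, H)
        assert list(perm) == [0, 1, 2, 3]
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_recovers_known_permutation(self):
        H = _sig(np.random.default_rng(1).uniform(0.1, 1, (5, 10)))
        sigma = np.array([3, 0, 4, 1, 2])
        Hq = SignatureMatrix(H.values[sigma], [f"Q{k}" for k in range(5)], H.mutation_types)
        perm, sims = match_signatures(H, Hq)
        # H_query rows reordered by perm must reproduce H_ref
        np.testing.assert_allclose(Hq.values[perm], H.values, atol=1e-12)
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(2)
        A = _sig(rng.uniform(0.01, 1, (4, 12)))
        B = _sig(rng.uniform(0.01, 1, (4, 12)))
        perm, sims = match_signatures(A, B)
        sim = cosine_similarity_matrix(A.values, B.values)
        brute = max(
            sum(sim[i, p[i]] for i in range(4)) for p in itertools.permutations(range(4))
        )
        assert sims.sum() == pytest.approx(brute, abs=1e-12)

    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(3)
        A = _sig(rng.uniform(0.01, 1, (5, 9)))
        B = _sig(rng.uniform(0.01, 1, (5, 9)))
        perm, _ = match_signatures(A, B)
        back, _ = match_signatures(B, A)
        assert list(back[perm]) == list(range(5))

    def test_shape_mismatch(self):
        A = _sig(np.ones((2, 4)))
        B = _sig(np.ones((3, 4)))
        with pytest.raises(ValueError, match="differ in shape"):
            match_signatures(A, B)


class TestInformationCriteria:
    def _fake_fit(self, model, N=10, M=6, K=2, loglik=-100.0):
        rng = np.random.default_rng(0)
        H = _sig(rng.uniform(0.1, 1, (K, M)))
        W = ExposureMatrix(rng.uniform(0, 1, (N, K)),
                           [f"P{n}" for n in range(N)], H.signature_ids)
        disp = None
        if model != "poisson":
            from nbsig.containers import DispersionVector
            disp = DispersionVector(np.full(N, 10.0), shared=(model == "negbin_shared"))
        return FactorizationFit(
            W=W, H=H, model=model, rank=K, divergence_trace=np.array([1.0]),
            n_inits=1, seed=0, loglik=loglik, dispersions=disp,
        )

    def test_aic_formula(self):
        fit = self._fake_fit("poisson", N=10, M=6, K=2, loglik=-100.0)
        V = CountMatrix(np.ones((10, 6)), fit.W.patient_ids, fit.H.mutation_types)
        ic = information_criteria(fit, V)
        assert ic.n_prm == 2 * (10 + 6)
        assert ic.aic == pytest.approx(200 + 2 * ic.n_prm)
        assert ic.bic == pytest.approx(200 + math.log(10) * ic.n_prm)

    def test_aic_bic_cross_at_nobs_e_squared(self):
        """BIC penalty exceeds AIC's exactly when ln(N) > 2, i.e. N >= 8."""
        for N, heavier in [(7, False), (8, True)]:
            fit = self._fake_fit("poisson", N=N, M=6, K=2)
            V = CountMatrix(np.ones((N, 6)), fit.W.patient_ids, fit.H.mutation_types)
            ic = information_criteria(fit, V)
            assert (ic.bic > ic.aic) == heavier

    @pytest.mark.parametrize(
        "model, extra", [("poisson", 0), ("negbin_patient", 10), ("negbin_shared", 1)]
    )
    def test_parameter_count_conventions(self, model, extra):
        assert n_parameters(model, N=10, M=6, K=3) == 3 * 16 + extra

    def test_dispersion_parameters_enter_criteria(self):
        V = CountMatrix(np.ones((10, 6)), [f"P{n}" for n in range(10)],
                        [f"M{m}" for m in range(6)])
        po = information_criteria(self._fake_fit("poisson"), V)
        nbp = information_criteria(self._fake_fit("negbin_patient"), V)
        assert nbp.aic - po.aic == pytest.approx(2 * 10)


class TestRankSelection:
    def test_single_candidate_grid(self, poisson_dataset):
        res = sigmos(poisson_dataset.counts, "poisson", [4], J=2, seed=0,
                     n_inits=1, tol=1e-4, max_iter=200)
        assert res.chosen_k == 4
        k = select_rank_ic(poisson_dataset.counts, "poisson", [2], criterion="bic",
                           seed=0, n_inits=1, tol=1e-4, max_iter=200)
        assert k == 2

    def test_sigmos_reproducible_and_grid_order_invariant(self, poisson_dataset):
        kw = dict(J=3, seed=5, n_inits=2, tol=1e-5, max_iter=500)
        r1 = sigmos(poisson_dataset.counts, "poisson", [2, 3, 4], **kw)
        r2 = sigmos(poisson_dataset.counts, "poisson", [4, 2, 3], **kw)
        assert r1.chosen_k == r2.chosen_k
        for K in (2, 3, 4):
            assert r1.median_costs[K] == pytest.approx(r2.median_costs[K], rel=1e-12)
            assert len(r1.per_split_costs[K]) == 3
            assert (r1.per_split_costs[K] >= 0).all()

    def test_sigmos_recovers_true_rank_poisson_data(self, poisson_dataset):
        res = sigmos(poisson_dataset.counts, "poisson", [2, 3, 4, 5], J=5, seed=1,
                     n_inits=3, tol=1e-5, max_iter=1500)
        assert res.chosen_k == 3

    def test_sigmos_rejects_bad_arguments(self, poisson_dataset):
        with pytest.raises(ValueError, match="split_fraction"):
            sigmos(poisson_dataset.counts, "poisson", [2], split_fraction=1.5)
        with pytest.raises(ValueError, match="unknown cost"):
            sigmos(poisson_dataset.counts, "poisson", [2], cost="hellinger")
        with pytest.raises(ValueError, match="unknown NMF method"):
            sigmos(poisson_dataset.counts, "gamma", [2])

    def test_oversized_k_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        V = rng.poisson(80.0, size=(6, 5)) + 1
        cm = CountMatrix(V, [f"P{n}" for n in range(6)], [f"M{m}" for m in range(5)])
        res = sigmos(cm, "poisson", [2, 5], J=2, seed=0, n_inits=1, tol=1e-4, max_iter=200)
        # training sets have 5 patients and M=5, so K=5 is feasible; K > 5 is not
        assert set(res.k_grid) <= {2, 5}

    def test_ic_selection_recovers_rank_on_poisson_data(self, poisson_dataset):
        k = select_rank_ic(poisson_dataset.counts, "poisson", [2, 3, 4, 5],
                           criterion="bic", seed=0, n_inits=3, tol=1e-5, max_iter=1500)
        assert k == 3

    def test_alternative_costs_run(self, poisson_dataset):
        for cost in ("frobenius", "itakura_saito"):
            res = sigmos(poisson_dataset.counts, "poisson", [3], J=2, seed=0,
                         cost=cost, n_inits=1, tol=1e-4, max_iter=200)
            assert res.cost_name == cost
            assert res.median_costs[3] >= 0


class TestCatalogHelpers:
    def test_synthetic_catalog_shape(self):
        cat = synthetic_catalog()
        assert cat.n_signatures == 10
        assert cat.signature_ids[0] == "SBS1" and "SBS5" in cat.signature_ids
        np.testing.assert_allclose(cat.values.sum(axis=1), 1.0, atol=1e-12)
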