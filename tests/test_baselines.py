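import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from linpert.baselines import (
    LinearModelFit,
    PredictionMatrix,
    fit_linear_model,
    fit_ridge_decoder,
    predict_additive,
    predict_additive_matrix,
    predict_linear_model,
    predict_mean,
    predict_no_change,
    predict_ridge_decoder,
)
from linpert.data_model import parse_condition_label
from linpert.embeddings import EmbeddingPair, pca_gene_embedding, perturbation_rows
from linpert.evaluation import l2_error, pearson_delta

from conftest import make_pb


def lab(s):
    return parse_condition_label(s)


def random_instance(n_genes, n_conds, seed=0):
    rng = np.random.default_rng(seed)
    cols = {"ctrl": rng.normal(size=n_genes)}
    for j in range(1, n_conds):
        cols[f"S{j}+ctrl"] = rng.normal(size=n_genes)
    return make_pb(cols)


def identity_embedding(pb):
    """G = I over genes, P = I over non-control conditions."""
    train = [l for l in pb.condition_labels if not l.is_control]
    G = pd.DataFrame(np.eye(len(pb.gene_ids)), index=pb.gene_ids)
    P = pd.DataFrame(
        np.eye(len(train)), index=[l.canonical_string for l in train]
    )
    return EmbeddingPair(G, P, "identity"), train


class TestNoChange:
    def test_all_columns_equal_control(self, simple_pb):
        pred = predict_no_change(simple_pb, [lab("g0+g1"), lab("g0+ctrl")])
        for l in pred.perturbation_labels:
            np.testing.assert_array_equal(pred.column(l), simple_pb.control_values)

    def test_l2_against_control_is_zero(self, simple_pb):
        pred = predict_no_change(simple_pb, [lab("g0+g1")])
        assert l2_error(pred.column(lab("g0+g1")), simple_pb.control_values) == 0.0

    def test_pearson_delta_missing_not_zero(self, simple_pb):
        pred = predict_no_change(simple_pb, [lab("g0+g1")])
        value = pearson_delta(
            pred.column(lab("g0+g1")),
            simple_pb.column(lab("g0+g1")),
            simple_pb.control_values,
        )
        assert np.isnan(value)


class TestMean:
    def test_row_mean(self):
        pb = make_pb({"ctrl": [0.0], "A+ctrl": [1.0], "B+ctrl": [3.0]})
        pred = predict_mean(pb.subset_conditions([lab("A+ctrl"), lab("B+ctrl")]),
                            [lab("C+ctrl")])
        # the training matrix passed in retains its control column
        assert pred.column(lab("C+ctrl"))[0] == pytest.approx((1 + 3 + 0) / 3)

    def test_single_training_column(self):
        pb = make_pb({"ctrl": [2.0, 4.0], "A+ctrl": [2.0, 4.0]})
        pred = predict_mean(pb, [lab("B+ctrl")])
        np.testing.assert_array_equal(pred.column(lab("B+ctrl")), [2.0, 4.0])

    def test_coincides_with_no_change_when_flat(self):
        pb = make_pb({"ctrl": [1.0], "A+ctrl": [1.0], "B+ctrl": [1.0]})
        m = predict_mean(pb, [lab("C+ctrl")])
        n = predict_no_change(pb, [lab("C+ctrl")])
        np.testing.assert_array_equal(m.values, n.values)


class TestAdditive:
    def test_arithmetic(self):
        pb = make_pb({"ctrl": [1.0], "A+ctrl": [2.0], "B+ctrl": [3.0]})
        assert predict_additive(pb, lab("A+B"))[0] == pytest.approx(4.0)

    def test_null_single_reduces_to_other(self):
        pb = make_pb({"ctrl": [1.0], "A+ctrl": [1.0], "B+ctrl": [3.0]})
        assert predict_additive(pb, lab("A+B"))[0] == pytest.approx(3.0)

    def test_both_null_gives_control(self):
        pb = make_pb({"ctrl": [1.0], "A+ctrl": [1.0], "B+ctrl": [1.0]})
        assert predict_additive(pb, lab("A+B"))[0] == pytest.approx(1.0)

    def test_missing_single_named_in_error(self):
        pb = make_pb({"ctrl": [1.0], "A+ctrl": [2.0]})
        with pytest.raises(KeyError, match="B\\+ctrl"):
            predict_additive(pb, lab("A+B"))


class TestFitLinearModel:
    def test_identity_embeddings_lambda_zero(self):
        pb = random_instance(4, 5, seed=0)
        emb, train = identity_embedding(pb)
        fit = fit_linear_model(pb, emb, lam=0.0)
        Y = np.column_stack([pb.column(l) for l in train])
        b = pb.values.mean(axis=1)  # row means over all training columns
        np.testing.assert_allclose(fit.W, Y - b[:, None], atol=1e-10)

    def test_shrinkage_limit(self):
        pb = random_instance(6, 5, seed=1)
        emb, train = identity_embedding(pb)
        fit = fit_linear_model(pb, emb, lam=1e6)
        Y = np.column_stack([pb.column(l) for l in train])
        Yc = Y - pb.values.mean(axis=1, keepdims=True)
        assert np.linalg.norm(fit.W) < 1e-3 * np.linalg.norm(Yc)

    def test_monotone_shrinkage(self):
        pb = random_instance(10, 6, seed=2)
        emb, _ = identity_embedding(pb)
        norms = [
            np.linalg.norm(fit_linear_model(pb, emb, lam=lam).W)
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_singular_at_lambda_zero_errors(self):
        pb = random_instance(4, 4, seed=3)
        train = [l for l in pb.condition_labels if not l.is_control]
        G = pd.DataFrame(np.ones((4, 2)), index=pb.gene_ids)  # rank 1
        P = pd.DataFrame(np.eye(3, 2), index=[l.canonical_string for l in train])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_linear_model(pb, EmbeddingPair(G, P), lam=0.0)

    def test_ridge_oracle_objective(self):
        # oracle: iterative minimization of the matching two-sided-penalty
        # objective; the closed form must reach the same objective value
        pb = random_instance(15, 7, seed=4)
        rng = np.random.default_rng(5)
        train = [l for l in pb.condition_labels if not l.is_control]
        G = pd.DataFrame(rng.normal(size=(15, 3)), index=pb.gene_ids)
        P = pd.DataFrame(
            rng.normal(size=(len(train), 3)),
            index=[l.canonical_string for l in train],
        )
        lam = 0.1
        fit = fit_linear_model(pb, EmbeddingPair(G, P), lam=lam)
        Y = np.column_stack([pb.column(l) for l in train])
        Yc = Y - pb.values.mean(axis=1, keepdims=True)
        Gm, Pm = G.to_numpy(), P.to_numpy()

        def objective(w_flat):
            W = w_flat.reshape(3, 3)
            resid = Yc - Gm @ W @ Pm.T
            return (
                np.sum(resid**2)
                + lam * np.sum((Gm @ W) ** 2)
                + lam * np.sum((W @ Pm.T) ** 2)
                + lam**2 * np.sum(W**2)
            )

        res = scipy.optimize.minimize(
            objective, np.zeros(9), method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        closed = objective(fit.W.ravel())
        assert closed == pytest.approx(res.fun, rel=1e-6)


class TestPredictLinearModel:
    def test_training_embedding_gives_fitted_values(self):
        pb = random_instance(8, 5, seed=6)
        emb, train = identity_embedding(pb)
        fit = fit_linear_model(pb, emb, lam=0.0)
        pred = predict_linear_model(fit, emb.P)
        Y = np.column_stack([pb.column(l) for l in train])
        np.testing.assert_allclose(pred.values, Y, atol=1e-9)

    def test_zero_w_reduces_to_mean(self):
        pb = random_instance(8, 5, seed=7)
        emb, train = identity_embedding(pb)
        fit = fit_linear_model(pb, emb, lam=0.1)
        fit.W = np.zeros_like(fit.W)
        pred = predict_linear_model(fit, emb.P)
        mean_pred = predict_mean(pb.subset_conditions(train), train)
        np.testing.assert_allclose(pred.values, mean_pred.values, atol=1e-12)

    def test_dimension_mismatch(self):
        pb = random_instance(4, 4, seed=8)
        emb, _ = identity_embedding(pb)
        fit = fit_linear_model(pb, emb, lam=0.1)
        bad = pd.DataFrame(np.ones((2, 99)), index=["A+ctrl", "B+ctrl"])
        with pytest.raises(ValueError, match="columns"):
            predict_linear_model(fit, bad)

    def test_additive_as_special_case(self):
        # G = single-perturbation data, P = binary double coding,
        # W = identity, b = -control: identical to the additive model
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(6)]
        singles = ["a", "b", "c"]
        cols = {"ctrl": rng.normal(size=6)}
        for s in singles:
            cols[f"{s}+ctrl"] = rng.normal(size=6)
        cols["a+b"] = rng.normal(size=6)
        pb = make_pb(cols, gene_ids=genes)

        pairs = [lab("a+b"), lab("a+c"), lab("b+c")]
        Y_single = np.column_stack(
            [pb.column(lab(f"{s}+ctrl")) for s in singles]
        )
        G = pd.DataFrame(Y_single, index=genes)
        coding = np.zeros((len(pairs), len(singles)))
        for i, pair in enumerate(pairs):
            for t in pair.targets:
                coding[i, singles.index(t)] = 1.0
        P = pd.DataFrame(coding, index=[p.canonical_string for p in pairs])
        emb = EmbeddingPair(G, P, "identity")
        fit = LinearModelFit(
            W=np.eye(3),
            b=pd.Series(-pb.control_values, index=genes),
            lam=0.0,
            embedding=emb,
        )
        pred = predict_linear_model(fit, P)
        additive = predict_additive_matrix(pb, pairs)
        np.testing.assert_allclose(pred.values, additive.values, atol=1e-12)


class TestRecovery:
    def test_low_rank_recovery_beats_mean(self):
        # data from the bilinear family: the fitted model must beat the mean
        # baseline on held-out singles (full tolerance check lives in the
        # acceptance suite)
        from linpert.data_model import make_single_split, pseudobulk
        from linpert.synthetic import SyntheticSpec, simulate_dataset

        wins = 0
        for seed in range(3):
            spec = SyntheticSpec(
                n_genes=400, n_singles=60, n_doubles=0, cells_per_condition=1,
                true_rank=5, effect_scale=0.5, noise_sd=0.1, seed=seed,
            )
            ds, _ = simulate_dataset(spec)
            pb = pseudobulk(ds)
            split = make_single_split(pb, 0.2, seed)
            train = [l for l in split.train_labels if not l.is_control]
            pb_train = pb.subset_conditions(train)
            G = pca_gene_embedding(pb_train, 5)
            P = perturbation_rows(G, train)
            fit = fit_linear_model(pb_train, EmbeddingPair(G, P), lam=0.1)
            test = list(split.test_labels)
            pred = predict_linear_model(fit, perturbation_rows(G, test))
            mean_pred = predict_mean(pb_train, test)
            e = np.mean([l2_error(pred.column(l), pb.column(l)) for l in test])
            em = np.mean(
                [l2_error(mean_pred.column(l), pb.column(l)) for l in test]
            )
            wins += e < em
        assert wins == 3


class TestRidgeDecoder:
    def test_one_hot_exact(self):
        pb = random_instance(5, 4, seed=10)
        train = [l for l in pb.condition_labels if not l.is_control]
        E = pd.DataFrame(np.eye(3), index=[l.canonical_string for l in train])
        fit = fit_ridge_decoder(E, pb, lam=0.0)
        pred = predict_ridge_decoder(fit, E)
        Y = np.column_stack([pb.column(l) for l in train])
        np.testing.assert_allclose(pred.values, Y, atol=1e-9)

    def test_infinite_shrinkage_gives_row_means(self):
        pb = random_instance(5, 4, seed=11)
        train = [l for l in pb.condition_labels if not l.is_control]
        rng = np.random.default_rng(0)
        E = pd.DataFrame(
            rng.normal(size=(3, 2)), index=[l.canonical_string for l in train]
        )
        fit = fit_ridge_decoder(E, pb, lam=1e12)
        pred = predict_ridge_decoder(fit, E)
        Y = np.column_stack([pb.column(l) for l in train])
        np.testing.assert_allclose(
            pred.values, np.tile(Y.mean(axis=1)[:, None], (1, 3)), atol=1e-6
        )

    def test_normal_equations_oracle(self):
        # oracle: augmented normal equations with an unpenalized intercept
        # column, solved independently
        pb = random_instance(7, 6, seed=12)
        train = [l for l in pb.condition_labels if not l.is_control]
        rng = np.random.default_rng(1)
        E = pd.DataFrame(
            rng.normal(size=(5, 3)), index=[l.canonical_string for l in train]
        )
        lam = 0.7
        fit = fit_ridge_decoder(E, pb, lam=lam)
        E_new = pd.DataFrame(rng.normal(size=(2, 3)), index=["A+ctrl", "B+ctrl"])
        pred = predict_ridge_decoder(fit, E_new)

        X = np.column_stack([np.ones(5), E.to_numpy()])
        Y = np.column_stack([pb.column(l) for l in train]).T  # conds x genes
        penalty = lam * np.diag([0.0, 1.0, 1.0, 1.0])
        beta = np.linalg.solve(X.T @ X + penalty, X.T @ Y)
        X_new = np.column_stack([np.ones(2), E_new.to_numpy()])
        oracle = (X_new @ beta).T
        np.testing.assert_allclose(pred.values, oracle, rtol=1e-8, atol=1e-8)


class TestPredictionMatrix:
    def test_tsv_round_trip(self, tmp_path, simple_pb):
        pred = predict_no_change(simple_pb, [lab("g0+g1"), lab("g1+ctrl")])
        path = tmp_path / "pred.tsv"
        pred.to_tsv(path)
        back = PredictionMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values, pred.values)
        assert back.perturbation_labels == pred.perturbation_labels

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            PredictionMatrix(np.array([[np.nan]]), ["g"], [lab("A+ctrl")])
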