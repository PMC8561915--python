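"""QCI scorer vs an independent eigendecomposition oracle, orientation,
scale contract and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from qcindex.errors import ContractError
from qcindex.indices import INDEX_COLUMNS
from qcindex.qci import QCIScorer, fit_pca, orient_component, score_qci

from conftest import make_index_frame


def eigen_oracle(df: pd.DataFrame):
    """Brute-force reference: leading eigenvector of the correlation
    matrix, oriented by the same MIR-negative rule, plus scores."""
    M = df[list(INDEX_COLUMNS)].to_numpy(float)
    corr = np.corrcoef(M, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v = evecs[:, 0]
    mir = list(INDEX_COLUMNS).index("mir")
    ylr = list(INDEX_COLUMNS).index("ylr")
    pivot = v[mir] if v[mir] != 0 else v[ylr]
    if pivot > 0:
        v = -v
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    return v, evals / evals.sum(), Z @ v


@pytest.mark.parametrize("n", [12, 40, 250])
def test_matches_eigendecomposition_oracle(rng, n):
    df = make_index_frame(rng, n)
    scorer = QCIScorer().fit(df)
    v, share, scores = eigen_oracle(df)
    np.testing.assert_allclose(scorer.loadings_, v, atol=1e-9)
    np.testing.assert_allclose(scorer.explained_share_,
                               np.sort(share)[::-1], atol=1e-9)
    np.testing.assert_allclose(scorer.raw_scores(df), scores, atol=1e-9)


def test_rank_one_structure_gives_full_first_share(rng):
    latent = rng.normal(0, 1, 30)
    df = pd.DataFrame({"pir": 2 + 3 * latent, "mir": 1 - 0.5 * latent,
                       "dpr": 10 * latent, "ylr": 4 - latent})
    scorer = QCIScorer().fit(df)
    assert scorer.explained_share_[0] == pytest.approx(1.0, abs=1e-9)


def test_isotropic_indices_share_a_quarter(rng):
    df = pd.DataFrame(rng.normal(0, 1, (10_000, 4)),
                      columns=list(INDEX_COLUMNS))
    scorer = QCIScorer().fit(df)
    assert scorer.explained_share_[0] == pytest.approx(0.25, abs=0.03)


def test_orientation_forces_mir_negative(rng):
    df = make_index_frame(rng, 60, latent=rng.uniform(0, 1, 60))
    model = fit_pca(df)
    oriented = orient_component(model)
    assert oriented.loadings_[list(INDEX_COLUMNS).index("mir")] < 0


def test_orientation_flip_negates_scores(rng):
    df = make_index_frame(rng, 40)
    model = fit_pca(df)
    raw_before = model.raw_scores(df).copy()
    mir = list(INDEX_COLUMNS).index("mir")
    flipped = model.loadings_[mir] > 0
    orient_component(model)
    raw_after = model.raw_scores(df)
    if flipped:
        np.testing.assert_allclose(raw_after, -raw_before, atol=1e-12)
    else:
        np.testing.assert_allclose(raw_after, raw_before, atol=1e-12)
    # orienting twice is the identity
    orient_component(model)
    np.testing.assert_allclose(model.raw_scores(df), raw_after, atol=1e-12)


def test_oriented_scores_track_latent_quality(rng):
    latent = rng.uniform(0, 1, 200)
    df = make_index_frame(rng, 200, latent=latent)
    scorer = QCIScorer().fit(df)
    rho = spearmanr(scorer.transform(df), latent).statistic
    assert rho > 0.9


def test_fit_extrema_map_to_exact_bounds(rng):
    df = make_index_frame(rng, 80)
    scorer = QCIScorer().fit(df)
    qci = scorer.transform(df)
    assert qci.min() == 0.0
    assert qci.max() == 100.0
    assert ((qci >= 0) & (qci <= 100)).all()


def test_out_of_fit_scores_clamped_with_warning(rng):
    df = make_index_frame(rng, 50)
    scorer = QCIScorer().fit(df)
    extreme = df.iloc[[int(np.argmax(scorer.raw_scores(df)))]].copy()
    extreme["mir"] = df["mir"].min() - 5 * df["mir"].std()
    with pytest.warns(UserWarning, match="clamped"):
        clamped = scorer.transform(extreme)
    assert clamped[0] == 100.0
    unclamped = scorer.transform(extreme, clip=False)
    assert unclamped[0] > 100.0


def test_missing_rows_scored_nan_and_reported(rng):
    df = make_index_frame(rng, 30)
    scorer = QCIScorer().fit(df)
    holed = df.copy()
    holed.loc[3, "pir"] = np.nan
    with pytest.warns(UserWarning, match="missing"):
        qci = scorer.transform(holed)
    assert np.isnan(qci[3])
    assert np.isfinite(np.delete(qci, 3)).all()


def test_fit_drops_incomplete_rows_and_counts_them(rng):
    df = make_index_frame(rng, 30)
    df.loc[:2, "ylr"] = np.nan
    scorer = QCIScorer().fit(df)
    assert scorer.n_dropped_ == 3
    assert scorer.n_fit_units_ == 27


@pytest.mark.parametrize("column, transform", [
    ("pir", lambda s: s + 1000.0),
    ("dpr", lambda s: s * 37.5),
    ("mir", lambda s: 5.0 + 2.0 * s),
])
def test_affine_invariance_of_single_index(rng, column, transform):
    """Shifting or positively scaling one ratio before standardisation
    must leave every QCI unchanged (z-scoring absorbs affine maps)."""
    df = make_index_frame(rng, 100)
    base = QCIScorer().fit(df).transform(df)
    mod = df.copy()
    mod[column] = transform(mod[column])
    changed = QCIScorer().fit(mod).transform(mod)
    np.testing.assert_allclose(changed, base, atol=1e-9)


def test_monotone_in_mir(rng):
    """With the model held fixed, raising a unit's MIR strictly lowers
    its score (orientation contract)."""
    df = make_index_frame(rng, 60)
    scorer = QCIScorer().fit(df)
    bumped = df.copy()
    bumped["mir"] = bumped["mir"] + 0.05
    assert (scorer.transform(bumped, clip=False)
            < scorer.transform(df, clip=False)).all()


def test_contract_errors(rng):
    df = make_index_frame(rng, 4)
    with pytest.raises(ContractError, match=">= 5"):
        QCIScorer().fit(df)
    df = make_index_frame(rng, 20)
    df["ylr"] = 3.0
    with pytest.raises(ContractError, match="ylr"):
        QCIScorer().fit(df)
    with pytest.raises(ContractError):
        QCIScorer().fit(make_index_frame(rng, 20)).transform(
            np.ones((3, 3)))


def test_score_frame_carries_unit_keys(rng):
    df = make_index_frame(rng, 10)
    df["location"] = [f"L{i}" for i in range(10)]
    df["year"] = 2000
    scorer = QCIScorer().fit(df)
    out = score_qci(scorer, df)
    assert list(out.columns) == ["location", "year", "raw_score", "qci"]
    assert len(out) == 10
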