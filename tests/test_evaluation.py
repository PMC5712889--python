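import numpy as np
import pytest

from nirtransfer import choose_master, evaluate, passing_bablok, sel
from nirtransfer.spectra import ReplicateTable


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_evaluate_known_values():
    y = np.array([10.0, 12.0, 14.0, 16.0])
    yhat = y + np.array([0.5, -0.5, 0.5, -0.5])
    rep = evaluate(yhat, y, "set")
    assert rep.n == 4
    assert rep.rmse == pytest.approx(0.5)
    assert rep.rpd == pytest.approx(np.std(y, ddof=1) / 0.5)
    assert 0 < rep.r2 < 1
    rep2 = evaluate(y, y, "perfect")
    assert rep2.rmse == 0.0 and np.isinf(rep2.rpd) and rep2.r2 == pytest.approx(1.0)


def test_evaluate_r2_is_squared_pearson():
    rng = np.random.default_rng(0)
    y = rng.normal(size=50)
    yhat = 3.0 * y + rng.normal(size=50)  # biased but correlated
    rep = evaluate(yhat, y)
    assert rep.r2 == pytest.approx(np.corrcoef(yhat, y)[0, 1] ** 2)


def test_evaluate_errors():
    with pytest.raises(ValueError, match="lengths"):
        evaluate([1.0, 2.0], [1.0])
    with pytest.raises(ValueError, match="zero-variance"):
        evaluate([1.0, 2.0], [3.0, 3.0])
    with pytest.raises(ValueError, match="at least 2"):
        evaluate([1.0], [1.0])


# ---------------------------------------------------------------------------
# SEL
# ---------------------------------------------------------------------------

def test_sel_hand_computed():
    t = ReplicateTable(
        sample_ids=["a", "b"],
        values=np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]),
    )
    # sum of squared deviations: sample a -> 2.0, sample b -> 0.0; N = 2
    assert sel(t) == pytest.approx(np.sqrt(2.0 / 2.0))


def test_sel_excludes_short_rows_with_warning():
    t = ReplicateTable(
        sample_ids=["a", "only_one"],
        values=np.array([[1.0, 3.0], [5.0, np.nan]]),
    )
    with pytest.warns(UserWarning, match="only_one"):
        v = sel(t)
    assert v == pytest.approx(np.sqrt(2.0 / 1.0))
    with pytest.raises(ValueError):
        sel(ReplicateTable(sample_ids=["x"], values=np.array([[1.0, np.nan]])))


# ---------------------------------------------------------------------------
# Passing-Bablok
# ---------------------------------------------------------------------------

def pb_slope_oracle(x, y):
    """Exhaustive enumeration of the 1983 procedure's slope estimate."""
    S = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                S.append(s)
    S.sort()
    N = len(S)
    K = sum(1 for s in S if s < -1.0)
    if N % 2 == 1:
        return S[min(max((N - 1) // 2 + K, 0), N - 1)], K
    lo = min(max(N // 2 - 1 + K, 0), N - 1)
    hi = min(max(N // 2 + K, 0), N - 1)
    return 0.5 * (S[lo] + S[hi]), K


def test_identity_relation_accepted():
    x = np.linspace(10.0, 24.0, 15)
    r = passing_bablok(x, x.copy())
    assert r.slope == pytest.approx(1.0)
    assert r.intercept == pytest.approx(0.0)
    assert r.h0_accepted


def test_doubling_relation_rejected():
    rng = np.random.default_rng(1)
    x = np.linspace(10.0, 24.0, 30)
    y = 2.0 * x + rng.normal(0, 0.05, size=30)
    r = passing_bablok(x, y)
    assert r.slope == pytest.approx(2.0, abs=0.05)
    assert not r.h0_accepted


@pytest.mark.parametrize("seed", range(8))
def test_slope_and_k_match_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 11))
    x = rng.normal(size=n)
    y = rng.choice([-2.0, 1.0]) * x + rng.normal(0, 0.5, size=n)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = passing_bablok(x, y)
    slope, K = pb_slope_oracle(x, y)
    assert r.slope == pytest.approx(slope)
    assert r.k_offset == K


def test_pb_input_handling():
    with pytest.raises(ValueError, match="at least 3"):
        passing_bablok([1.0, 2.0], [1.0, 2.0])
    with pytest.warns(UserWarning, match="fewer than 10"):
        with pytest.raises(ValueError, match="identical"):
            passing_bablok([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="fewer than 10"):
        passing_bablok([1.0, 2.0, 3.0, 4.0], [1.1, 2.0, 3.2, 3.9])


def test_pb_ci_orders_and_contains_estimate():
    rng = np.random.default_rng(2)
    x = np.linspace(10, 24, 40)
    y = x + rng.normal(0, 0.3, size=40)
    r = passing_bablok(x, y)
    assert r.slope_ci[0] <= r.slope <= r.slope_ci[1]
    assert r.intercept_ci[0] <= r.intercept_ci[1]
    assert r.h0_accepted == (
        (r.slope_ci[0] <= 1.0 <= r.slope_ci[1])
        and (r.intercept_ci[0] <= 0.0 <= r.intercept_ci[1])
    )


def test_choose_master():
    rng = np.random.default_rng(3)
    x = np.linspace(10, 24, 40)
    good = passing_bablok(x, x + rng.normal(0, 0.2, size=40))
    bad = passing_bablok(x, 2.0 * x + rng.normal(0, 0.2, size=40))
    assert good.h0_accepted and not bad.h0_accepted
    assert choose_master({"A": bad, "B": good}) == "B"
    assert choose_master({"A": bad, "B": bad}) is None
    assert choose_master({"A": good, "B": good}) in ("A", "B")
    with pytest.raises(ValueError):
        choose_master({})
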