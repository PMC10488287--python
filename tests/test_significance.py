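import numpy as np
import pytest
import scipy.special

from sctiger.causal import ADDSTCNConfig
from sctiger.matrix import ExpressionMatrix
from sctiger.significance import (
    EdgeFrequencyTable,
    background_run,
    fit_significance,
    frequency_histogram,
    run_permutations,
    shuffle_within_genes,
    significant_edges,
)

FAST = ADDSTCNConfig(epochs=150, pi_shuffles=3, pi_aggregate="all", seed=0)


def _paired_with_planted_edge(T=150, n_noise=4, seed=0):
    """case - control contains a strong lag-1 dependency GOI -> RESP.

    The differential signal is an AR(1) series, so the target's own past
    cannot substitute for the cause channel.
    """
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal(T)
    for t in range(1, T):
        sig[t] = 0.6 * sig[t - 1] + 0.8 * sig[t]
    base = rng.uniform(4.0, 6.0, size=(2 + n_noise, 1)) * np.ones((1, T))
    control = base + rng.normal(0, 0.1, base.shape)
    case = control + rng.normal(0, 0.1, base.shape)
    case[0] += sig                      # GOI differential
    case[1] += 1.5 * np.roll(sig, 1)    # RESP follows at lag 1
    for k in range(n_noise):
        case[2 + k] += rng.normal(0, 0.4, T)
    genes = ["GOI", "RESP"] + [f"N{k}" for k in range(n_noise)]
    mk = lambda c, cond: ExpressionMatrix(
        counts=np.clip(c, 0, None), gene_ids=genes,
        cell_ids=[f"{cond}{i}" for i in range(T)], condition=cond)
    return mk(case, "case"), mk(control, "ctrl")


class TestRunPermutations:
    def test_deterministic_and_counts_bounded(self):
        case, control = _paired_with_planted_edge()
        t1 = run_permutations(case, control, None, R=2, cfg=FAST, seed=1)
        t2 = run_permutations(case, control, None, R=2, cfg=FAST, seed=1)
        assert t1.counts == t2.counts
        assert all(0 <= c <= 2 for c in t1.counts.values())

    def test_planted_edge_recalled(self):
        case, control = _paired_with_planted_edge()
        table = run_permutations(case, control, None, R=5, cfg=FAST, seed=0)
        assert table.pair_counts().get(("GOI", "RESP"), 0) >= 4

    def test_r_below_one_rejected(self):
        case, control = _paired_with_planted_edge()
        with pytest.raises(ValueError):
            run_permutations(case, control, None, R=0, cfg=FAST)


class TestBackground:
    def test_shuffle_preserves_marginals(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(counts=rng.poisson(3.0, size=(4, 30)).astype(float),
                             gene_ids=list("abcd"), cell_ids=[f"c{i}" for i in range(30)])
        s = shuffle_within_genes(m, np.random.default_rng(1))
        for g in range(4):
            assert sorted(s.counts[g]) == sorted(m.counts[g])

    def test_background_deterministic(self):
        case, control = _paired_with_planted_edge()
        b1 = background_run(case, control, None, R=2, cfg=FAST, seed=3)
        b2 = background_run(case, control, None, R=2, cfg=FAST, seed=3)
        assert b1.counts == b2.counts
        assert b1.is_background

    def test_background_mostly_empty_on_structured_data(self):
        case, control = _paired_with_planted_edge()
        b = background_run(case, control, None, R=3, cfg=FAST, seed=0)
        # shuffling destroys the planted structure
        assert b.pair_counts().get(("GOI", "RESP"), 0) <= 1


def _bg_table(counts_list, genes, R=10):
    """Background table with given per-pair counts (rest of universe zero)."""
    pairs = [(a, b) for a in genes for b in genes if a != b]
    table = EdgeFrequencyTable(counts={}, R=R, genes=list(genes), is_background=True)
    for (a, b), c in zip(pairs, counts_list):
        if c:
            table.counts[(a, b, "positive")] = c
    return table


def _nb_tail_oracle(mean, var, m):
    """Brute-force NB tail P(X >= m) by direct pmf summation.

    pmf(k) = Gamma(k + r) / (Gamma(r) k!) * p^r * (1 - p)^k with the
    method-of-moments parameters r = mean^2/(var - mean), p = mean/var.
    """
    r = mean**2 / (var - mean)
    p = mean / var
    total = 0.0
    for k in range(m):
        logpmf = (
            scipy.special.gammaln(k + r)
            - scipy.special.gammaln(r)
            - scipy.special.gammaln(k + 1)
            + r * np.log(p)
            + k * np.log(1 - p)
        )
        total += np.exp(logpmf)
    return 1.0 - total


class TestFitSignificance:
    def test_degenerate_all_zero_background(self):
        # a lone detection is not recurrence: the floor is 2 (for R >= 2)
        table = _bg_table([], list("abcd"))
        model = fit_significance(table, alpha=0.05)
        assert model.min_detections == 2
        assert model.tail(1) == 0.0

    def test_nb_threshold_matches_tail_summation_oracle(self):
        # engineered background: mean 2, variance 4 over a 12-pair universe
        genes = list("abcd")
        counts = [0, 0, 0, 0, 2, 2, 2, 2, 3, 3, 3, 7]
        table = _bg_table(counts, genes, R=10)
        model = fit_significance(table, alpha=0.05)
        mean, var = np.mean(counts), np.var(counts, ddof=1)
        assert model.mean == pytest.approx(mean)
        assert var > mean  # NB branch active
        expect = 1
        while _nb_tail_oracle(mean, var, expect) > 0.05:
            expect += 1
        assert model.min_detections == expect
        assert model.tail(model.min_detections) <= 0.05

    def test_alpha_one_passes_everything(self):
        table = _bg_table([1, 2], list("abc"))
        model = fit_significance(table, alpha=1.0)
        assert model.min_detections == 0

    def test_min_detections_monotone_in_alpha(self):
        table = _bg_table([0, 0, 0, 0, 2, 2, 2, 2, 3, 3, 3, 7], list("abcd"))
        thresholds = [fit_significance(table, a).min_detections
                      for a in (0.01, 0.05, 0.1, 0.5)]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_rejects_non_background(self):
        t = EdgeFrequencyTable(counts={}, R=5, genes=["a", "b"])
        with pytest.raises(ValueError, match="background"):
            fit_significance(t)

    def test_empty_universe(self):
        t = EdgeFrequencyTable(counts={}, R=5, genes=["a"], is_background=True)
        with pytest.raises(ValueError, match="universe"):
            fit_significance(t)


class TestSignificantEdges:
    def _model(self, min_det, R=100):
        table = _bg_table([], list("ab"), R=R)
        model = fit_significance(table, alpha=0.05)
        model.min_detections = min_det
        return model

    def test_clear_pass(self):
        obs = EdgeFrequencyTable(counts={("a", "b", "positive"): 100}, R=100,
                                 genes=["a", "b"],
                                 delays={("a", "b", "positive"): [1] * 100})
        edges = significant_edges(obs, self._model(60))
        assert len(edges) == 1
        assert edges[0].count == 100 and edges[0].delay == 1

    def test_boundary_below_dropped(self):
        obs = EdgeFrequencyTable(counts={("a", "b", "positive"): 59}, R=100,
                                 genes=["a", "b"])
        assert significant_edges(obs, self._model(60)) == []

    def test_sign_majority_kept_tie_dropped(self):
        obs = EdgeFrequencyTable(
            counts={("a", "b", "positive"): 70, ("a", "b", "negative"): 20,
                    ("b", "a", "positive"): 40, ("b", "a", "negative"): 40},
            R=100, genes=["a", "b"],
            delays={("a", "b", "positive"): [2] * 70, ("a", "b", "negative"): [2] * 20},
        )
        edges = significant_edges(obs, self._model(60))
        assert len(edges) == 1  # b->a tie dropped despite total 80
        assert edges[0].sign == "positive" and edges[0].count == 90

    def test_mismatched_r_rejected(self):
        obs = EdgeFrequencyTable(counts={}, R=50, genes=["a", "b"])
        with pytest.raises(ValueError, match="R="):
            significant_edges(obs, self._model(10, R=100))


def test_frequency_histogram():
    obs = EdgeFrequencyTable(
        counts={("a", "b", "positive"): 3, ("b", "c", "negative"): 3,
                ("a", "c", "positive"): 1},
        R=5, genes=list("abc"))
    assert frequency_histogram(obs) == {1: 1, 3: 2}


def test_counts_exchangeable_under_run_relabeling():
    """Counting is a sum over runs; permuting run order cannot change it."""
    case, control = _paired_with_planted_edge()
    fwd = run_permutations(case, control, None, R=3, cfg=FAST, seed=7)
    # rebuild from the same runs in a different order by summing single runs
    singles = [run_permutations(case, control, None, R=1, cfg=FAST, seed=7 + r)
               for r in (2, 0, 1)]
    merged: dict = {}
    for s in singles:
        for k, v in s.counts.items():
            merged[k] = merged.get(k, 0) + v
    assert merged == fwd.counts
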