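import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from tcrkit import (
    SimulationConfig,
    build_motif_matrix,
    count_kmers,
    embed_new,
    filter_mwu,
    filter_prevalence,
    filter_samples,
    fit_embedding,
    mann_whitney_u,
    simulate_cohort,
    zscore_normalize,
)
from tcrkit.errors import EmptyInputError, StageError
from tcrkit.motifs import MotifMatrix, motif_universe
from tests.conftest import make_repertoire


def exhaustive_mwu_oracle(x, y):
    """Independent permutation oracle: U by pair counting, p by enumeration."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    pooled = x + y
    # two-sided: assignments as or more extreme on either side of nm/2
    d_obs = abs(u_obs - n * m / 2.0)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(n + m), n):
        mask = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n + m) if i not in mask]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - n * m / 2.0) >= d_obs - 1e-9:
            extreme += 1
    return u_obs, min(1.0, extreme / total)


class TestCountKmers:
    def test_sliding_window(self):
        rep = make_repertoire([("CASSF", "V", "J", 1)])
        assert count_kmers(rep) == Counter({"CAS": 1, "ASS": 1, "SSF": 1})

    def test_repeated_letters(self):
        rep = make_repertoire([("CAAAF", "V", "J", 1)])
        assert count_kmers(rep) == Counter({"CAA": 1, "AAA": 1, "AAF": 1})

    def test_weighted_multiplies_by_count(self):
        rep = make_repertoire([("CASSF", "V", "J", 4)])
        assert count_kmers(rep, weighted=True)["CAS"] == 4

    def test_window_conservation(self, sim_rep):
        counts = count_kmers(sim_rep)
        expected = sum(len(s) - 2 for s in set(sim_rep.sequences))
        assert sum(counts.values()) == expected

    def test_short_sequences_skipped(self):
        rep = make_repertoire([("CAF", "V", "J", 1), ("CASSF", "V", "J", 1)])
        counts = count_kmers(rep, k=5)
        assert sum(counts.values()) == 1

    def test_universe_cap(self, sim_rep):
        assert len(motif_universe()) == 8000
        assert set(count_kmers(sim_rep)) <= set(motif_universe())


class TestMotifMatrix:
    def test_block_structure_disjoint_samples(self):
        r1 = make_repertoire([("CAAAAAAAAF", "V", "J", 1)], "s1")
        r2 = make_repertoire([("CWWWWWWWWF", "V", "J", 1)], "s2")
        m = build_motif_matrix([r1, r2], {"s1": "a", "s2": "b"})
        overlap = (m.values.loc["s1"] > 0) & (m.values.loc["s2"] > 0)
        assert not overlap.any()

    def test_row_sums_are_window_counts(self, sim_rep):
        m = build_motif_matrix([sim_rep], {})
        assert m.values.loc[sim_rep.sample_id].sum() == sum(
            count_kmers(sim_rep).values()
        )

    def test_duplicate_sample_id_rejected(self, sim_rep):
        with pytest.raises(ValueError):
            build_motif_matrix([sim_rep, sim_rep], {})


def _matrix_with_totals(totals):
    """One-motif-per-sample matrix so total = that motif's count."""
    samples = {f"s{i:02d}": t for i, t in enumerate(totals)}
    motifs = sorted({f"M{i}" for i in range(len(totals))})
    values = pd.DataFrame(0, index=sorted(samples), columns=motifs)
    for i, (s, t) in enumerate(sorted(samples.items())):
        values.loc[s, f"M{i}"] = t
    return MotifMatrix(values=values, labels={}, stage="raw")


class TestFilterSamples:
    def test_ten_samples_quantile_rule(self):
        m = _matrix_with_totals([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        out = filter_samples(m)
        kept_totals = sorted(out.values.sum(axis=1))
        assert kept_totals == [3, 4, 5, 6, 7, 8]
        assert out.stage == "sample_filtered"

    def test_zero_quantiles_identity(self):
        m = _matrix_with_totals([5, 1, 9])
        out = filter_samples(m, 0, 0)
        assert list(out.values.index) == list(m.values.index)

    def test_small_cohort_ceiling_rule(self):
        m = _matrix_with_totals([1, 5, 9])
        out = filter_samples(m)  # ceil(3*0.2)=1 from each tail
        assert sorted(out.values.sum(axis=1)) == [5]

    def test_all_removed_raises(self):
        m = _matrix_with_totals([1, 2])
        with pytest.raises(EmptyInputError):
            filter_samples(m, 0.5, 0.5)

    def test_wrong_stage_rejected(self):
        m = _matrix_with_totals([1, 2, 3])
        out = filter_samples(m, 0, 0)
        with pytest.raises(StageError):
            filter_samples(out)


class TestFilterPrevalence:
    def _matrix(self):
        values = pd.DataFrame(
            {
                "AAA": [1, 2, 3, 0],  # 3/4 disease
                "CCC": [1, 1, 0, 0],  # 2/4 = exactly 0.5
                "DDD": [0, 0, 0, 0],  # absent
            },
            index=["d1", "d2", "d3", "d4"],
        )
        labels = {s: "disease" for s in values.index}
        return MotifMatrix(values=values, labels=labels, stage="sample_filtered")

    def test_strict_majority_rule(self):
        out = filter_prevalence(self._matrix(), "disease")
        assert out.motifs == ["AAA"]  # 0.75 > 0.5 kept; 0.5 and 0 removed
        assert out.stage == "prevalence_filtered"

    def test_unknown_group(self):
        with pytest.raises(KeyError):
            filter_prevalence(self._matrix(), "nope")


class TestMannWhitney:
    def test_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / 20)  # exact enumeration over C(6,3)

    def test_identical_multisets(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # nm/2
        assert p == 1.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=int(rng.integers(1, 8)))
            y = rng.integers(0, 6, size=int(rng.integers(1, 8)))
            ux, px = mann_whitney_u(x, y)
            uy, py = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))
            assert px == pytest.approx(py)

    def test_all_identical_values(self):
        _, p = mann_whitney_u([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            x = rng.integers(0, 5, size=n)
            y = rng.integers(0, 5, size=m)
            u_ref, p_ref = exhaustive_mwu_oracle(x, y)
            u, p = mann_whitney_u(x, y)
            assert u == pytest.approx(u_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_large_sample_against_scipy(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 55)
        u, p = mann_whitney_u(x, y)
        res = scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=6),
        st.lists(st.integers(0, 3), min_size=1, max_size=6),
    )
    def test_p_in_unit_interval(self, x, y):
        _, p = mann_whitney_u(x, y)
        assert 0.0 < p <= 1.0


class TestFilterMwu:
    def _pair(self, disease_vals, healthy_vals, motifs=("AAA",)):
        d = MotifMatrix(
            values=pd.DataFrame(disease_vals, columns=list(motifs),
                                index=[f"d{i}" for i in range(len(disease_vals))]),
            labels={}, stage="prevalence_filtered",
        )
        h = MotifMatrix(
            values=pd.DataFrame(healthy_vals, columns=list(motifs),
                                index=[f"h{i}" for i in range(len(healthy_vals))]),
            labels={}, stage="sample_filtered",
        )
        return d, h

    def test_identical_distribution_removed(self):
        d, h = self._pair([[3], [4], [5]], [[3], [4], [5]])
        assert filter_mwu(d, h).motifs == []

    def test_fully_separated_kept(self):
        d, h = self._pair([[50 + i] for i in range(10)], [[0]] * 10)
        out = filter_mwu(d, h)
        assert out.motifs == ["AAA"]
        assert out.stage == "mwu_filtered"

    def test_motif_absent_from_healthy_compared_to_zeros(self):
        d = MotifMatrix(
            values=pd.DataFrame({"AAA": [9, 8, 7, 9, 8, 9]},
                                index=[f"d{i}" for i in range(6)]),
            labels={}, stage="prevalence_filtered",
        )
        h = MotifMatrix(
            values=pd.DataFrame({"CCC": [1, 1, 1, 1, 1, 1]},
                                index=[f"h{i}" for i in range(6)]),
            labels={}, stage="sample_filtered",
        )
        assert filter_mwu(d, h).motifs == ["AAA"]

    def test_alpha_one_keeps_everything(self):
        d, h = self._pair([[3], [4]], [[3], [4]])
        assert filter_mwu(d, h, alpha=1.0).motifs == ["AAA"]


class TestZscore:
    def test_hand_column(self):
        m = MotifMatrix(
            values=pd.DataFrame({"AAA": [2, 4, 6]}, index=["a", "b", "c"]),
            labels={}, stage="mwu_filtered",
        )
        z = zscore_normalize(m)
        assert z.values["AAA"].tolist() == pytest.approx(
            [-1.2247448714, 0.0, 1.2247448714]
        )
        assert z.stage == "normalized"

    def test_constant_column_zeroed(self):
        m = MotifMatrix(
            values=pd.DataFrame({"AAA": [5, 5, 5], "CCC": [1, 2, 3]},
                                index=["a", "b", "c"]),
            labels={}, stage="mwu_filtered",
        )
        z = zscore_normalize(m)
        assert (z.values["AAA"] == 0).all()

    def test_columns_standardized(self, rng):
        vals = pd.DataFrame(rng.poisson(5, size=(10, 20)),
                            index=[f"s{i}" for i in range(10)],
                            columns=[f"M{i}" for i in range(20)])
        z = zscore_normalize(MotifMatrix(values=vals, labels={}, stage="raw"))
        means = z.values.mean(axis=0)
        stds = z.values.std(axis=0, ddof=0)
        assert np.allclose(means, 0, atol=1e-9)
        assert all(abs(s) < 1e-9 or abs(s - 1) < 1e-9 for s in stds)


@pytest.fixture(scope="module")
def fitted_cohort():
    samples, labels = simulate_cohort(
        {"disease_a": 12, "disease_b": 12},
        SimulationConfig(n_clones=300, seed=5),
    )
    m = zscore_normalize(
        MotifMatrix(
            values=build_motif_matrix(samples, labels).values,
            labels=labels, stage="mwu_filtered",
        )
    )
    model = fit_embedding(m, seed=0)
    return samples, labels, m, model


class TestEmbedding:
    def test_determinism(self, fitted_cohort):
        _, _, m, model = fitted_cohort
        again = fit_embedding(m, seed=0)
        assert np.allclose(
            model.reference_coordinates.to_numpy(),
            again.reference_coordinates.to_numpy(),
        )

    def test_duplicate_rows_identical_coordinates(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(8, 30)),
                            index=[f"s{i}" for i in range(8)],
                            columns=[f"M{i}" for i in range(30)])
        vals.iloc[1] = vals.iloc[0]
        m = zscore_normalize(MotifMatrix(values=vals, labels={}, stage="raw"))
        model = fit_embedding(m)
        coords = model.reference_coordinates.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-6)

    def test_too_few_samples(self):
        vals = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                            columns=["M1", "M2"])
        m = MotifMatrix(values=vals, labels={}, stage="normalized")
        with pytest.raises(ValueError):
            fit_embedding(m, n_components=2)

    def test_requires_normalized_stage(self, sim_rep):
        m = build_motif_matrix([sim_rep], {})
        with pytest.raises(StageError):
            fit_embedding(m)

    def test_group_separation(self, fitted_cohort):
        _, labels, _, model = fitted_cohort
        coords = model.reference_coordinates
        lab = pd.Series({s: labels[s] for s in coords.index})
        a = coords[lab == "disease_a"].to_numpy()
        b = coords[lab == "disease_b"].to_numpy()
        centroid_gap = np.linalg.norm(a.mean(0) - b.mean(0))
        within = np.mean(
            [np.linalg.norm(x - a.mean(0)) for x in a]
            + [np.linalg.norm(x - b.mean(0)) for x in b]
        )
        assert centroid_gap > 3 * within


class TestEmbedNew:
    def test_training_sample_self_projection(self, fitted_cohort):
        samples, _, m, model = fitted_cohort
        coords = model.reference_coordinates
        ranges = coords.max() - coords.min()
        rep = samples[0]
        point = embed_new(model, count_kmers(rep))
        fitted = coords.loc[rep.sample_id].to_numpy()
        assert np.all(np.abs(point - fitted) <= 0.10 * ranges.to_numpy() + 1e-12)

    def test_new_samples_project_to_own_group(self, fitted_cohort):
        _, labels, _, model = fitted_cohort
        hold, hold_labels = simulate_cohort(
            {"disease_a": 5, "disease_b": 5},
            SimulationConfig(n_clones=300, seed=99),
        )
        coords = model.reference_coordinates
        lab = pd.Series({s: labels[s] for s in coords.index})
        cent = {
            g: coords[lab == g].mean().to_numpy() for g in ("disease_a", "disease_b")
        }
        correct = 0
        for rep in hold:
            p = embed_new(model, count_kmers(rep))
            own = hold_labels[rep.sample_id]
            other = "disease_b" if own == "disease_a" else "disease_a"
            correct += np.linalg.norm(p - cent[own]) < np.linalg.norm(p - cent[other])
        assert correct >= 8

    def test_all_zero_vector_returns_centroid(self, fitted_cohort):
        _, _, _, model = fitted_cohort
        point = embed_new(model, {})
        centroid = model.reference_coordinates.to_numpy().mean(axis=0)
        assert np.allclose(point, centroid)


def test_pipeline_determinism():
    kwargs = dict(n_per_group={"disease_a": 6, "disease_b": 6},
                  base_cfg=SimulationConfig(n_clones=200, seed=21))
    from tcrkit.motifs import discriminative_pipeline

    runs = []
    for _ in range(2):
        samples, labels = simulate_cohort(**kwargs)
        m = discriminative_pipeline(samples, labels, healthy_label=None,
                                    sample_filter=False)
        runs.append((tuple(m.motifs), m.values.to_numpy().copy()))
    assert runs[0][0] == runs[1][0]
    assert np.array_equal(runs[0][1], runs[1][1])


def test_filters_never_add_rows_or_columns(rng):
    samples, labels = simulate_cohort(
        {"disease_a": 5, "healthy": 5}, SimulationConfig(n_clones=120, seed=8)
    )
    m = build_motif_matrix(samples, labels)
    f1 = filter_samples(m, 0.1, 0.1)
    assert set(f1.sample_ids) <= set(m.sample_ids)
    assert f1.motifs == m.motifs
    f2 = filter_prevalence(f1, "disease_a")
    assert set(f2.motifs) <= set(f1.motifs)
    disease_rows = [s for s in f2.sample_ids if labels[s] == "disease_a"]
    d = MotifMatrix(values=f2.values.loc[disease_rows], labels=labels,
                    stage="prevalence_filtered")
    healthy_rows = [s for s in f1.sample_ids if labels[s] == "healthy"]
    h = MotifMatrix(values=f1.values.loc[healthy_rows], labels=labels,
                    stage="sample_filtered")
    f3 = filter_mwu(d, h)
    assert set(f3.motifs) <= set(f2.motifs)
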