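import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from darkprofiler.profiles import (
    DEFAULT_SIGNIFICANCE_CUTOFF,
    ConstantProfileError,
    ControlMadScaler,
    ReplicateCorrelationSelector,
    activity_call,
    aggregate_to_wells,
    biosimilarity,
    compute_zprofile,
    induction,
    mad,
    replicate_concordance,
    select_robust_features,
    zscore_wells,
)
from darkprofiler.synthdata import (
    GeneratorSpec,
    generate_reference_plate_pair,
    generate_replicate_pair,
    generate_run,
    make_cluster_templates,
)

# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _site_table(values, plate="P1", well="A01"):
    n = len(values)
    return pd.DataFrame({
        "plate_id": plate, "well": well, "site": range(1, n + 1),
        "compound_id": "c1", "concentration_um": 10.0, "role": "test",
        "dmso_percent": 0.1, "f": values,
    })


@pytest.mark.parametrize("values,expected", [
    (list(range(1, 10)), 5.0),        # nine sites, median of 1..9
    ([7.5], 7.5),                     # single site: identity
    ([2.0, 4.0, 100.0], 4.0),         # outlier site does not drag the median
])
def test_aggregate_site_medians(values, expected):
    out = aggregate_to_wells(_site_table(values))
    assert len(out) == 1
    assert out.loc[0, "f"] == expected


def test_aggregate_excludes_missing_and_flags_all_missing(caplog):
    df = _site_table([1.0, np.nan, 3.0])
    assert aggregate_to_wells(df).loc[0, "f"] == 2.0
    df_all_nan = pd.concat(
        [_site_table([np.nan, np.nan], well="A02"), df], ignore_index=True)
    with caplog.at_level("WARNING"):
        out = aggregate_to_wells(df_all_nan)
    assert out.set_index("well").loc["A02", "f"] != out.set_index("well").loc["A02", "f"]  # NaN
    assert any("no values" in r.message for r in caplog.records)


def test_aggregate_replicate_plates_by_compound():
    df = pd.concat([
        _site_table([1.0], plate="P1"),
        _site_table([3.0], plate="P2"),
        _site_table([11.0], plate="P3"),
    ], ignore_index=True).drop(columns="site")
    out = aggregate_to_wells(df, by=("compound_id", "concentration_um"))
    assert len(out) == 1
    assert out.loc[0, "f"] == 3.0


# ---------------------------------------------------------------------------
# MAD scaling / Z-scores
# ---------------------------------------------------------------------------


def test_mad_conventions():
    x = [1.0, 2.0, 3.0]
    assert mad(x) == 1.0
    assert mad(x, scale="normal") == pytest.approx(1.4826, abs=1e-3)


def test_control_mad_scaler_hand_case():
    scaler = ControlMadScaler().fit([[1.0], [2.0], [3.0]])
    assert scaler.transform([[5.0]])[0, 0] == pytest.approx(3.0)
    assert scaler.transform([[2.0]])[0, 0] == 0.0


def test_control_mad_scaler_degenerate_controls():
    scaler = ControlMadScaler(eps_abs=1e-6).fit([[4.0], [4.0], [4.0], [4.0]])
    assert scaler.degenerate_mask_[0]
    z = scaler.transform([[7.0]])[0, 0]
    assert np.isfinite(z) and z == pytest.approx(3.0 / max(1e-6, 1e-6 * 4.0))


def test_control_mad_scaler_is_sklearn_compatible():
    scaler = ControlMadScaler(mad_scale="normal")
    assert clone(scaler).get_params()["mad_scale"] == "normal"
    X = np.random.default_rng(0).normal(size=(30, 4))
    Z = scaler.fit(X).transform(X)
    assert Z.shape == X.shape
    # control observations score to per-feature median zero
    assert np.abs(np.median(Z, axis=0)).max() < 1e-12


def test_zscore_wells_hand_case(small_well_table):
    prof = zscore_wells(small_well_table, significance_cutoff=3.0)
    assert prof.loc[("cpd_a", 10.0), "fa"] == pytest.approx(3.0)
    assert prof.loc[("cpd_a", 10.0), "fb"] == 0.0
    assert prof.loc[("cpd_a", 10.0), "induction"] == pytest.approx(50.0)
    assert prof.loc[("cpd_b", 10.0), "fb"] == pytest.approx(3.0)


def test_compute_zprofile_single_compound(small_well_table):
    zp = compute_zprofile(small_well_table, None, "cpd_a", 10.0,
                          significance_cutoff=3.0)
    assert zp.z["fa"] == pytest.approx(3.0)
    assert zp.induction == pytest.approx(50.0)
    assert len(zp) == 2


def test_zscore_wells_matches_controls_by_dmso_load(small_well_table):
    # same plate, different DMSO load: controls at 0.3% sit far away, and the
    # test well at 0.3% must be scored against them, not the 0.1% controls
    extra = pd.DataFrame({
        "plate_id": "P001",
        "well": ["C01", "C02", "C03", "D01"],
        "compound_id": ["DMSO"] * 3 + ["cpd_hi"],
        "concentration_um": [0.0] * 3 + [30.0],
        "role": ["control"] * 3 + ["test"],
        "dmso_percent": 0.3,
        "fa": [101.0, 102.0, 103.0, 104.0],
        "fb": [10.0, 20.0, 30.0, 20.0],
    })
    prof = zscore_wells(pd.concat([small_well_table, extra], ignore_index=True))
    assert prof.loc[("cpd_hi", 30.0), "fa"] == pytest.approx(2.0)


def test_zscore_wells_requires_enough_matching_controls(small_well_table):
    starved = small_well_table.drop(index=[1, 2])
    starved.loc[0, "role"] = "control"
    with pytest.raises(ValueError, match="control"):
        zscore_wells(starved)


def test_zscore_wells_rejects_profiles_with_missing_features(small_well_table):
    df = small_well_table.copy()
    df.loc[df["compound_id"] == "cpd_b", ["fa", "fb"]] = np.nan
    prof, diags = zscore_wells(df, return_diagnostics=True,
                               max_missing_fraction=0.05)
    assert ("cpd_b", 10.0) in diags.rejected_profiles
    assert ("cpd_b", 10.0) not in prof.index


# ---------------------------------------------------------------------------
# induction / activity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("z,cutoff,expected", [
    ([0.0] * 6, 3.0, 0.0),
    ([0, 0, 4, -5, 1], 3.0, 40.0),
    ([5, -6, 7, 8], 3.0, 100.0),
    ([3.0, 0.0], 3.0, 50.0),          # boundary |z| == cutoff counts
])
def test_induction_counts_significant_features(z, cutoff, expected):
    assert induction(z, cutoff=cutoff) == pytest.approx(expected)


def test_induction_empty_vector_is_an_error():
    with pytest.raises(ValueError):
        induction([])


@given(st.lists(st.floats(-20, 20), min_size=3, max_size=60))
@settings(derandomize=True, max_examples=50)
def test_induction_monotone_in_cutoff_and_order_invariant(z):
    cuts = [0.5, 1.0, 3.0, 5.0]
    vals = [induction(z, cutoff=c) for c in cuts]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    perm = list(reversed(z))
    assert induction(perm, cutoff=3.0) == induction(z, cutoff=3.0)


@pytest.mark.parametrize("ind,expected", [
    (5.0, True), (4.9, False), (12.0, True),
])
def test_activity_call_boundary_inclusive(ind, expected):
    assert activity_call(ind) is expected


# ---------------------------------------------------------------------------
# biosimilarity
# ---------------------------------------------------------------------------


def test_biosimilarity_examples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert biosimilarity(x, x) == pytest.approx(100.0)
    assert biosimilarity(x, -x) == 0.0
    assert biosimilarity(x, [1, 2, 3, 5]) == pytest.approx(98.3, abs=0.1)


def test_biosimilarity_rejects_constant_or_mismatched_input():
    with pytest.raises(ConstantProfileError):
        biosimilarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        biosimilarity([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        biosimilarity([1.0], [2.0])


def test_biosimilarity_agrees_with_pearson_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(3, 100))
        x, y = rng.normal(size=(2, n))
        r = stats.pearsonr(x, y).statistic
        assert biosimilarity(x, y) == pytest.approx(max(0.0, r) * 100, abs=1e-9)


@given(st.integers(0, 2**32 - 1), st.floats(0.1, 50), st.floats(-100, 100))
@settings(derandomize=True, max_examples=50)
def test_biosimilarity_symmetric_and_affine_invariant(seed, a, b):
    g = np.random.default_rng(seed)
    x, y = g.normal(size=(2, 20))
    s = biosimilarity(x, y)
    assert biosimilarity(y, x) == pytest.approx(s, abs=1e-9)
    assert biosimilarity(a * x + b, y) == pytest.approx(s, abs=1e-6)


# ---------------------------------------------------------------------------
# robust feature selection
# ---------------------------------------------------------------------------


def test_selector_identical_and_anticorrelated_features():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(30, 2))
    A = base.copy()
    B = np.column_stack([base[:, 0], -base[:, 1]])  # negated second feature
    sel = ReplicateCorrelationSelector(min_similarity=80).fit(A, B)
    assert sel.similarities_[0] == pytest.approx(100.0)
    assert sel.similarities_[1] == 0.0
    assert list(sel.get_support()) == [True, False]


def test_selector_drops_constant_features(caplog):
    A = np.column_stack([np.ones(10), np.arange(10.0)])
    B = A.copy()
    with caplog.at_level("WARNING"):
        sel = ReplicateCorrelationSelector().fit(A, B)
    assert np.isnan(sel.similarities_[0])
    assert list(sel.get_support()) == [False, True]


def test_select_robust_features_recovers_planted_signal():
    rep_a, rep_b, signal = generate_reference_plate_pair(
        n_signal=10, n_noise=10, n_wells=96, signal_r=0.95, seed=11)
    rfs = select_robust_features(rep_a, rep_b, min_similarity=80)
    assert rfs.feature_names == signal
    # brute-force per-feature Pearson oracle
    feats = signal + [f"noise_{i + 1:02d}" for i in range(10)]
    a = rep_a.set_index("well").sort_index()
    b = rep_b.set_index("well").sort_index()
    for f in feats:
        r = stats.pearsonr(a[f], b[f]).statistic
        assert rfs.source_similarity[f] == pytest.approx(
            max(0.0, r) * 100, abs=1e-9)


def test_select_robust_features_reports_mismatched_wells():
    rep_a, rep_b, _ = generate_reference_plate_pair(n_wells=8, seed=2)
    with pytest.raises(ValueError, match="A08"):
        select_robust_features(rep_a, rep_b.iloc[:-1])


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------


def _noise_profiles(rng, n_compounds=20, n_features=100, seed_shift=0):
    g = np.random.default_rng(rng)
    feats = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(g.normal(size=(n_compounds, n_features)), columns=feats,
                      index=pd.Index([f"c{i}" for i in range(n_compounds)],
                                     name="compound_id"))
    df["induction"] = [induction(row, cutoff=3.0) for row in df[feats].to_numpy()]
    return df


def test_concordance_of_identical_runs():
    run = _noise_profiles(1)
    per, summary = replicate_concordance(run, run.copy())
    assert summary["median_biosimilarity"] == pytest.approx(100.0)
    assert summary["fraction_biosim_ge_threshold"] == 1.0
    assert summary["induction_pearson"] == pytest.approx(1.0)


def test_concordance_of_independent_noise_runs():
    _, summary = replicate_concordance(_noise_profiles(2), _noise_profiles(3))
    assert summary["median_biosimilarity"] < 10.0


def test_concordance_requires_shared_compounds():
    a = _noise_profiles(4)
    b = _noise_profiles(5)
    b.index = pd.Index([f"other{i}" for i in range(len(b))], name="compound_id")
    with pytest.raises(ValueError, match="share no compounds"):
        replicate_concordance(a, b)


def test_precipitation_halves_confirmed_fraction():
    templates = make_cluster_templates(13, 579, 0.15, seed=6)
    spec = GeneratorSpec(seed=15, cluster_templates=templates,
                         precipitation_rate=0.5)
    assignments = {f"a{i}": list(templates)[i % 13] for i in range(200)}
    run1, run2, truth = generate_replicate_pair(spec, assignments=assignments)
    _, summary = replicate_concordance(zscore_wells(run1), zscore_wells(run2))
    # strong actives confirm unless precipitated, so the confirmed fraction
    # tracks 1 - p within binomial error (3 sigma at n = 200)
    assert summary["fraction_confirmed_active"] == pytest.approx(
        0.5, abs=3 * np.sqrt(0.25 / 200))
    # and exactly matches the generator's drawn precipitation flags
    assert summary["fraction_confirmed_active"] == pytest.approx(
        1.0 - truth["precipitated"].mean(), abs=0.02)


# ---------------------------------------------------------------------------
# activity recovery on generator defaults
# ---------------------------------------------------------------------------


def test_activity_call_recovers_labels_on_synthetic_screen():
    """With true induction >= 2x the 5% threshold and default noise, activity
    calls recover the planted active/inactive labels at >= 95% accuracy."""
    templates = make_cluster_templates(4, 579, 0.15, seed=8)
    spec = GeneratorSpec(seed=21, cluster_templates=templates, effect_size=5.0)
    assignments = {f"act{i}": list(templates)[i % 4] for i in range(84)}
    assignments.update({f"inact{i}": None for i in range(84)})
    run, truth = generate_run(spec, assignments=assignments, site_level=False)
    prof = zscore_wells(run)
    truth = truth.set_index("compound_id")
    active_truth = truth["cluster"].notna()
    ind = prof["induction"]
    ind.index = prof.index.get_level_values(0)
    assert ind[active_truth[ind.index]].min() >= 10.0  # 2x threshold holds
    calls = activity_call(ind.to_numpy())
    accuracy = np.mean(calls == active_truth[ind.index].to_numpy())
    assert accuracy >= 0.95
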