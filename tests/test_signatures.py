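"""Expression generator and signature-scoring arm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mammilieu.signatures import (
    collapse_probes,
    compare_age_groups,
    holm_adjust,
    read_gmt,
    scale_genes,
    score_signatures,
    write_gmt,
)
from mammilieu.simulate.expression import ExpressionSpec, generate_expression


def _sigs(n=20, start=0, name="sig"):
    return {name: [f"G{i:04d}" for i in range(start, start + n)]}


def test_default_group_sizes():
    _, _, ages = generate_expression(ExpressionSpec(n_genes=50, seed=0), _sigs(5))
    assert (ages <= 35).sum() == 51
    assert (ages >= 50).sum() == 23


def test_unknown_signature_gene_listed_in_error():
    sigs = {"bad": ["G0001", "NOPE1", "NOPE2"]}
    with pytest.raises(ValueError) as err:
        generate_expression(ExpressionSpec(n_genes=10, seed=0), sigs)
    assert "NOPE1" in str(err.value) and "NOPE2" in str(err.value)


def test_effect_applied_to_member_genes_only():
    sigs = {"sig": [f"G{i:04d}" for i in range(10)]}
    spec = ExpressionSpec(n_genes=60, signature_effects={"sig": 2.0}, noise_sd=0.5, seed=1)
    mat, ann, ages = generate_expression(spec, sigs)
    gene = collapse_probes(mat, ann)
    old = ages >= 50
    diff = gene.loc[:, old.to_numpy()].mean(axis=1) - gene.loc[:, (~old).to_numpy()].mean(axis=1)
    member = diff.index.isin(sigs["sig"])
    assert diff[member].mean() > 0.7
    assert abs(diff[~member].mean()) < 0.15


def test_collapse_keeps_probe_with_max_mean():
    mat = pd.DataFrame(
        {"s1": [5.0, 7.0, 3.0], "s2": [5.0, 7.0, 3.0]},
        index=["g1_a", "g1_b", "g2_a"],
    )
    ann = pd.DataFrame({"gene": ["g1", "g1", "g2"]}, index=mat.index)
    out = collapse_probes(mat, ann)
    assert out.loc["g1", "s1"] == 7.0
    assert out.loc["g2", "s1"] == 3.0


def test_collapse_single_probe_is_identity_and_empty_errors():
    mat = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["p1"])
    ann = pd.DataFrame({"gene": ["g1"]}, index=["p1"])
    assert collapse_probes(mat, ann).loc["g1"].tolist() == [1.0, 2.0]
    with pytest.raises(ValueError, match="empty"):
        collapse_probes(mat.iloc[:0], ann)


def test_collapse_matches_brute_force_argmax():
    rng = np.random.default_rng(2)
    probes = [f"g{i}_p{j}" for i in range(15) for j in range(rng.integers(1, 4))]
    genes = [p.split("_")[0] for p in probes]
    mat = pd.DataFrame(rng.normal(size=(len(probes), 9)), index=probes)
    ann = pd.DataFrame({"gene": genes}, index=probes)
    out = collapse_probes(mat, ann)
    for g in set(genes):
        rows = sorted(p for p in probes if p.startswith(g + "_"))
        best = max(rows, key=lambda p: (mat.loc[p].mean(), ))
        # ties broken by probe order: emulate with stable max over sorted rows
        best = rows[int(np.argmax([mat.loc[p].mean() for p in rows]))]
        assert out.loc[g].tolist() == mat.loc[best].tolist()


def test_scale_genes_properties():
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.normal(5, 2, size=(10, 8)))
    scaled = scale_genes(mat)
    assert np.abs(scaled.mean(axis=1)).max() < 1e-12
    assert np.abs(scaled.std(axis=1, ddof=1) - 1).max() < 1e-12
    # constant shift leaves scaled rows identical
    assert np.allclose(scale_genes(mat + 100.0), scaled)
    # zero-variance gene dropped
    mat.iloc[0] = 4.2
    assert len(scale_genes(mat)) == 9


def test_score_is_mean_of_member_rows():
    rng = np.random.default_rng(4)
    scaled = pd.DataFrame(
        rng.normal(size=(6, 5)), index=[f"g{i}" for i in range(6)]
    )
    sigs = {"one": ["g2"], "many": ["g0", "g3", "g5"], "absent": ["zz"]}
    scores = score_signatures(scaled, sigs)
    assert np.allclose(scores.loc["one"], scaled.loc["g2"])
    assert np.allclose(scores.loc["many"], scaled.loc[["g0", "g3", "g5"]].mean(axis=0))
    assert scores.loc["absent"].isna().all()


def test_holm_stepdown_worked_example():
    assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])


def test_holm_matches_statsmodels_and_is_monotone():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=25)
    ours = holm_adjust(p)
    ref = multipletests(p, method="holm")[1]
    assert np.allclose(ours, ref)
    order = np.argsort(p)
    assert np.all(np.diff(ours[order]) >= -1e-15)
    # m = 1 reduces to Bonferroni (identity)
    assert holm_adjust([0.031])[0] == pytest.approx(0.031)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_holm_properties_hold_for_arbitrary_p(p):
    """Holm adjustment dominates the raw p, is capped at 1, and agrees
    with the reference implementation."""
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    assert np.allclose(adj, multipletests(p, method="holm")[1])


def test_planted_shift_detected_with_direction():
    """+1 sd shift on one 20-gene signature at the default group sizes is
    detected (adj. p < 0.05, direction up) in >= 18 of 20 seeds; pilot runs
    put the detection rate at 20/20."""
    sigs = {**_sigs(20, 0, "hit"), **_sigs(20, 30, "null")}
    hits = 0
    for seed in range(20):
        spec = ExpressionSpec(n_genes=100, signature_effects={"hit": 1.0}, seed=seed)
        mat, ann, ages = generate_expression(spec, sigs)
        res = {
            r.signature: r
            for r in compare_age_groups(
                score_signatures(scale_genes(collapse_probes(mat, ann)), sigs), ages
            )
        }
        if (
            res["hit"].adjusted_p < 0.05
            and res["hit"].direction == "up"
            and res["hit"].p_value < 0.001
        ):
            hits += 1
    assert hits >= 18


def test_mid_age_samples_are_excluded_from_testing():
    rng = np.random.default_rng(6)
    scores = pd.DataFrame(
        rng.normal(size=(1, 30)), index=["s"], columns=[f"c{i}" for i in range(30)]
    )
    ages = pd.Series(
        [30.0] * 10 + [42.0] * 10 + [60.0] * 10, index=scores.columns
    )
    res = compare_age_groups(scores, ages)[0]
    from scipy.stats import ranksums

    manual = ranksums(scores.iloc[0, 20:], scores.iloc[0, :10])
    assert res.p_value == pytest.approx(manual.pvalue)


def test_group_size_validation():
    scores = pd.DataFrame(np.ones((1, 4)), columns=list("abcd"))
    ages = pd.Series([30, 30, 30, 42.0], index=list("abcd"))
    with pytest.raises(ValueError, match="at least 2"):
        compare_age_groups(scores, ages)


def test_gmt_round_trip(tmp_path):
    sigs = {"a": ["g1", "g2"], "b": ["g3"]}
    path = tmp_path / "sigs.gmt"
    write_gmt(sigs, path)
    assert read_gmt(path) == sigs
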