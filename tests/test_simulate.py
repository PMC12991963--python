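"""Tests of the synthetic paired-exclosure survey generator."""

import numpy as np
import pandas as pd
import pytest

import exclosure as ex
from exclosure.errors import ConfigError
from exclosure.simulate import DEFAULT_MONTHS


def small_config(**kw):
    base = dict(sites=("S1",), n_pairs=5, months=tuple(range(0, 25, 6)),
                pool_size=40, seed=1)
    base.update(kw)
    return ex.SimConfig(**base)


def test_default_grid_has_18_occasions():
    assert len(DEFAULT_MONTHS) == 18
    assert list(DEFAULT_MONTHS) == sorted(DEFAULT_MONTHS)


def test_plot_occasion_bookkeeping():
    """No missing occasions: every plot appears at every survey month."""
    cfg = small_config(n_pairs=15, months=tuple(range(0, 103, 6)))  # 18 occasions
    sv = ex.simulate_survey(cfg)
    groups = sv.groupby(["plot", "month"]).ngroups
    assert groups == 15 * 2 * 18


def test_seeded_determinism():
    cfg = small_config(seed=99)
    a = ex.simulate_survey(cfg)
    b = ex.simulate_survey(cfg)
    assert a.equals(b)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_seed_changes_output():
    a = ex.simulate_survey(small_config(seed=1))
    b = ex.simulate_survey(small_config(seed=2))
    assert not a.equals(b)


def test_output_satisfies_survey_invariants():
    sv = ex.simulate_survey(small_config())
    validated = ex.validate_survey(sv)  # raises on any violation
    assert (validated["count"] > 0).all()  # zeros are implicit in long format
    roster = validated.drop_duplicates(["pair", "plot", "treatment"])
    per_pair = roster.groupby("pair")["treatment"].apply(sorted)
    assert all(t == ["control", "exclusion"] for t in per_pair)


def test_missing_months_are_dropped_per_site():
    cfg = ex.SimConfig(sites=("A", "B"), pool_size=30, n_pairs=3,
                       months=(0, 6, 12, 18),
                       missing_months_by_site={"B": (6, 18)}, seed=3)
    sv = ex.simulate_survey(cfg)
    assert sorted(sv.loc[sv.site == "A", "month"].unique()) == [0, 6, 12, 18]
    assert sorted(sv.loc[sv.site == "B", "month"].unique()) == [0, 12]


@pytest.mark.parametrize("field,value", [
    ("n_pairs", 0),
    ("months", (0, 6, 6)),
    ("months", (6, 0)),
    ("convergence_rate", 1.5),
    ("dispersion", 0.0),
    ("n_hyperdominant", 999),
    ("affinity_pair_corr", -0.1),
    ("sad_sdlog", 0.0),
])
def test_invalid_config_names_offending_field(field, value):
    cfg = small_config(**{field: value})
    with pytest.raises(ConfigError, match=field):
        cfg.validate()


def test_presets():
    null = ex.scenario_preset("null")
    assert (null.delta_richness, null.hyper_release_rate, null.convergence_rate) == (0, 0, 0)
    hom = ex.scenario_preset("homogenization")
    assert hom.delta_richness > 0 and hom.hyper_release_rate > 0 and hom.convergence_rate > 0
    rel = ex.scenario_preset("release_only")
    assert rel.hyper_release_rate > 0 and rel.convergence_rate == 0


def test_unknown_preset_lists_available():
    with pytest.raises(ConfigError, match="homogenization"):
        ex.scenario_preset("nonsense")


def test_null_preset_treatments_are_exchangeable():
    """Mean control-vs-exclusion difference of per-plot totals and richness
    is zero within Monte-Carlo error under the null scenario."""
    diffs_total, diffs_rich = [], []
    for i in range(500):
        cfg = ex.SimConfig(sites=("S1",), n_pairs=3, months=(0, 12),
                           pool_size=20, seed=50_000 + i)
        sv = ex.simulate_survey(cfg)
        per_plot = sv.groupby(["treatment", "plot", "month"]).agg(
            total=("count", "sum"), richness=("species", "nunique"))
        by_treat = per_plot.groupby("treatment").mean()
        diffs_total.append(by_treat.loc["exclusion", "total"] - by_treat.loc["control", "total"])
        diffs_rich.append(by_treat.loc["exclusion", "richness"] - by_treat.loc["control", "richness"])
    for diffs in (diffs_total, diffs_rich):
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 4 * sem


def test_homogenization_lowers_final_month_beta():
    """Exclusion plots end up less dissimilar than controls in nearly all
    replicates of the homogenization scenario (full 13-year span)."""
    months = tuple(range(0, 91, 18)) + (156,)
    lower = 0
    n_rep = 100
    for i in range(n_rep):
        cfg = ex.scenario_preset("homogenization", sites=("S1",), n_pairs=8,
                                 months=months, pool_size=60, seed=70_000 + i)
        sv = ex.simulate_survey(cfg)
        b = ex.beta_summaries(sv, jackknife=False)
        final = b[b["month"] == 156].set_index("treatment")["total"]
        lower += final["exclusion"] < final["control"]
    assert lower >= 0.95 * n_rep


def test_lmm_dataset_structure():
    df = ex.simulate_lmm_dataset((1.0, 0.0, 0.0, 0.0), n_pairs=4,
                                 months=(0, 6), seed=0)
    assert len(df) == 4 * 2 * 2
    assert set(df["treatment"]) == {"control", "exclusion"}
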