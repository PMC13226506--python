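import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr import CausalScenario, GeneLocus, simulate_exposure_stats
from targetmr.instruments import (
    DRUG_TARGET_CRITERIA,
    IMMUNE_TRAIT_CRITERIA,
    apply_blocklist,
    clump,
    exclude_outcome_associated,
    filter_cis_window,
    filter_maf,
    filter_significance,
    per_snp_f,
    select_instruments,
)
from targetmr.io import SummaryStatSet, records_from_arrays


def make_set(n=10, pos=None, p=None, eaf=None, ea=None, oa=None, chrom="1"):
    for arg in (pos, p, eaf, ea, oa):
        if arg is not None:
            n = len(arg)
            break
    pos = np.arange(n) * 1000 + 1 if pos is None else np.asarray(pos)
    return SummaryStatSet(
        trait_id="t",
        records=records_from_arrays(
            [f"rs{i}" for i in range(n)], chrom, pos,
            ea if ea is not None else ["A"] * n,
            oa if oa is not None else ["G"] * n,
            eaf if eaf is not None else np.full(n, 0.3),
            np.full(n, 0.1), np.full(n, 0.01),
            p if p is not None else np.full(n, 1e-8),
            5000,
        ),
    )


def test_presets_match_selection_criteria():
    assert DRUG_TARGET_CRITERIA.p_threshold == 1e-5
    assert DRUG_TARGET_CRITERIA.r2_threshold == 0.30
    assert DRUG_TARGET_CRITERIA.clump_window_kb == 100
    assert DRUG_TARGET_CRITERIA.maf_min == 0.05
    assert DRUG_TARGET_CRITERIA.cis_window_kb == 300
    assert IMMUNE_TRAIT_CRITERIA.r2_threshold == 0.001
    assert IMMUNE_TRAIT_CRITERIA.clump_window_kb == 10_000
    assert IMMUNE_TRAIT_CRITERIA.cis_window_kb is None


def test_cis_window_boundaries_inclusive():
    locus = GeneLocus("g", "1", 1_000_000, 1_050_000)
    s = make_set(pos=[700_000, 699_999, 1_350_000, 1_350_001])
    kept = filter_cis_window(s, locus, 300.0).records["SNP"].tolist()
    assert kept == ["rs0", "rs2"]  # exactly at start-300kb / end+300kb retained


def test_cis_window_other_chromosome_removed():
    locus = GeneLocus("g", "2", 1, 10)
    s = make_set(pos=[5])  # chromosome "1"
    assert len(filter_cis_window(s, locus, 300.0)) == 0


def test_cis_window_matches_bruteforce_oracle(rng):
    locus = GeneLocus("g", "1", 2_000_000, 2_100_000)
    pos = rng.integers(1, 5_000_000, 1000)
    s = make_set(pos=pos)
    got = set(filter_cis_window(s, locus, 300.0).records["SNP"])
    expected = {
        f"rs{i}" for i, p in enumerate(pos)
        if locus.start - 300_000 <= p <= locus.end + 300_000
    }
    assert got == expected


def test_significance_strictly_below_threshold(rng):
    s = make_set(p=[1e-5, 9.999e-6, 0.5])
    kept = filter_significance(s, 1e-5).records["SNP"].tolist()
    assert kept == ["rs1"]  # p exactly 1e-5 removed, strict inequality
    # brute-force count agreement on random p-values
    p = rng.uniform(0, 1, 500)
    s2 = make_set(pos=np.arange(500), p=p)
    assert len(filter_significance(s2, 0.3)) == int(np.sum(p < 0.3))
    assert len(filter_significance(s2, 0.0)) == 0  # empty survivor set allowed


def _brute_force_clump(df, r2_lookup, r2_threshold, window_bp):
    """Literal restatement of the greedy rule, for the oracle."""
    remaining = df.sort_values(["P", "SNP"]).to_dict("records")
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best["SNP"])
        remaining = [
            r for r in remaining
            if not (
                r["CHR"] == best["CHR"]
                and abs(r["POS"] - best["POS"]) <= window_bp
                and r2_lookup(best["SNP"], r["SNP"]) >= r2_threshold
            )
        ]
    return kept


def test_clump_trivial_cases():
    s = make_set(n=5, p=[0.5, 0.1, 0.3, 0.2, 0.4])
    # all independent -> everything retained
    assert len(clump(s, lambda a, b: 0.0, 0.3, 100.0)) == 5
    # perfectly correlated pair within window -> smaller p survives
    s2 = make_set(pos=[1000, 2000], p=[0.2, 0.1])
    kept = clump(s2, lambda a, b: 1.0, 0.3, 100.0).records["SNP"].tolist()
    assert kept == ["rs1"]


def test_clump_matches_bruteforce_on_small_sets(rng):
    for trial in range(20):
        n = int(rng.integers(3, 13))
        pos = rng.integers(1, 500_000, n)
        p = rng.uniform(0, 1, n)
        s = make_set(pos=pos, p=p)
        r2 = rng.uniform(0, 1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        idx = {f"rs{i}": i for i in range(n)}
        lookup = lambda a, b: r2[idx[a], idx[b]]
        got = clump(s, lookup, 0.3, 100.0).records["SNP"].tolist()
        expected = _brute_force_clump(s.records, lookup, 0.3, 100_000)
        assert got == expected


def test_clumped_output_pairwise_independent(rng):
    """Post-condition: all retained pairs within the window have r2 < cut."""
    n = 30
    s = make_set(pos=rng.integers(1, 200_000, n), p=rng.uniform(0, 1, n))
    r2 = rng.uniform(0, 1, (n, n))
    r2 = (r2 + r2.T) / 2
    idx = {f"rs{i}": i for i in range(n)}
    lookup = lambda a, b: r2[idx[a], idx[b]]
    out = clump(s, lookup, 0.3, 100.0).records
    for a, b in itertools.combinations(out.itertuples(index=False), 2):
        if abs(a.POS - b.POS) <= 100_000:
            assert lookup(a.SNP, b.SNP) < 0.3


def test_maf_filter_rules():
    s = make_set(
        eaf=[0.96, 0.45, 0.45, np.nan],
        ea=["A", "A", "A", "A"],
        oa=["G", "T", "C", "G"],
    )
    kept = filter_maf(s, maf_min=0.05, maf_ambiguous_max=0.42).records["SNP"].tolist()
    # rs0: MAF 0.04 <= 0.05 -> out; rs1: palindromic MAF 0.45 > 0.42 -> out;
    # rs2: non-palindromic MAF 0.45 -> kept; rs3: missing EAF fails closed
    assert kept == ["rs2"]


def test_per_snp_f():
    assert per_snp_f(0.1, 0.1) == pytest.approx(1.0)
    assert per_snp_f(0.1, 0.02) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        per_snp_f(0.1, 0.0)


@given(st.floats(-1, 1, allow_nan=False), st.floats(0.001, 1))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_f_exceeds_10_iff_abs_z_exceeds_sqrt10(beta, se):
    assert (per_snp_f(beta, se) > 10) == (abs(beta / se) > np.sqrt(10))


def test_exclude_outcome_associated():
    instruments = make_set(n=3)
    outcome = make_set(n=2, p=[0.5, 1e-6])  # rs2 missing from outcome
    kept, unmatched = exclude_outcome_associated(instruments, outcome, 1e-5)
    assert kept.records["SNP"].tolist() == ["rs0"]
    assert unmatched == ["rs2"]


def test_blocklist_semantics():
    s = make_set(n=4)
    same = apply_blocklist(s, [])
    pd.testing.assert_frame_equal(same.records, s.records)
    log = []
    out = apply_blocklist(s, ["rs1", "rs3", "rs_absent"], log=log)
    assert out.records["SNP"].tolist() == ["rs0", "rs2"]
    assert len(log) == 2
    with pytest.warns(UserWarning):
        empty = apply_blocklist(s, [f"rs{i}" for i in range(4)])
    assert len(empty) == 0


def test_filters_are_pure_subsets(default_scenario):
    """Every filter returns a row subset with no field mutation."""
    exp, _ = simulate_exposure_stats(default_scenario)
    filtered = filter_significance(exp, 1e-5)
    orig = exp.records.set_index("SNP")
    sub = filtered.records.set_index("SNP")
    assert set(sub.index) <= set(orig.index)
    pd.testing.assert_frame_equal(sub, orig.loc[sub.index])


def test_select_instruments_cascade_counts(default_scenario):
    exp, truth = simulate_exposure_stats(default_scenario)
    locus = GeneLocus("target", "1", 5_000_000, 5_120_000)
    instruments, counts = select_instruments(
        exp, DRUG_TARGET_CRITERIA, locus=locus
    )
    assert counts["input"] == 13
    stages = list(counts)
    assert stages.index("cis_window") < stages.index("significance") < stages.index("maf")
    # cascade counts never increase
    ordered = [counts[k] for k in ("input", "cis_window", "significance", "maf",
                                   "blocklist", "strength")]
    assert all(a >= b for a, b in zip(ordered, ordered[1:]))
    assert len(instruments) == counts["strength"]
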