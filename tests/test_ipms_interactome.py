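"""IP-MS interactor filtering: rules, intersection, abundance, RNase class."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1quant.ipms_interactome import (
    InteractomeConfig,
    background_filter,
    build_interactome,
    intersect_replicates,
    normalized_abundance,
    rnase_dependence,
    stringency_filter,
)
from l1quant.synthetic_data import simulate_psm_experiment


class TestBackgroundFilter:
    @pytest.mark.parametrize(
        "ip, neg, keep, rule",
        [
            (5, 5, False, "neg>=ip"),          # equal counts: background wins
            (12, 10, False, "high-background, diff<3"),
            (13, 10, True, None),              # margin of exactly 3 is kept
            (3, 0, True, None),
            (0, 0, False, "neg>=ip"),
        ],
    )
    def test_rules(self, ip, neg, keep, rule):
        got_keep, got_rule = background_filter(ip, neg)
        assert (got_keep, got_rule) == (keep, rule)

    @given(ip=st.integers(0, 60), neg=st.integers(0, 60), bump=st.integers(1, 20))
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_both_arguments(self, ip, neg, bump):
        """More IP signal never flips keep→exclude; more background never
        flips exclude→keep."""
        keep, _ = background_filter(ip, neg)
        if keep:
            assert background_filter(ip + bump, neg)[0]
        else:
            assert not background_filter(ip, neg + bump)[0]


class TestStringencyFilter:
    @pytest.mark.parametrize(
        "low, high, keep",
        [
            (9, 3, True),    # ratio exactly 3: strict inequality keeps
            (10, 3, False),
            (5, 0, False),   # completely lost at high salt
            (0, 0, True),    # no evidence of loss
            (0, 4, True),
        ],
    )
    def test_rules(self, low, high, keep):
        assert stringency_filter(low, high) is keep


class TestIntersectReplicates:
    def test_set_algebra(self):
        got = intersect_replicates(
            {"E1": [{"A", "B"}, {"A", "B", "C"}], "E2": [{"A", "C"}, {"A"}]}
        )
        assert got == {"A"}

    def test_single_replicate_identity(self):
        assert intersect_replicates({"E1": [{"X", "Y"}]}) == {"X", "Y"}

    def test_disjoint_experiments_empty(self):
        assert intersect_replicates({"E1": [{"A"}], "E2": [{"B"}]}) == set()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            intersect_replicates({})


class TestNormalizedAbundance:
    def test_bait_is_one(self):
        assert normalized_abundance(100, 40, 100, 40) == 1.0

    def test_worked_ratio(self):
        assert normalized_abundance(10, 50, 100, 40) == pytest.approx(0.08)

    def test_zero_psm_is_zero(self):
        assert normalized_abundance(0, 50, 100, 40) == 0.0

    def test_unrecovered_bait_errors(self):
        with pytest.raises(ValueError, match="bait"):
            normalized_abundance(10, 50, 0, 40)


class TestRnaseDependence:
    @pytest.mark.parametrize(
        "minus, plus, expected",
        [
            (0.5, 0.0, "lost"),
            (0.9, 0.6, "resistant"),
            (0.9, 0.2, "reduced"),  # 4.5-fold drop > default 3
            (0.0, 0.0, "resistant"),
        ],
    )
    def test_classes(self, minus, plus, expected):
        assert rnase_dependence(minus, plus) == expected


def _random_psm_table(rng) -> pd.DataFrame:
    """Small random table: 2 experiments x 2 replicates, optional salt_high."""
    proteins = [f"p{i}" for i in range(rng.integers(3, 10))]
    mw = {p: float(rng.uniform(20, 200)) for p in proteins}
    mw["ORF1p"] = 40.0
    rows = []
    for exp in ("E1", "E2"):
        with_salt = rng.random() < 0.7
        neg_role = "BO" if rng.random() < 0.5 else "IGG"
        for rep in (1, 2):
            for p in proteins:
                rows.append([p, mw[p], exp, "IP", "salt_low", "rnase_minus", rep,
                             int(rng.integers(0, 15))])
                rows.append([p, mw[p], exp, neg_role, "salt_low", "rnase_minus", rep,
                             int(rng.integers(0, 12))])
                if with_salt:
                    rows.append([p, mw[p], exp, "IP", "salt_high", "rnase_minus", rep,
                                 int(rng.integers(0, 15))])
            rows.append(["ORF1p", 40.0, exp, "IP", "salt_low", "rnase_minus", rep, 50])
            rows.append(["ORF1p", 40.0, exp, neg_role, "salt_low", "rnase_minus", rep, 1])
            if with_salt:
                rows.append(["ORF1p", 40.0, exp, "IP", "salt_high", "rnase_minus", rep, 45])
    return pd.DataFrame(
        rows,
        columns=["protein_id", "mw_kda", "experiment", "role", "salt", "rnase",
                 "replicate", "psm"],
    )


def _oracle_interactors(table: pd.DataFrame, config: InteractomeConfig) -> set:
    """Brute-force re-application of the three filter rules, plain loops."""
    survivors_by_exp = {}
    for exp in sorted(table["experiment"].unique()):
        sub = table[table["experiment"] == exp]
        replicate_sets = []
        for rep in sorted(sub["replicate"].unique()):
            surv = set()
            for p in table["protein_id"].unique():
                def psm(role, salt="salt_low"):
                    m = sub[(sub.protein_id == p) & (sub.role == role)
                            & (sub.salt == salt) & (sub.rnase == "rnase_minus")
                            & (sub.replicate == rep)]
                    return int(m.psm.sum()) if len(m) else 0
                negs = [psm(r) for r in ("BO", "IGG") if (sub.role == r).any()]
                neg = max(negs) if negs else 0
                ip = psm("IP")
                if neg >= ip:
                    continue
                if neg >= config.neg_high_psm and ip - neg < config.neg_min_diff:
                    continue
                surv.add(p)
            replicate_sets.append(surv)
        common = set.intersection(*replicate_sets)
        if (sub["salt"] == "salt_high").any():
            kept = set()
            for p in common:
                m = sub[(sub.protein_id == p) & (sub.role == "IP")
                        & (sub.rnase == "rnase_minus")]
                low = int(m[m.salt == "salt_low"].psm.sum())
                high = int(m[m.salt == "salt_high"].psm.sum())
                if high == 0:
                    if low == 0:
                        kept.add(p)
                elif low / high <= config.stringency_fold:
                    kept.add(p)
            common = kept
        survivors_by_exp[exp] = common
    return set.intersection(*survivors_by_exp.values())


class TestBuildInteractome:
    def test_matches_brute_force_oracle_on_random_tables(self):
        config = InteractomeConfig()
        rng = np.random.default_rng(42)
        for _ in range(60):
            table = _random_psm_table(rng)
            res = build_interactome(table, config)
            called = set(res.loc[res["is_interactor"], "protein_id"])
            assert called == _oracle_interactors(table, config)

    def test_recovers_simulated_interactors(self):
        table, truth = simulate_psm_experiment(seed=1)
        res = build_interactome(table)
        called = set(res.loc[res["is_interactor"], "protein_id"]) - {"ORF1p"}
        positives = set(
            truth.loc[
                truth["entity_class"].isin(["true_interactor", "rnase_sensitive"]),
                "entity_id",
            ]
        )
        tp = len(called & positives)
        assert tp / len(called) >= 0.9  # precision
        assert tp / len(positives) >= 0.9  # recall

    def test_salt_sensitive_proteins_rarely_survive(self):
        """The stringency filter removes the salt-labile subset in at least
        95% of simulations."""
        fails = 0
        for seed in range(10):
            table, truth = simulate_psm_experiment(seed=seed)
            res = build_interactome(table)
            called = set(res.loc[res["is_interactor"], "protein_id"])
            salt = set(truth.loc[truth["entity_class"] == "salt_sensitive", "entity_id"])
            fails += bool(called & salt)
        assert fails == 0

    def test_everything_matching_background_leaves_only_bait(self):
        rows = []
        for rep in (1, 2):
            for p in ("a", "b", "c"):
                for role in ("IP", "BO"):
                    rows.append([p, 50.0, "E1", role, "salt_low", "rnase_minus", rep, 7])
            rows.append(["ORF1p", 40.0, "E1", "IP", "salt_low", "rnase_minus", rep, 30])
            rows.append(["ORF1p", 40.0, "E1", "BO", "salt_low", "rnase_minus", rep, 0])
        table = pd.DataFrame(rows, columns=["protein_id", "mw_kda", "experiment",
                                            "role", "salt", "rnase", "replicate", "psm"])
        res = build_interactome(table)
        assert set(res.loc[res["is_interactor"], "protein_id"]) == {"ORF1p"}

    def test_bait_survives_with_unit_abundance_and_ordering(self):
        table, _ = simulate_psm_experiment(seed=5)
        res = build_interactome(table)
        bait = res[res["protein_id"] == "ORF1p"]
        assert bool(bait["is_interactor"].item())
        assert bait["normalized_abundance"].item() == 1.0
        ab = res["normalized_abundance"].to_numpy()
        assert (np.diff(ab) <= 1e-12).all()  # sorted descending
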