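"""Poisson-corrected divergence statistics against an independent oracle."""

import math
import random
from itertools import combinations

import numpy as np
import pytest

from npevo.alignment_io import MSA
from npevo.conservation_stats import (
    AllPairsUndefinedError,
    UndefinedDistanceError,
    average_evolutionary_divergence,
    median_of,
    pairwise_p_distance,
    poisson_distance,
    summarize_family,
)

AMBIG = "-X?"


def brute_force_aed(rows):
    """Independent oracle: explicit double loop, no shared code with the package."""
    dists = []
    for a, b in combinations(rows, 2):
        diffs = 0
        valid = 0
        for x, y in zip(a, b):
            if x in AMBIG or y in AMBIG:
                continue
            valid += 1
            if x != y:
                diffs += 1
        if valid == 0:
            continue
        p = diffs / valid
        if p >= 1.0:
            continue
        dists.append(-math.log(1.0 - p))
    if not dists:
        raise ValueError("all pairs undefined")
    return sum(dists) / len(dists)


class TestPairwise:
    @pytest.mark.parametrize(
        "a,b,p,n_valid",
        [
            ("RYLPT", "RYLPT", 0.0, 5),
            ("RYLPT", "RYLPV", 0.2, 5),
            ("RY?PT", "RYLPV", 0.25, 4),  # '?' site deleted pairwise
            ("R-LPT", "RYLPT", 0.0, 4),   # gap treated like an ambiguity
        ],
    )
    def test_pairwise_deletion(self, a, b, p, n_valid):
        d = pairwise_p_distance(a, b)
        assert d.n_valid == n_valid
        assert d.p == pytest.approx(p)

    def test_no_comparable_sites_is_undefined_not_error(self):
        d = pairwise_p_distance("??", "AA")
        assert not d.defined and d.n_valid == 0


class TestPoisson:
    def test_closed_form(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.2) == pytest.approx(0.22314, abs=1e-5)

    def test_singularity_raises(self):
        with pytest.raises(UndefinedDistanceError):
            poisson_distance(1.0)

    def test_distance_dominates_p(self):
        for p in np.linspace(0, 0.99, 25):
            assert poisson_distance(float(p)) >= p


class TestAED:
    def test_identical_rows_have_zero_divergence(self):
        res = average_evolutionary_divergence(
            MSA(list("abc"), ["RYLPT"] * 3), n_boot=50, seed=0
        )
        assert res.aed == 0.0 and res.se == 0.0

    def test_three_row_example(self):
        res = average_evolutionary_divergence(
            MSA(list("abc"), ["RYLPT", "RYLPV", "RYLAT"]), n_boot=10, seed=0
        )
        expected = (0.22314355 + 0.22314355 + 0.51082562) / 3
        assert res.aed == pytest.approx(expected, abs=1e-6)

    def test_seeded_bootstrap_is_deterministic(self):
        msa = MSA(list("abc"), ["RYLPT", "RYLPV", "RYLAT"])
        r1 = average_evolutionary_divergence(msa, n_boot=100, seed=5)
        r2 = average_evolutionary_divergence(msa, n_boot=100, seed=5)
        assert r1 == r2

    def test_matches_brute_force_oracle_on_random_msas(self):
        rng = random.Random(1234)
        alphabet = "ACDEFGHIKLMNPQRSTVWY-X?"
        for _ in range(200):
            n = rng.randint(2, 8)
            m = rng.randint(2, 30)
            rows = [
                "".join(rng.choice(alphabet) for _ in range(m)) for _ in range(n)
            ]
            try:
                expected = brute_force_aed(rows)
            except ValueError:
                with pytest.raises(AllPairsUndefinedError):
                    average_evolutionary_divergence(
                        MSA([f"s{i}" for i in range(n)], rows), n_boot=0, seed=0
                    )
                continue
            res = average_evolutionary_divergence(
                MSA([f"s{i}" for i in range(n)], rows), n_boot=0, seed=0
            )
            assert res.aed == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_row_permutation(self):
        rows = ["RYLPTAC", "RYLPVAC", "KYLATAD"]
        a = average_evolutionary_divergence(MSA(list("abc"), rows), n_boot=0, seed=0)
        b = average_evolutionary_divergence(
            MSA(list("cba"), rows[::-1]), n_boot=0, seed=0
        )
        assert a.aed == pytest.approx(b.aed, abs=1e-15)

    def test_all_gap_column_does_not_change_aed(self):
        rows = ["RYLPT", "RYLPV", "RYLAT"]
        base = average_evolutionary_divergence(MSA(list("abc"), rows), n_boot=0, seed=0)
        padded = average_evolutionary_divergence(
            MSA(list("abc"), [r + "-" for r in rows]), n_boot=0, seed=0
        )
        assert padded.aed == pytest.approx(base.aed, abs=1e-15)

    def test_bootstrap_se_shrinks_with_column_count(self):
        rng = np.random.default_rng(7)
        ses = []
        for m in (20, 200, 2000):
            rows = [
                "".join(rng.choice(list("ACDEFG"), size=m)) for _ in range(4)
            ]
            ses.append(
                average_evolutionary_divergence(
                    MSA(list("abcd"), rows), n_boot=200, seed=3
                ).se
            )
        assert ses[0] > ses[1] > ses[2]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            average_evolutionary_divergence(MSA(["a"], ["RYLPT"]), n_boot=0, seed=0)


class TestSummary:
    def test_median_of_groups(self):
        msas = {
            "g1": MSA(list("ab"), ["AAAA", "AAAA"]),          # aed 0
            "g2": MSA(list("ab"), ["AAAA", "AAAC"]),          # aed -ln(0.75)
            "g3": MSA(list("ab"), ["AAAA", "ACCC"]),          # aed -ln(0.25)
        }
        s = summarize_family(msas, n_boot=10, seed=0)
        assert s.median_aed == pytest.approx(-math.log(0.75))

    def test_even_group_count_averages_central_pair(self):
        assert median_of([0.1, 0.3]) == pytest.approx(0.2)
        assert median_of([0.1, 0.2, 0.4]) == pytest.approx(0.2)

    def test_single_group_median_is_that_group(self):
        msas = {"g1": MSA(list("ab"), ["AAAA", "AAAC"])}
        s = summarize_family(msas, n_boot=10, seed=0)
        assert s.median_aed == pytest.approx(s.per_group["g1"].aed)

    def test_group_failures_do_not_abort_other_groups(self):
        msas = {
            "bad": MSA(["a"], ["AAAA"]),  # single sequence
            "good": MSA(list("ab"), ["AAAA", "AAAC"]),
        }
        s = summarize_family(msas, n_boot=10, seed=0)
        assert s.per_group["bad"] is None
        assert "bad" in s.errors
        assert s.per_group["good"] is not None
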