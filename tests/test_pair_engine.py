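import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iloci.genotype_io import MISSING, relabel_alleles
from iloci.pair_engine import (
    JointGenotypeTable,
    build_joint_table,
    encode_genotypes,
    pair_count,
    rho,
    scan_to_records,
    score_pair,
)

from conftest import make_matrix, random_case_control, rho_oracle


def table_from(p):
    p = np.asarray(p, dtype=float)
    return JointGenotypeTable(p=p, n_used=100)


class TestEncoding:
    def test_codes_map_to_signed_values(self):
        enc = encode_genotypes(np.array([0, 1, 2, MISSING]))
        assert list(enc.values[:3]) == [-1, 0, 1]
        assert list(enc.mask) == [True, True, True, False]


class TestJointTable:
    def test_direct_tally(self):
        t = build_joint_table(
            np.array([0, 0, 2, 2]), np.array([0, 0, 2, 2]), np.ones(4, bool)
        )
        assert t.n_used == 4
        assert t.p[0, 0] == pytest.approx(0.5)
        assert t.p[2, 2] == pytest.approx(0.5)
        assert t.p.sum() == pytest.approx(1.0)

    def test_missing_individual_excluded(self):
        gx = np.array([0, 0, 2, 2])
        gy = np.array([0, 0, 2, MISSING])
        t = build_joint_table(gx, gy, np.ones(4, bool))
        assert t.n_used == 3

    def test_empty_group_flagged(self):
        t = build_joint_table(np.array([0, 1]), np.array([0, 1]), np.zeros(2, bool))
        assert t.empty
        assert math.isnan(rho(t))

    def test_matches_nested_loop_oracle(self, rng):
        gx = rng.integers(0, 3, 50)
        gy = rng.integers(0, 3, 50)
        gx[rng.integers(0, 50, 5)] = MISSING
        group = rng.random(50) < 0.7
        t = build_joint_table(gx, gy, group)
        counts = np.zeros((3, 3))
        n = 0
        for a, b, g in zip(gx, gy, group):
            if g and a != MISSING and b != MISSING:
                counts[a, b] += 1
                n += 1
        assert t.n_used == n
        np.testing.assert_allclose(t.p, counts / n)


class TestRho:
    @pytest.mark.parametrize(
        "p, expected",
        [
            # perfect concordance of homozygotes
            ([[0.5, 0, 0], [0, 0, 0], [0, 0, 0.5]], 1.0),
            # perfect discordance
            ([[0, 0, 0.5], [0, 0, 0], [0.5, 0, 0]], -1.0),
            # uniform table: numerator cancels
            (np.full((3, 3), 1 / 9), 0.0),
            # quarter-mass on the w/h block: 0.25 / sqrt(0.5*0.5)
            ([[0.25, 0.25, 0], [0.25, 0.25, 0], [0, 0, 0]], 0.5),
        ],
    )
    def test_closed_form_examples(self, p, expected):
        assert rho(table_from(p)) == pytest.approx(expected, abs=1e-15)

    def test_all_heterozygote_margin_undefined(self):
        p = np.zeros((3, 3))
        p[1, 0] = p[1, 2] = 0.5  # x always heterozygous
        assert math.isnan(rho(table_from(p)))

    def test_symmetry_under_transpose(self, rng):
        for _ in range(50):
            p = rng.random((3, 3))
            p /= p.sum()
            assert rho(table_from(p)) == pytest.approx(rho(table_from(p.T)), abs=1e-12)

    def test_bounded_on_genotype_tables(self, rng):
        # Cauchy-Schwarz bound holds for any table realizable from genotypes
        for _ in range(200):
            gx = rng.integers(0, 3, 40)
            gy = rng.integers(0, 3, 40)
            r = rho(build_joint_table(gx, gy, np.ones(40, bool)))
            if not math.isnan(r):
                assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    def test_self_pair_is_one_with_homozygotes(self, rng):
        for _ in range(20):
            gx = rng.integers(0, 3, 30)
            if (gx != 1).sum() == 0:
                continue
            r = rho(build_joint_table(gx, gx, np.ones(30, bool)))
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_equals_individual_level_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 200))
            gx = rng.integers(0, 3, n)
            gy = rng.integers(0, 3, n)
            group = rng.random(n) < 0.8
            expected = rho_oracle(gx, gy, group)
            got = rho(build_joint_table(gx, gy, group))
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestScorePair:
    def test_identical_vectors_zero_contrast(self):
        g = np.array([0, 2, 0, 2, 1, 0, 2, 0])
        status = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        s = score_pair(g, g, status, ~status)
        assert s.rho_case == pytest.approx(1.0)
        assert s.rho_control == pytest.approx(1.0)
        assert s.rho_diff == pytest.approx(0.0)

    def test_maximal_contrast_is_two(self):
        # controls concordant (rho=+1), cases discordant (rho=-1)
        gx = np.array([0, 2, 0, 2, 0, 2, 0, 2])
        gy = np.array([2, 0, 2, 0, 0, 2, 0, 2])
        case = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        s = score_pair(gx, gy, case, ~case)
        assert s.rho_control == pytest.approx(1.0)
        assert s.rho_case == pytest.approx(-1.0)
        assert s.rho_diff == pytest.approx(2.0)

    def test_invalid_when_group_degenerate(self):
        gx = np.array([1, 1, 0, 2])  # cases all heterozygous at x
        gy = np.array([0, 2, 0, 2])
        case = np.array([1, 1, 0, 0], bool)
        s = score_pair(gx, gy, case, ~case)
        assert not s.valid
        assert math.isnan(s.rho_diff)

    def test_random_pairs_match_end_to_end_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            gx = rng.integers(0, 3, n)
            gy = rng.integers(0, 3, n)
            status = np.zeros(n, bool)
            status[: n // 2] = True
            s = score_pair(gx, gy, status, ~status)
            rc = rho_oracle(gx, gy, status)
            rk = rho_oracle(gx, gy, ~status)
            if s.valid:
                assert s.rho_diff == pytest.approx(abs(rk - rc), abs=1e-12)
            else:
                assert math.isnan(rc) or math.isnan(rk)


class TestScan:
    def test_pair_count_formula(self):
        assert pair_count(100) == 4950
        with pytest.raises(ValueError, match="at least two"):
            pair_count(1)

    def test_emits_each_pair_once(self, rng):
        gm, labels = random_case_control(rng, 12, 30)
        rec = scan_to_records(gm, labels, chunk_size=5)
        pairs = {(int(i), int(j)) for i, j in zip(rec["i"], rec["j"])}
        assert len(pairs) == rec.size == pair_count(12)
        assert all(i < j for i, j in pairs)

    @pytest.mark.parametrize("chunk_size", [5, 37, 100])
    @pytest.mark.parametrize("workers", [1, 3])
    def test_chunking_and_workers_bit_identical(self, rng, chunk_size, workers):
        gm, labels = random_case_control(rng, 37, 50, missing_rate=0.05)
        baseline = scan_to_records(gm, labels, chunk_size=37, workers=1)
        other = scan_to_records(gm, labels, chunk_size=chunk_size, workers=workers)
        order_b = np.lexsort((baseline["j"], baseline["i"]))
        order_o = np.lexsort((other["j"], other["i"]))
        for fld in baseline.dtype.names:
            np.testing.assert_array_equal(baseline[order_b][fld], other[order_o][fld])

    def test_scan_matches_score_pair(self, rng):
        gm, labels = random_case_control(rng, 10, 40, missing_rate=0.1)
        rec = scan_to_records(gm, labels, chunk_size=3)
        by_pair = {(int(r["i"]), int(r["j"])): r for r in rec}
        for i in range(10):
            for j in range(i + 1, 10):
                s = score_pair(
                    gm.genotypes[i], gm.genotypes[j],
                    labels.case_mask, labels.control_mask, i=i, j=j,
                )
                r = by_pair[(i, j)]
                assert bool(r["valid"]) == s.valid
                if s.valid:
                    assert r["rho_diff"] == pytest.approx(s.rho_diff, abs=1e-12)
                assert r["n_case_used"] == s.n_case_used

    def test_allele_relabel_negates_rhos_fixes_rho_diff(self, rng):
        gm, labels = random_case_control(rng, 6, 60)
        base = scan_to_records(gm, labels)
        flipped = scan_to_records(relabel_alleles(gm, 2), labels)
        for b, f in zip(base, flipped):
            touches = 2 in (b["i"], b["j"])
            sign = -1.0 if touches else 1.0
            assert f["rho_case"] == pytest.approx(sign * b["rho_case"], abs=1e-12)
            assert f["rho_control"] == pytest.approx(sign * b["rho_control"], abs=1e-12)
            assert f["rho_diff"] == pytest.approx(b["rho_diff"], abs=1e-12)

    def test_permutation_null_contrast_near_zero(self, rng):
        # with labels random, mean rho_diff is small relative to its spread
        gm, _ = random_case_control(rng, 20, 400)
        status = np.zeros(400, bool)
        status[rng.permutation(400)[:200]] = True
        from iloci.genotype_io import PhenotypeLabels

        labels = PhenotypeLabels(gm.sample_ids, status)
        rec = scan_to_records(gm, labels)
        diffs = rec["rho_diff"][rec["valid"]]
        # rho_diff >= 0 by construction; under the null its typical size is
        # sampling noise ~ 1/sqrt(n); check the scale, not the sign
        assert np.mean(diffs) < 0.2
        assert np.quantile(diffs, 0.99) < 0.35


@st.composite
def genotype_pair(draw):
    n = draw(st.integers(min_value=8, max_value=60))
    codes = st.integers(min_value=0, max_value=2)
    gx = draw(st.lists(codes, min_size=n, max_size=n))
    gy = draw(st.lists(codes, min_size=n, max_size=n))
    return np.array(gx), np.array(gy)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(genotype_pair())
def test_rho_property_bounds_and_oracle(pair):
    """rho is within [-1,1] and equals the individual-level moment ratio."""
    gx, gy = pair
    group = np.ones(gx.size, bool)
    got = rho(build_joint_table(gx, gy, group))
    expected = rho_oracle(gx, gy, group)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert abs(got - expected) < 1e-12
        assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12


def test_ld_concordance_monotone(rng):
    """|rho| tracks haplotype-level LD: rank-monotone in r over a grid.

    Haplotype pairs are simulated under HWE by random union of gametes with
    allele frequency 0.3 at both loci and haplotype correlation r; the
    genotype-level statistic must increase with the generating |r|.
    """
    q = 0.3
    rs = np.linspace(0.0, 0.9, 10)
    rhos = []
    for r in rs:
        d = r * q * (1 - q)  # D = r * sqrt(pq * pq) for equal frequencies
        probs = np.array(
            [
                (1 - q) * (1 - q) + d,  # AB (major-major)
                (1 - q) * q - d,  # Ab
                q * (1 - q) - d,  # aB
                q * q + d,  # ab
            ]
        )
        hap = rng.choice(4, size=(20000, 2), p=probs)
        # variant-allele dosage per locus from the two gametes
        a1 = np.isin(hap[:, 0], (2, 3)).astype(int) + np.isin(hap[:, 1], (2, 3))
        a2 = np.isin(hap[:, 0], (1, 3)).astype(int) + np.isin(hap[:, 1], (1, 3))
        rhos.append(abs(rho_oracle(a1, a2, np.ones(20000, bool))))
    from scipy.stats import spearmanr

    corr = spearmanr(rs, rhos).statistic
    assert corr > 0.95
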