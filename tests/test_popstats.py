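"""Windowed pi, FST (Weir-Cockerham and Hudson), PBS, outlier calling."""

import itertools
import math

import numpy as np
import pytest

from popgenscan.popstats import (
    PbsComponents,
    WindowStat,
    empirical_outliers,
    mean_fst,
    pbs_scan,
    pbs_to_window_stats,
    site_fst,
    window_fst,
    window_pi,
)
from popgenscan.simdata import DemographyConfig, SweepSpec, simulate_truth

from conftest import make_gm


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_pairwise_oracle(geno_col):
    """Mean per-pair allele differences over all haploid pairs at a site."""
    alleles = []
    for g in geno_col:
        if g < 0:
            continue
        alleles += [1] * int(g) + [0] * (2 - int(g))
    diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
    return float(np.mean(diffs)) if diffs else float("nan")


def wc_fst_oracle(g1, g2):
    """Line-by-line transcription of the two-population Weir-Cockerham
    (1984) per-site estimator from the published formulas."""
    g1 = [g for g in g1 if g >= 0]
    g2 = [g for g in g2 if g >= 0]
    n1, n2 = len(g1), len(g2)
    r = 2
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, a + b + c


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

class TestWindowPi:
    def test_forced_single_site_value(self):
        # n = 4 alleles, j = 2: pi = 2*2*(4-2)/(4*3) = 2/3, i.e. 4 of the
        # 6 haploid pairs differ; window 100 bp
        gm = make_gm(np.array([[1], [1]], dtype=np.int8), pos=[50], chrom_lengths={"1": 100})
        [w] = window_pi(gm, "P", window_bp=100)
        assert w.value == pytest.approx((2 / 3) / 100, abs=1e-12)

    def test_monomorphic_window_zero(self):
        gm = make_gm(np.zeros((3, 5), dtype=np.int8), chrom_lengths={"1": 1000})
        [w] = window_pi(gm, "P", window_bp=1000)
        assert w.value == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_pairwise_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.choice([-1, 0, 1, 2], p=[0.1, 0.4, 0.3, 0.2], size=(6, 40)).astype(np.int8)
        pos = np.sort(rng.choice(5000, 40, replace=False)) + 1
        gm = make_gm(geno, pos=pos, chrom_lengths={"1": 5000})
        [w] = window_pi(gm, "P", window_bp=5000)
        exp = np.nansum([pi_pairwise_oracle(gm.geno[:, s]) for s in range(gm.n_sites)])
        assert w.value == pytest.approx(exp / 5000, abs=1e-12)

    def test_invariance_to_sample_order_and_allele_swap(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        gm = make_gm(geno, chrom_lengths={"1": 4000})
        base = [w.value for w in window_pi(gm, "P", window_bp=4000)]
        perm = make_gm(geno[::-1], chrom_lengths={"1": 4000})
        swapped = make_gm((2 - geno).astype(np.int8), chrom_lengths={"1": 4000})
        assert [w.value for w in window_pi(perm, "P", window_bp=4000)] == base
        assert [w.value for w in window_pi(swapped, "P", window_bp=4000)] == base

    def test_bad_window_rejected(self):
        gm = make_gm(np.ones((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            window_pi(gm, "P", window_bp=0)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

class TestSiteFst:
    def _two_pop_gm(self, g1, g2):
        geno = np.vstack([g1, g2]).astype(np.int8)
        pops = ["A"] * len(g1) + ["B"] * len(g2)
        return make_gm(geno, pops=pops)

    def test_equal_frequencies_near_zero(self):
        # identical genotype composition in both populations, 30 each
        col = np.array([0, 1, 2] * 10, dtype=np.int8)
        g = np.tile(col, (10, 1)).T  # 30 samples x 10 sites
        gm = self._two_pop_gm(g, g)
        num, den, usable = site_fst(gm, "A", "B")
        assert np.all(usable)
        assert np.all(np.abs(num / den) < 0.05)
        ws = window_fst(gm, "A", "B", window_bp=10_000, step_bp=None)
        assert abs(ws[0].value) < 0.05

    def test_fixed_difference_near_one(self):
        g1 = np.zeros((20, 1), dtype=np.int8)
        g2 = np.full((20, 1), 2, dtype=np.int8)
        gm = self._two_pop_gm(g1, g2)
        for est in ("wc", "hudson"):
            num, den, _ = site_fst(gm, "A", "B", estimator=est)
            assert num[0] / den[0] == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("seed", range(4))
    def test_wc_formula_transcription_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.choice([-1, 0, 1, 2], p=[0.05, 0.4, 0.3, 0.25], size=(8, 20)).astype(np.int8)
        g2 = rng.choice([-1, 0, 1, 2], p=[0.05, 0.25, 0.3, 0.4], size=(6, 20)).astype(np.int8)
        gm = self._two_pop_gm(g1, g2)
        num, den, usable = site_fst(gm, "A", "B")
        for s in range(20):
            if not usable[s]:
                continue
            a_exp, denom_exp = wc_fst_oracle(g1[:, s], g2[:, s])
            assert num[s] == pytest.approx(a_exp, abs=1e-12)
            assert den[s] == pytest.approx(denom_exp, abs=1e-12)

    def test_unknown_estimator(self):
        gm = self._two_pop_gm(np.zeros((2, 2), dtype=np.int8), np.ones((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            site_fst(gm, "A", "B", estimator="nei")


class TestWindowFst:
    def test_single_site_window_equals_site_value(self):
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 3, size=(10, 1)).astype(np.int8)
        geno[0] = 0
        geno[5] = 2
        gm = make_gm(geno, pops=["A"] * 5 + ["B"] * 5)
        num, den, _ = site_fst(gm, "A", "B")
        [w] = window_fst(gm, "A", "B", window_bp=1000, step_bp=None)
        assert w.value == pytest.approx(num[0] / den[0], abs=1e-12)

    @pytest.mark.parametrize("estimator", ["wc", "hudson"])
    def test_reaggregation_oracle(self, estimator):
        rng = np.random.default_rng(8)
        geno = rng.choice([-1, 0, 1, 2], p=[0.05, 0.45, 0.25, 0.25], size=(12, 60)).astype(np.int8)
        pos = np.sort(rng.choice(30_000, 60, replace=False)) + 1
        gm = make_gm(geno, pos=pos, pops=["A"] * 6 + ["B"] * 6, chrom_lengths={"1": 30_000})
        num, den, usable = site_fst(gm, "A", "B", estimator=estimator)
        wins = window_fst(gm, "A", "B", window_bp=5000, step_bp=None,
                          estimator=estimator, anchor="first_variant")
        first = int(pos.min())
        for w in wins:
            in_win = (gm.pos >= w.start) & (gm.pos <= w.end) & usable
            assert w.start >= first
            if in_win.sum() == 0:
                assert w.value is None
            else:
                assert w.value == pytest.approx(
                    num[in_win].sum() / den[in_win].sum(), abs=1e-12
                )

    def test_windows_anchor_at_first_variant_per_chromosome(self):
        geno = np.zeros((4, 6), dtype=np.int8)
        geno[0] = 1
        gm = make_gm(
            geno,
            pos=[5000, 6000, 7000, 300, 900, 1500],
            chrom=["1"] * 3 + ["2"] * 3,
            pops=["A", "A", "B", "B"],
        )
        wins = window_fst(gm, "A", "B", window_bp=1000, step_bp=None)
        by_chrom = {}
        for w in wins:
            by_chrom.setdefault(w.chrom, []).append(w)
        assert by_chrom["1"][0].start == 5000
        assert by_chrom["2"][0].start == 300


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

class TestPbs:
    def test_printed_equation(self):
        # fabricate components with t_no=0.3, t_nd=0.2, t_od=0.1
        f = lambda t: 1.0 - math.exp(-t)
        c = PbsComponents("1", 1, 100, 5, f(0.3), f(0.2), f(0.1))
        assert c.pbs == pytest.approx((0.3 + 0.2 - 0.1) / 2, abs=1e-12)

    def test_clamping_no_nan(self):
        c = PbsComponents("1", 1, 100, 5, -0.5, 1.5, 0.0)
        assert c.t_no == 0.0
        assert math.isfinite(c.t_nd) and c.t_nd > 0
        assert math.isfinite(c.pbs)

    def test_branch_relabel_symmetry(self):
        c = PbsComponents("1", 1, 100, 5, 0.12, 0.30, 0.22)
        swapped = PbsComponents("1", 1, 100, 5, 0.12, 0.22, 0.30)
        # swapping N and OT exchanges t_nd and t_od, keeps t_no
        assert swapped.t_no == c.t_no
        assert swapped.t_nd == c.t_od and swapped.t_od == c.t_nd
        assert swapped.pbs + c.pbs == pytest.approx(c.t_no, abs=1e-12)

    def test_disjoint_groups_required(self, sim_default):
        _, gm, _ = sim_default
        with pytest.raises(ValueError, match="disjoint"):
            pbs_scan(gm, "NGZ", ["NGZ", "EAZ"], "BUF")

    def test_null_pbs_near_zero(self):
        """Target and control drawn from one panmictic population give
        mean PBS within 0.02 of zero (averaged over 5 seeds)."""
        means = []
        for seed in range(5):
            cfg = DemographyConfig(seed=seed, chrom_lengths={"1": 1_500_000})
            gm, _ = simulate_truth(cfg, [])
            ngz = [s for s in gm.samples if s.startswith("NGZ")]
            halves = {s: "A" for s in ngz[:15]}
            halves.update({s: "B" for s in ngz[15:]})
            halves.update(
                {s: "D" for s in gm.samples if s.startswith(("BAN", "BUF"))}
            )
            gm2 = gm.with_populations(halves)
            comps = pbs_scan(gm2, "A", "B", "D", 50_000, 2_000)
            means.append(np.mean([c.pbs for c in comps]))
        assert abs(np.mean(means)) < 0.02

    def test_four_scenarios_share_windows_and_pool_controls(self, sim_default):
        from popgenscan.popstats import pbs_four_scenarios

        _, gm, _ = sim_default
        # reuse the five simulated populations as stand-ins for the four
        # control configurations
        scans = pbs_four_scenarios(
            gm, "NGZ", european="EUT", asian="BAN", african_zebu="EAZ",
            distant="BUF", window_bp=100_000, step_bp=None,
        )
        assert set(scans) == {"PBS1", "PBS2", "PBS3", "PBS4"}
        pooled = pbs_scan(gm, "NGZ", ["EUT", "BAN"], "BUF", 100_000, None)
        assert [c.pbs for c in scans["PBS3"]] == [c.pbs for c in pooled]
        keys = {tuple((c.chrom, c.start) for c in s) for s in scans.values()}
        assert len(keys) == 1  # one shared window grid

    def test_sweep_window_in_top_percent(self):
        """A strong simulated sweep puts a sweep-covering window in the
        top 1% of PBS windows in at least 4 of 5 seeds."""
        hits = 0
        for seed in range(5):
            cfg = DemographyConfig(seed=seed)
            gm, _ = simulate_truth(cfg, [SweepSpec("1", 1_000_000, 100_000, 0.9)])
            comps = pbs_scan(gm, "NGZ", "EAZ", ["BAN", "BUF"], 50_000, 2_000)
            top = empirical_outliers(pbs_to_window_stats(comps), 0.01)
            hits += any(w.start <= 1_000_000 <= w.end for w in top)
        assert hits >= 4


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

class TestEmpiricalOutliers:
    @staticmethod
    def _wins(values):
        return [
            WindowStat("1", 1 + i * 10, 10 + i * 10, 1, v, "x")
            for i, v in enumerate(values)
        ]

    def test_exact_count_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(1000).astype(float).tolist()
        top = empirical_outliers(self._wins(vals), 0.01)
        assert len(top) == 10
        assert sorted(w.value for w in top) == sorted(vals)[-10:]

    def test_all_ties_returned(self):
        top = empirical_outliers(self._wins([5.0] * 20), 0.01)
        assert len(top) == 20

    def test_missing_windows_excluded(self):
        wins = self._wins([1.0, None, 2.0, None, 3.0])
        top = empirical_outliers(wins, 0.4)
        assert all(w.value is not None for w in top)

    @pytest.mark.parametrize("seed", range(3))
    def test_sort_and_slice_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(157).tolist()
        q = 0.05
        top = empirical_outliers(self._wins(vals), q)
        k = math.ceil((1 - q) * len(vals))
        thr = sorted(vals)[min(k, len(vals) - 1)]
        expected = {v for v in vals if v >= thr}
        assert {w.value for w in top} == expected
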