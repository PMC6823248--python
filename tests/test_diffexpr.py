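"""Moderated-t differential expression: transforms, prior, moderation, FDR."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma

from immunosig.core import SCALE_LOG2, SCALE_RAW, ExpressionMatrix, StudyDesign, ValidationError
from immunosig.diffexpr import (
    VariancePrior,
    bh_fdr,
    call_de,
    de_table,
    estimate_prior,
    fit_two_group,
    moderate,
    normalize_log2,
)

from oracles import naive_bh, naive_pooled_t


class TestNormalizeLog2:
    def test_zero_count_in_million_read_sample_maps_to_minus_one(self):
        data = pd.DataFrame(
            {"s1": [0.0, 1_000_000.0], "s2": [10.0, 999_990.0]},
            index=["g1", "g2"],
        )
        em = normalize_log2(ExpressionMatrix(data, SCALE_RAW))
        assert em.data.loc["g1", "s1"] == pytest.approx(math.log2(0.5))
        assert em.scale == SCALE_LOG2

    def test_depth_doubling_shifts_only_via_offset(self, rng):
        counts = rng.integers(500, 5000, (50, 1)).astype(float)
        base = pd.DataFrame(counts, columns=["s1"])
        doubled = pd.DataFrame(2 * counts, columns=["s1"])

        def transform(frame):
            both = pd.concat([frame, frame.rename(columns={"s1": "s2"})], axis=1)
            return normalize_log2(ExpressionMatrix(both, SCALE_RAW)).data["s1"]

        a = transform(base)
        b = transform(doubled)
        shift = (a - b).abs()
        cpm = counts.ravel() / counts.sum() * 1e6
        assert shift.to_numpy()[cpm >= 500].max() <= 0.002

    def test_log2_input_passes_through(self, toy_log2):
        out = normalize_log2(toy_log2)
        pd.testing.assert_frame_equal(out.data, toy_log2.data)

    def test_all_zero_sample_is_an_error(self):
        data = pd.DataFrame({"ok": [1.0, 2.0], "empty": [0.0, 0.0]})
        with pytest.raises(ValidationError, match="empty"):
            normalize_log2(ExpressionMatrix(data, SCALE_RAW))


class TestFitTwoGroup:
    def test_identical_groups_give_zero_logfc_and_variance(self):
        data = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0]], index=["g"], columns=list("abcd")
        )
        em = ExpressionMatrix(data, SCALE_LOG2)
        design = StudyDesign.from_mapping(
            {"a": "x", "b": "x", "c": "y", "d": "y"}, reference="x"
        )
        frame, d, n1, n2 = fit_two_group(em, design)
        assert frame["logFC"].iloc[0] == 0 and frame["s2"].iloc[0] == 0
        assert (d, n1, n2) == (2, 2, 2)

    def test_hand_computed_pooled_variance(self):
        data = pd.DataFrame(
            [[0.0, 2.0, 3.0, 5.0]], index=["g"], columns=list("abcd")
        )
        em = ExpressionMatrix(data, SCALE_LOG2)
        design = StudyDesign.from_mapping(
            {"a": "x", "b": "x", "c": "y", "d": "y"}, reference="x"
        )
        frame, d, *_ = fit_two_group(em, design)
        assert frame["logFC"].iloc[0] == pytest.approx(3.0)
        assert frame["s2"].iloc[0] == pytest.approx(2.0)
        assert d == 2

    def test_label_swap_flips_logfc_only(self, toy_log2, toy_design):
        frame, *_ = fit_two_group(toy_log2, toy_design)
        swapped = StudyDesign.from_mapping(
            dict(toy_design.assignments), reference="trt"
        )
        frame2, *_ = fit_two_group(toy_log2, swapped)
        np.testing.assert_allclose(frame2["logFC"], -frame["logFC"])
        np.testing.assert_allclose(frame2["s2"], frame["s2"])

    def test_group_of_one_rejected(self, toy_log2):
        design = StudyDesign.from_mapping(
            {"A1": "x", "A2": "x", "B1": "x", "B2": "y"}
        )
        with pytest.raises(ValidationError, match=">= 2"):
            fit_two_group(toy_log2, design)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 3.0)
        prior = estimate_prior(s2, d=4)
        assert math.isinf(prior.d0)
        assert prior.s02 == pytest.approx(3.0)

    def test_parameter_recovery_from_scaled_f_draws(self):
        rng = np.random.default_rng(7)
        d0_true, s02_true, d = 4.0, 2.0, 4
        s2 = s02_true * stats.f.rvs(d, d0_true, size=20_000, random_state=rng)
        prior = estimate_prior(s2, d)
        assert abs(prior.d0 - d0_true) / d0_true < 0.15
        assert abs(prior.s02 - s02_true) / s02_true < 0.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        s2 = stats.f.rvs(4, 6, size=5000, random_state=rng)
        p1 = estimate_prior(s2, 4)
        p2 = estimate_prior(2 * s2, 4)
        assert p2.s02 == pytest.approx(2 * p1.s02, rel=1e-9)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-6)

    def test_too_few_positive_variances_instructs_more_genes(self):
        with pytest.raises(ValidationError, match="50"):
            estimate_prior(np.ones(10), 4)


class TestModerate:
    def test_degenerate_prior_reproduces_pooled_t(self, rng):
        for _ in range(20):
            g1 = rng.normal(0, 1, 4).tolist()
            g2 = rng.normal(1, 1, 4).tolist()
            logfc = np.mean(g2) - np.mean(g1)
            s2 = (
                np.sum((np.array(g1) - np.mean(g1)) ** 2)
                + np.sum((np.array(g2) - np.mean(g2)) ** 2)
            ) / 6
            t, _, _ = moderate(
                np.array([logfc]), np.array([s2]), 6,
                VariancePrior(0.0, 1.0), 4, 4,
            )
            assert t[0] == pytest.approx(naive_pooled_t(g1, g2), abs=1e-12)

    def test_infinite_prior_is_fixed_variance_z(self):
        t, p, s2t = moderate(
            np.array([1.0]), np.array([5.0]), 4,
            VariancePrior(math.inf, 2.0), 3, 3,
        )
        expected_t = 1.0 / math.sqrt(2.0 * (2 / 3))
        assert t[0] == pytest.approx(expected_t)
        assert s2t[0] == 2.0
        assert p[0] == pytest.approx(2 * stats.norm.sf(expected_t))

    def test_hand_computed_toy_gene(self):
        # logFC 3, s2 2, d 2, prior (d0=2, s02=1): s~2 = 1.5, t = 3/sqrt(1.5)
        t, p, s2t = moderate(
            np.array([3.0]), np.array([2.0]), 2, VariancePrior(2.0, 1.0), 2, 2
        )
        assert s2t[0] == pytest.approx(1.5)
        assert t[0] == pytest.approx(3 / math.sqrt(1.5))
        assert p[0] == pytest.approx(2 * stats.t.sf(3 / math.sqrt(1.5), 4))

    def test_shrinkage_is_convex_combination(self, rng):
        s2 = rng.gamma(2, 1, 200)
        prior = VariancePrior(3.0, 1.5)
        _, _, s2t = moderate(np.ones(200), s2, 4, prior, 3, 3)
        w = 3.0 / (3.0 + 4)
        np.testing.assert_allclose(s2t, w * 1.5 + (1 - w) * s2, rtol=1e-12)
        assert np.all(s2t >= np.minimum(s2, 1.5) - 1e-12)
        assert np.all(s2t <= np.maximum(s2, 1.5) + 1e-12)

    def test_zero_variance_nonzero_logfc_convention(self):
        t, p, _ = moderate(
            np.array([2.0, 0.0]), np.array([0.0, 0.0]), 2,
            VariancePrior(0.0, 1.0), 2, 2,
        )
        assert math.isinf(t[0]) and p[0] == 0.0
        assert t[1] == 0.0 and p[1] == 1.0


class TestBhFdr:
    def test_forced_arithmetic(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_fdr(np.ones(5)), np.ones(5))

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 8)
            np.testing.assert_allclose(bh_fdr(p), naive_bh(p.tolist()), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_fdr(p)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_monotone_under_single_p_increase(self, rng):
        p = rng.uniform(0, 1, 15)
        q = bh_fdr(p)
        for i in range(15):
            bumped = p.copy()
            bumped[i] = min(1.0, p[i] + 0.2)
            assert np.all(bh_fdr(bumped) >= q - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 1.5]))


class TestCallDe:
    def test_partition_and_sorting(self, rng):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "logFC": rng.normal(0, 1, 20),
                "p": rng.uniform(0, 1, 20),
            }
        )
        table["q"] = bh_fdr(table["p"].to_numpy() / 50)
        inc, dec = call_de(table, 0.1)
        n_sig = int((table["q"] < 0.1).sum())
        assert len(inc) + len(dec) == n_sig
        ps = table.set_index("gene")["p"]
        assert list(ps[inc]) == sorted(ps[inc])
        assert list(ps[dec]) == sorted(ps[dec])

    def test_no_significance_gives_empty_lists(self):
        table = pd.DataFrame(
            {"gene": ["a"], "logFC": [2.0], "p": [0.5], "q": [0.5]}
        )
        inc, dec = call_de(table, 0.05)
        assert inc == [] and dec == []


def test_null_simulation_type_one_control():
    """With no true effects, the q < 0.1 discovery fraction stays near zero."""
    from immunosig.simulate import CellModule, SimulationConfig, simulate_bulk

    frac = []
    for seed in range(10):
        cfg = SimulationConfig(
            n_genes=1000, n_control=4, n_treated=4,
            modules=(CellModule("PC", 10, 0.05, 1.0),),
            n_direct=0, seed=seed,
        )
        matrix, _, design = simulate_bulk(cfg)
        table = de_table(normalize_log2(matrix), design, 0.1)
        frac.append((table["q"] < 0.1).mean())
    mcse = np.std(frac, ddof=1) / np.sqrt(len(frac))
    assert np.mean(frac) <= 0.1 + 3 * mcse


def test_agrees_with_limma_ebayes(tmp_path, rng):
    """Cross-check the whole moderation chain against limma via Rscript."""
    import subprocess

    p, n = 300, 8
    base = rng.normal(7, 2, (p, 1))
    sd = rng.uniform(0.2, 1.2, (p, 1))  # heteroscedastic: finite-d0 branch
    x = base + rng.normal(0, 1, (p, n)) * sd
    x[: p // 10, n // 2:] += 1.0
    frame = pd.DataFrame(
        x, index=[f"g{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)],
    )
    frame.to_csv(tmp_path / "expr.tsv", sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        x <- as.matrix(read.delim(args[1], row.names=1))
        group <- factor(rep(c("ctl","trt"), each=ncol(x)/2), levels=c("ctl","trt"))
        fit <- eBayes(lmFit(x, model.matrix(~group)))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(format(out, digits=15), args[2], sep="\t", quote=FALSE)
        """
    )
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "expr.tsv"),
         str(tmp_path / "limma_out.tsv")],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")

    em = ExpressionMatrix(frame, SCALE_LOG2)
    design = StudyDesign.from_mapping(
        {f"s{j}": ("ctl" if j < n // 2 else "trt") for j in range(n)},
        reference="ctl",
    )
    table = de_table(em, design, 0.05)
    prior = table.attrs["prior"]
    assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert prior.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
    np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(table["p"], ref["p"], rtol=1e-5)
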