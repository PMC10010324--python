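"""Conditional logistic regression: closed forms, oracles, invariances.

The independent oracle below recomputes the conditional likelihood by
straightforward per-set enumeration (no shared code with the fitter) and
maximizes it with scipy's derivative-free Nelder-Mead, refined by a dense
grid where the dimension allows.
"""
from __future__ import annotations

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from drugscreen.clr import (MatchedDesign, conditional_loglik,
                            fit_categorical_model, fit_clr,
                            fit_dose_response_model)
from drugscreen.errors import FitError, NoExposedSubjectsError


def brute_loglik(X, y, sets, beta):
    """Plain-Python conditional log likelihood (oracle, no vectorization)."""
    total = 0.0
    for s in sorted(set(sets)):
        rows = [i for i in range(len(y)) if sets[i] == s]
        etas = {i: float(np.dot(X[i], beta)) for i in rows}
        case = [i for i in rows if y[i]]
        assert len(case) == 1
        shift = max(etas.values())
        den = sum(np.exp(e - shift) for e in etas.values())
        total += (etas[case[0]] - shift) - np.log(den)
    return total


def brute_fit(X, y, sets, p):
    res = minimize(lambda b: -brute_loglik(X, y, sets, b), np.zeros(p),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


def design_from(X, y, sets):
    return MatchedDesign.from_rows(np.asarray(X, float), y, sets,
                                   [f"b{i}" for i in range(np.shape(X)[1])])


def discordant_design(n_case_exposed, n_control_exposed, n_concordant):
    """1:1 sets with a single binary exposure."""
    X, y, sets = [], [], []
    s = 0
    for _ in range(n_case_exposed):
        X += [[1.0], [0.0]]; y += [1, 0]; sets += [f"S{s:04d}"] * 2; s += 1
    for _ in range(n_control_exposed):
        X += [[0.0], [1.0]]; y += [1, 0]; sets += [f"S{s:04d}"] * 2; s += 1
    for _ in range(n_concordant):
        X += [[1.0], [1.0]]; y += [1, 0]; sets += [f"S{s:04d}"] * 2; s += 1
    return design_from(X, y, sets)


class TestLoglik:
    def test_uniform_softmax_at_zero(self):
        rng = np.random.default_rng(0)
        X, y, sets = [], [], []
        sizes = [2, 4, 6, 11]
        for s, m in enumerate(sizes):
            for j in range(m):
                X.append([rng.normal()]); y.append(1 if j == 0 else 0)
                sets.append(f"S{s}")
        d = design_from(X, y, sets)
        ll, _, _ = conditional_loglik(d, np.zeros(1))
        assert ll == pytest.approx(sum(np.log(1.0 / m) for m in sizes))

    @pytest.mark.parametrize("b", [-2.0, 0.0, 0.7, 3.0])
    def test_single_pair_closed_form(self, b):
        d = discordant_design(1, 0, 0)
        ll, _, _ = conditional_loglik(d, np.array([b]))
        assert ll == pytest.approx(b - np.log(1 + np.exp(b)))

    def test_loglik_nonpositive(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = ([1] + [0] * 4) * 6
        sets = np.repeat([f"S{i}" for i in range(6)], 5)
        d = design_from(X, y, sets)
        for _ in range(5):
            ll, _, _ = conditional_loglik(d, rng.normal(size=2))
            assert ll <= 0

    def test_gradient_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 3))
        y = ([1] + [0] * 3) * 6
        sets = np.repeat([f"S{i}" for i in range(6)], 4)
        d = design_from(X, y, sets)
        beta = rng.normal(size=3) * 0.5
        ll, grad, hess = conditional_loglik(d, beta)
        eps = 1e-6
        for k in range(3):
            e = np.zeros(3); e[k] = eps
            lp, gp, _ = conditional_loglik(d, beta + e)
            lm, gm, _ = conditional_loglik(d, beta - e)
            assert grad[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)
            assert hess[:, k] == pytest.approx((gp - gm) / (2 * eps), abs=1e-5)

    def test_nonfinite_predictor_names_set(self):
        d = discordant_design(1, 0, 0)
        d.X[0, 0] = np.inf
        with pytest.raises(FitError, match="S0000"):
            conditional_loglik(d, np.array([1.0]))


class TestFit:
    def test_discordant_pair_closed_form_or(self):
        # 10 case-exposed-only vs 5 control-exposed-only discordant 1:1 sets
        # -> conditional MLE is exactly the ratio 10/5 = 2
        d = discordant_design(10, 5, 85)
        res = fit_clr(d)
        assert res.converged
        assert res.or_[0] == pytest.approx(2.0, abs=1e-7)
        assert res.beta[0] == pytest.approx(np.log(2.0), abs=1e-7)

    def test_no_information_gives_null_or(self):
        # case and control identical within every set: OR 1, no precision
        X = [[1.0], [1.0], [0.0], [0.0]]
        y = [1, 0, 1, 0]
        sets = ["A", "A", "B", "B"]
        res = fit_clr(design_from(X, y, sets))
        assert res.beta[0] == pytest.approx(0.0)
        assert res.or_[0] == pytest.approx(1.0)

    def test_matches_bruteforce_on_small_designs(self):
        # tiny designs may be separable by chance; compare only draws whose
        # oracle optimum is finite and interior
        rng = np.random.default_rng(3)
        compared = 0
        for trial in range(20):
            X = rng.normal(size=(9, 2))
            y = ([1] + [0] * 2) * 3
            sets = np.repeat([f"S{i}" for i in range(3)], 3)
            oracle = brute_fit(X, y, list(sets), 2)
            if np.max(np.abs(oracle)) > 5:
                continue
            res = fit_clr(design_from(X, y, sets))
            assert res.converged
            assert np.max(np.abs(res.beta - oracle)) < 1e-4
            compared += 1
            if compared >= 4:
                break
        assert compared >= 4

    def test_translation_invariance_of_covariates(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        y = ([1] + [0] * 3) * 5
        sets = np.repeat([f"S{i}" for i in range(5)], 4)
        res1 = fit_clr(design_from(X, y, sets))
        shifted = X.copy()
        shifted[:, 1] += 57.3
        res2 = fit_clr(design_from(shifted, y, sets))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-7)
        assert res1.se == pytest.approx(res2.se, abs=1e-7)

    def test_separation_flagged(self):
        d = discordant_design(12, 0, 0)  # exposure perfectly predicts case
        res = fit_clr(d)
        assert not res.converged
        assert any("separation" in w for w in res.warnings)

    def test_zero_control_sets_dropped_and_counted(self):
        X = [[1.0], [1.0], [0.0], [0.5]]
        y = [1, 0, 1, 1]
        sets = ["A", "A", "B", "C"]
        d = MatchedDesign.from_rows(np.asarray(X), y, sets, ["b0"])
        assert d.n_sets == 1
        assert d.n_dropped_sets == 2

    def test_ci_width_shrinks_with_replication(self):
        # duplicating informative sets k-fold scales the SE by 1/sqrt(k)
        base = (8, 4, 20)
        widths = {}
        for k in (1, 4, 16):
            d = discordant_design(*(k * b for b in base))
            res = fit_clr(d)
            widths[k] = np.log(res.ci95[0, 1]) - np.log(res.ci95[0, 0])
        slope = (np.log(widths[16]) - np.log(widths[1])) / np.log(16)
        assert slope == pytest.approx(-0.5, abs=0.1)


def model_frame(rows):
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "n_fills", "cci",
                                     "education"])
    df["category"] = pd.cut(df["n_fills"], [-1, 0, 2, 7, np.inf],
                            labels=["nonuse", "low", "intermediate", "high"])
    df["ever_use"] = (df["n_fills"] >= 1).astype(int)
    df["log2_fills"] = np.where(df["n_fills"] >= 1,
                                np.log2(df["n_fills"].clip(lower=1)), 0.0)
    df["person_id"] = [f"P{i}" for i in range(len(df))]
    return df


class TestModelWrappers:
    def test_all_never_users_rejected(self):
        df = model_frame([("A", 1, 0, 0, "basic"), ("A", 0, 0, 0, "basic")])
        with pytest.raises(NoExposedSubjectsError):
            fit_categorical_model(df)

    def test_categorical_reports_all_three_contrasts(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(40):
            rows.append((f"S{s}", 1, int(rng.integers(0, 15)),
                         int(rng.integers(0, 3)), "basic"))
            for _ in range(3):
                rows.append((f"S{s}", 0, int(rng.integers(0, 15)),
                             int(rng.integers(0, 3)), "vocational"))
        res = fit_categorical_model(model_frame(rows))
        for name in ("low", "intermediate", "high"):
            lo, hi = res.ci_for(name)
            assert lo < res.or_for(name) < hi

    def test_constant_log2_among_users_flagged(self):
        # every user has exactly 4 fills: log2 term collinear with ever-use
        rows = []
        for s in range(20):
            rows.append((f"S{s}", 1, 4 if s % 2 else 0, 0, "basic"))
            rows.append((f"S{s}", 0, 0 if s % 2 else 4, 0, "basic"))
        res = fit_dose_response_model(model_frame(rows))
        assert (not res.converged) or res.warnings

    def test_exposed_case_count_reported(self):
        rows = [("S0", 1, 9, 0, "basic"), ("S0", 0, 0, 0, "basic"),
                ("S1", 1, 0, 0, "basic"), ("S1", 0, 9, 0, "basic")]
        res = fit_categorical_model(model_frame(rows))
        assert res.n_exposed_cases == 1


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstRSurvival:
    def test_matches_clogit(self, tmp_path):
        """Cross-check against the survival package's clogit fitter."""
        rng = np.random.default_rng(6)
        rows = []
        for s in range(60):
            for j in range(4):
                rows.append({"set": s, "y": 1 if j == 0 else 0,
                             "x1": float(rng.normal())
                             + (0.8 if j == 0 else 0.0),
                             "x2": float(rng.integers(0, 3))})
        df = pd.DataFrame(rows)
        d = MatchedDesign.from_rows(df[["x1", "x2"]].to_numpy(),
                                    df["y"], df["set"].astype(str),
                                    ["x1", "x2"])
        res = fit_clr(d)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- clogit(y ~ x1 + x2 + strata(set), data = d)
            cat(sprintf("%.10f %.10f\\n", coef(f)[1], coef(f)[2]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=240)
        assert out.returncode == 0, out.stderr
        r_beta = np.array([float(v) for v in out.stdout.split()])
        assert np.max(np.abs(res.beta - r_beta)) < 1e-4
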