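"""Simulation studies that characterise the estimator and the pipeline.

These routines are the package's own statistical validation: likelihood
correctness against a direct multivariate-normal density, type-I error of
PGLS versus ordinary least squares under clade-clustered predictors, effect
and λ recovery, AIC model selection under Brownian generation, and end-to-end
calibration of the full occurrence → extremes → PGLS pipeline on synthetic
bundles with known truth. The same routines back the test suite and the
acceptance script.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from . import contrast_pipeline as cp
from .backbone_tree import BranchLengthScheme
from .pgls_core import (
    CorrelationModel,
    Family,
    TreeData,
    build_design,
    fit_pgls,
    gls_fit,
    model_suite,
    transform_vcv,
)
from .synthetic_data import (
    ScenarioConfig,
    assign_states_by_clades,
    make_scenario,
    sigma_for_power,
    simulate_yule_tree,
)


def _clustered_design(tree, rng, n_transitions: int = 5):
    """C4 indicator painted on clades — the predictor regime of the study system."""
    states, _ = assign_states_by_clades(tree, n_transitions, rng)
    td = TreeData.ensure(tree)
    ordered = [states[l] for l in td.labels]
    return td, build_design(ordered), states


def loglik_oracle_deviation(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |GLS profile log-likelihood − direct MVN density| over random instances.

    Instances are random 4–8 taxon Yule trees with Brownian covariance; the
    oracle evaluates the multivariate-normal density at (X β̂, σ̂²V) with
    scipy, independently of the GLS solve path.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 9))
        tree = simulate_yule_tree(n, 1.0, rng)
        td = TreeData(tree)
        states = ["C3"] * (n // 2) + ["C4"] * (n - n // 2)
        X = build_design(states)
        y = rng.normal(size=n) * 2.0 + 1.0
        res = gls_fit(y, X, td.V, method="ML")
        direct = stats.multivariate_normal.logpdf(
            y, mean=X @ res.beta, cov=res.sigma2 * td.V
        )
        worst = max(worst, abs(res.log_likelihood - float(direct)))
    return {"max_abs_deviation": worst, "n": n_instances}


def type_i_error_study(
    n_tips: int = 200,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    trees: int = 10,
) -> dict:
    """Rejection rates of PGLS (Brownian) and OLS when β1 = 0.

    Responses are Brownian on the tree; the C4 predictor is clade-clustered,
    the regime in which OLS treats phylogenetic pseudo-replication as sample
    size and inflates its type-I error.
    """
    rng = np.random.default_rng(seed)
    reps_per_tree = n_reps // trees
    pgls_rej = ols_rej = 0
    total = 0
    for _ in range(trees):
        tree = simulate_yule_tree(n_tips, 1.0, rng)
        td, X, _ = _clustered_design(tree, rng)
        L = np.linalg.cholesky(td.V)
        for _ in range(reps_per_tree):
            y = L @ rng.standard_normal(td.n)  # β0 = β1 = 0, σ = 1
            fit_p = fit_pgls(y, X, td, Family.BROWNIAN)
            fit_o = fit_pgls(y, X, td, Family.INDEPENDENT)
            pgls_rej += fit_p.p_value <= alpha
            ols_rej += fit_o.p_value <= alpha
            total += 1
    return {
        "pgls_rate": pgls_rej / total,
        "ols_rate": ols_rej / total,
        "n": total,
    }


def recovery_study(
    n_tips: int = 200,
    n_reps: int = 1000,
    beta1: float = 1.61,
    seed: int = 0,
    trees: int = 10,
) -> dict:
    """β1 recovery and 95% CI coverage under Brownian generation.

    σ is set by the generator's analytic power rule, so the injected warm-limit
    shift is detectable by design; coverage uses β̂1 ± t₀.₉₇₅,ₙ₋₂·se."""
    rng = np.random.default_rng(seed)
    reps_per_tree = n_reps // trees
    estimates, covered = [], 0
    total = 0
    for _ in range(trees):
        tree = simulate_yule_tree(n_tips, 1.0, rng)
        td, X, states = _clustered_design(tree, rng)
        sigma = sigma_for_power(td, states, beta1, power=0.95)
        L = np.linalg.cholesky(td.V)
        tcrit = stats.t.ppf(0.975, td.n - 2)
        for _ in range(reps_per_tree):
            y = X @ np.array([0.0, beta1]) + sigma * (L @ rng.standard_normal(td.n))
            fit = fit_pgls(y, X, td, Family.BROWNIAN)
            estimates.append(fit.beta1)
            covered += abs(fit.beta1 - beta1) <= tcrit * fit.se_beta1
            total += 1
    return {
        "mean_beta1": float(np.mean(estimates)),
        "true_beta1": beta1,
        "ci_coverage": covered / total,
        "n": total,
    }


def lambda_recovery_study(
    n_tips: int = 200,
    n_reps: int = 1000,
    true_lambda: float = 0.7,
    seed: int = 0,
    trees: int = 10,
) -> dict:
    """Mean λ̂ when data are generated under Pagel's λ."""
    rng = np.random.default_rng(seed)
    reps_per_tree = n_reps // trees
    estimates = []
    for _ in range(trees):
        tree = simulate_yule_tree(n_tips, 1.0, rng)
        td, X, _ = _clustered_design(tree, rng)
        C = transform_vcv(td.V, td, CorrelationModel(Family.PAGEL_LAMBDA, true_lambda))
        L = np.linalg.cholesky(C)
        for _ in range(reps_per_tree):
            y = X @ np.array([0.0, 1.0]) + L @ rng.standard_normal(td.n)
            fit = fit_pgls(y, X, td, Family.PAGEL_LAMBDA)
            estimates.append(fit.model.theta)
    return {
        "mean_lambda": float(np.mean(estimates)),
        "true_lambda": true_lambda,
        "n": len(estimates),
    }


def model_selection_study(
    n_tips: int = 200,
    n_reps: int = 200,
    seed: int = 0,
    trees: int = 10,
) -> dict:
    """How often Brownian (or λ̂ ≈ 1) wins the AIC race on Brownian data."""
    rng = np.random.default_rng(seed)
    reps_per_tree = n_reps // trees
    hits = total = 0
    for _ in range(trees):
        tree = simulate_yule_tree(n_tips, 1.0, rng)
        td, X, states = _clustered_design(tree, rng)
        sigma = sigma_for_power(td, states, 1.61, power=0.95)
        L = np.linalg.cholesky(td.V)
        for _ in range(reps_per_tree):
            y = X @ np.array([0.0, 1.61]) + sigma * (L @ rng.standard_normal(td.n))
            sel = model_suite(y, X, td)
            best = sel.best
            ok = best.model.family is Family.BROWNIAN or (
                best.model.family is Family.PAGEL_LAMBDA and best.model.theta >= 0.9
            )
            hits += ok
            total += 1
    return {"brownian_or_lambda1_rate": hits / total, "n": total}


@dataclass
class CalibrationResult:
    power: dict[str, float]  # per nonzero-effect response key
    sign_recovery: dict[str, float]
    false_positive_rate: float
    n_scenarios: int
    n_zero_rows: int

    def as_dict(self) -> dict:
        return {
            "min_power": min(self.power.values()),
            "min_sign_recovery": min(self.sign_recovery.values()),
            "false_positive_rate": self.false_positive_rate,
            "n_scenarios": self.n_scenarios,
            **{f"power_{k}": v for k, v in self.power.items()},
        }


def end_to_end_calibration(
    n_scenarios: int = 100,
    seed: int = 0,
    config: ScenarioConfig | None = None,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Run the full pipeline on synthetic bundles and score against truth.

    For every response with a nonzero injected C4 − C3 shift: the fraction of
    scenarios whose best-model row is significant (power) and whose estimated
    difference has the true sign. Zero-effect rows contribute to the false
    positive rate. Fits use the clade-mean branch-length scheme, matching the
    generating tree.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    sig_counts: dict[str, int] = {}
    sign_counts: dict[str, int] = {}
    nonzero_total: dict[str, int] = {}
    fp = zero_rows = 0
    for _ in range(n_scenarios):
        scen_seed = int(rng.integers(2**31 - 1))
        with tempfile.TemporaryDirectory() as tmp:
            truth = make_scenario(cfg, scen_seed, tmp)
            out = Path(tmp)
            run_cfg = cp.RunConfig(
                occurrences=str(out / "occurrences.csv"),
                grids={v: str(out / f"grid_{v}.asc") for v in ("AI", "MTWQ", "MTCQ")},
                tree=str(out / "tree.nwk"),
                backbone_spec=str(out / "backbone.txt"),
                assignments=str(out / "assignments.csv"),
                schemes=[BranchLengthScheme.CLADE_MEAN],
                alpha=alpha,
                seed=scen_seed,
            )
            rows = cp.run_contrasts(run_cfg)
        for row in rows:
            key = f"{row.variable}_{row.extreme}"
            true_beta1 = truth.effects[key]["beta1"]
            if true_beta1 == 0.0:
                zero_rows += 1
                fp += row.significant
            else:
                nonzero_total[key] = nonzero_total.get(key, 0) + 1
                sig_counts[key] = sig_counts.get(key, 0) + row.significant
                sign_counts[key] = sign_counts.get(key, 0) + (
                    math.copysign(1.0, row.difference) == math.copysign(1.0, true_beta1)
                )
    power = {k: sig_counts.get(k, 0) / n for k, n in nonzero_total.items()}
    sign = {k: sign_counts.get(k, 0) / n for k, n in nonzero_total.items()}
    return CalibrationResult(
        power=power,
        sign_recovery=sign,
        false_positive_rate=fp / zero_rows if zero_rows else 0.0,
        n_scenarios=n_scenarios,
        n_zero_rows=zero_rows,
    )


def equal_scheme_invariance(seed: int = 0) -> bool:
    """Equal-branch-length results are invariant to source branch lengths.

    Builds one synthetic bundle, then permutes the source tree's branch
    lengths; with the all-equal scheme every working branch is reset to 1, so
    the contrast report must be byte-identical.
    """
    from .backbone_tree import parse_newick, write_newick

    rng = np.random.default_rng(seed)
    texts = []
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp)
        make_scenario(ScenarioConfig(), seed, tmp)
        tree = parse_newick((out / "tree.nwk").read_text())
        edges = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
        lengths = [nd.edge.length for nd in edges]
        rng.shuffle(lengths)
        for nd, ln in zip(edges, lengths):
            nd.edge.length = ln
        permuted = out / "tree_permuted.nwk"
        permuted.write_text(write_newick(tree), encoding="utf-8")
        for tree_path in ("tree.nwk", "tree_permuted.nwk"):
            run_cfg = cp.RunConfig(
                occurrences=str(out / "occurrences.csv"),
                grids={v: str(out / f"grid_{v}.asc") for v in ("AI", "MTWQ", "MTCQ")},
                tree=str(out / tree_path),
                backbone_spec=str(out / "backbone.txt"),
                assignments=str(out / "assignments.csv"),
                schemes=[BranchLengthScheme.EQUAL],
                seed=seed,
            )
            rows = cp.run_contrasts(run_cfg)
            report = out / f"report_{tree_path}.tsv"
            cp.write_report(rows, str(report))
            texts.append(report.read_bytes())
    return texts[0] == texts[1]


def determinism_check(seed: int = 0) -> bool:
    """Identical scenario seed + config ⇒ byte-identical contrast reports."""
    texts = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(tmp)
            make_scenario(ScenarioConfig(), seed, tmp)
            run_cfg = cp.RunConfig(
                occurrences=str(out / "occurrences.csv"),
                grids={v: str(out / f"grid_{v}.asc") for v in ("AI", "MTWQ", "MTCQ")},
                tree=str(out / "tree.nwk"),
                backbone_spec=str(out / "backbone.txt"),
                assignments=str(out / "assignments.csv"),
                schemes=[BranchLengthScheme.EQUAL],
                seed=seed,
            )
            rows = cp.run_contrasts(run_cfg)
            report = out / "report.tsv"
            cp.write_report(rows, str(report))
            texts.append(report.read_bytes())
    return texts[0] == texts[1]
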