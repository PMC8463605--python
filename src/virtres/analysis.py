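"""Cohort-level orchestration and statistics.

Ties the pieces together the way the study design prescribes: validate the
eigenvector-centrality surrogate against the SIR model per subject, build
each subject's effect curve and optimal (90%-effect) resection, score every
comparison strategy at the optimal size by both the normalized EC
difference and the normalized I(t0) reduction, compare spared versus
removed candidate connections, and run the group statistics with
false-discovery-rate control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .centrality import centrality_suite, eigenvector_centrality, remove_edges, seed_ec
from .connectome import ConnectomeMatrix, SeedSet, read_connectome, threshold_to_density
from .errors import ConfigError, ParameterError, StatisticsError
from .resection import (
    EffectCurve,
    ResectionPlan,
    SAParams,
    candidate_edges,
    effect_curve,
    strategy_select,
)
from .sir import SIRParameters, calibrate_beta, sir_ensemble
from .synthetic import CohortSpec, Subject, generate_cohort

__all__ = [
    "SurrogateValidation",
    "StrategyComparison",
    "validate_surrogate",
    "compare_strategies",
    "spared_removed_stats",
    "fdr_bh",
    "group_compare",
    "run_pipeline",
]

_METRIC_STRATEGIES = ("edge_bc", "neighbor_ec", "neighbor_degree", "neighbor_bc")


def _conn_ez(subject) -> tuple[ConnectomeMatrix, SeedSet]:
    if isinstance(subject, Subject):
        return subject.connectome, subject.ez
    conn, ez = subject[0], subject[1]
    return conn, ez


@dataclass(frozen=True)
class SurrogateValidation:
    """Correlation between nodal EC and early single-seed propagation I(t=10)."""

    per_subject_r: tuple[float, ...]
    pooled_r: float
    pairs: pd.DataFrame  # columns: subject, node, ec, i_t10
    betas: tuple[float, ...]


def validate_surrogate(
    cohort: Sequence,
    rng: np.random.Generator,
    *,
    gamma: float = 0.03,
    t0: int = 10,
    n_runs: int = 1000,
    betas: Sequence[float] | None = None,
    calibration_runs: int = 1000,
) -> SurrogateValidation:
    """Check the surrogate's premise: EC predicts early spreading.

    For every node of every subject, the SIR model is run with that node as
    the sole seed (at the subject's calibrated beta) and the mean active
    fraction at ``t0`` is read out; the Pearson correlation of (EC, I(t0))
    is computed per subject and pooled over all subjects' nodes.
    """
    rows = []
    used_betas: list[float] = []
    per_r: list[float] = []
    for s_idx, subject in enumerate(cohort):
        conn, ez = _conn_ez(subject)
        if conn.n_nodes < 3:
            raise StatisticsError("need at least 3 nodes to correlate")
        if betas is not None:
            beta = float(betas[s_idx])
        else:
            beta = calibrate_beta(
                conn, ez, gamma=gamma, n_runs=calibration_runs, rng=rng
            ).beta
        used_betas.append(beta)
        ec = eigenvector_centrality(conn)
        params = SIRParameters(beta=beta, gamma=gamma, t_max=t0, n_runs=n_runs, t0=t0)
        for node in range(conn.n_nodes):
            res = sir_ensemble(conn, SeedSet((node,)), params, rng)
            rows.append((s_idx, node, float(ec[node]), res.I_t0))
        sub = [r for r in rows if r[0] == s_idx]
        per_r.append(float(stats.pearsonr([r[2] for r in sub], [r[3] for r in sub])[0]))
    pairs = pd.DataFrame(rows, columns=["subject", "node", "ec", "i_t10"])
    pooled = float(stats.pearsonr(pairs["ec"], pairs["i_t10"])[0])
    return SurrogateValidation(
        per_subject_r=tuple(per_r),
        pooled_r=pooled,
        pairs=pairs,
        betas=tuple(used_betas),
    )


@dataclass(frozen=True)
class StrategyComparison:
    """Per-subject strategy table plus paired-test summaries.

    ``table`` has one row per subject with the candidate count K, the
    optimal size k*, the spared fraction 1 - k*/K, and for each strategy
    the normalized EC difference (``ec_*``) and, when propagation was
    evaluated, the normalized I(t0) reduction (``prop_*``).  The
    full-resection columns are identically 1 by construction.
    """

    table: pd.DataFrame
    tests: pd.DataFrame
    curves: tuple[EffectCurve, ...]
    optimal_plans: tuple[ResectionPlan, ...]
    strategy_plans: tuple[dict[str, ResectionPlan], ...]
    betas: tuple[float, ...]


def _paired_tests(table: pd.DataFrame, prefix: str) -> list[dict]:
    out = []
    pairs = [("optimal", "random_mean")]
    pairs += [("optimal", s) for s in _METRIC_STRATEGIES]
    pairs += [(s, "random_mean") for s in _METRIC_STRATEGIES]
    for a, b in pairs:
        x = table[f"{prefix}_{a}"]
        y = table[f"{prefix}_{b}"]
        if len(x) < 2:
            continue
        t, p = stats.ttest_rel(x, y)
        out.append(
            {
                "measure": prefix,
                "pair": f"{a}-{b}",
                "mean_diff": float((x - y).mean()),
                "t": float(t),
                "df": len(x) - 1,
                "p": float(p),
            }
        )
    return out


def compare_strategies(
    cohort: Sequence,
    rng: np.random.Generator,
    *,
    sa_params: SAParams = SAParams(),
    fraction: float = 0.9,
    n_random: int = 100,
    gamma: float = 0.03,
    t0: int = 10,
    propagation_runs: int | None = 2000,
    calibration_runs: int = 1000,
    betas: Sequence[float] | None = None,
    subject_seeds: Sequence[int] | None = None,
) -> StrategyComparison:
    """Full strategy comparison at the per-subject optimal size k*.

    For each subject the effect curve is annealed, k* selected at
    ``fraction`` of the full effect, and every strategy evaluated at k*.
    The random baseline is summarized as mean +/- sd over ``n_random``
    draws.  Set ``propagation_runs=None`` to skip the SIR evaluation and
    compare on the EC surrogate only.
    """
    rows: list[dict] = []
    curves: list[EffectCurve] = []
    optimal_plans: list[ResectionPlan] = []
    strategy_plans: list[dict[str, ResectionPlan]] = []
    used_betas: list[float] = []
    for s_idx, subject in enumerate(cohort):
        conn, ez = _conn_ez(subject)
        cand = candidate_edges(conn, ez)
        if not cand:
            warnings.warn(f"subject {s_idx}: empty candidate set, skipped")
            continue
        if subject_seeds is not None:
            s_rng = np.random.default_rng(
                np.random.SeedSequence([int(subject_seeds[s_idx])])
            )
        else:
            s_rng = rng
        curve = effect_curve(conn, ez, sa_params, s_rng, effect_fraction=fraction)
        k_star = curve.k_star
        opt = curve.k_star_plan
        bundle = centrality_suite(conn)
        plans: dict[str, ResectionPlan] = {"optimal": opt}
        for strat in _METRIC_STRATEGIES:
            plans[strat] = strategy_select(
                conn, ez, k_star, strat, candidates=cand, bundle=bundle
            )
        random_plans = strategy_select(
            conn, ez, k_star, "random", s_rng, candidates=cand, n_random=n_random
        )
        ec_random = np.array(
            [p.effect.ec_diff_normalized for p in random_plans]
        )
        row: dict[str, Any] = {
            "subject": s_idx,
            "K": len(cand),
            "k_star": k_star,
            "spared_fraction": curve.spared_fraction,
            "seed_ec": seed_ec(conn, ez),
            "ec_optimal": opt.effect.ec_diff_normalized,
            "ec_full": 1.0,
            "ec_random_mean": float(ec_random.mean()),
            "ec_random_sd": float(ec_random.std(ddof=1)),
        }
        for strat in _METRIC_STRATEGIES:
            row[f"ec_{strat}"] = plans[strat].effect.ec_diff_normalized

        if propagation_runs is not None:
            if betas is not None:
                beta = float(betas[s_idx])
            else:
                beta = calibrate_beta(
                    conn, ez, gamma=gamma, n_runs=calibration_runs, rng=s_rng
                ).beta
            used_betas.append(beta)
            params = SIRParameters(
                beta=beta, gamma=gamma, t_max=max(t0, 1), n_runs=propagation_runs,
                t0=t0,
            )
            def _i_t0(edges: tuple) -> float:
                cut = ConnectomeMatrix(
                    remove_edges(conn.values, edges) if edges else conn.values,
                    labels=conn.labels, is_binary=True,
                )
                return sir_ensemble(cut, ez, params, s_rng).I_t0

            i_intact = _i_t0(())
            i_full = _i_t0(tuple(cand))
            denom = i_intact - i_full

            def _prop(plan: ResectionPlan) -> float:
                return (i_intact - _i_t0(plan.edges)) / denom

            i_t0_post = _i_t0(opt.edges)
            row["prop_optimal"] = (i_intact - i_t0_post) / denom
            row["prop_full"] = 1.0
            prop_random = np.array([_prop(p) for p in random_plans])
            row["prop_random_mean"] = float(prop_random.mean())
            row["prop_random_sd"] = float(prop_random.std(ddof=1))
            for strat in _METRIC_STRATEGIES:
                row[f"prop_{strat}"] = _prop(plans[strat])
            row["i_t0_pre"] = i_intact
            row["i_t0_post_optimal"] = i_t0_post

        rows.append(row)
        curves.append(curve)
        optimal_plans.append(opt)
        strategy_plans.append(plans)
    if not rows:
        raise StatisticsError("no subject had a non-empty candidate set")
    table = pd.DataFrame(rows)
    tests = _paired_tests(table, "ec")
    if propagation_runs is not None:
        tests += _paired_tests(table, "prop")
    return StrategyComparison(
        table=table,
        tests=pd.DataFrame(tests),
        curves=tuple(curves),
        optimal_plans=tuple(optimal_plans),
        strategy_plans=tuple(strategy_plans),
        betas=tuple(used_betas),
    )


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spared_removed_stats(
    cohort: Sequence, optimal_plans: Sequence[ResectionPlan]
) -> pd.DataFrame:
    """Do removed candidate connections differ from spared ones?

    Pools every subject's candidate edges, labelled removed (in the
    optimal plan) or spared, and compares edge betweenness and the
    non-seed endpoint's EC, degree and betweenness between the two groups
    with unpaired t-tests, Benjamini-Hochberg corrected across the four
    measures.
    """
    records = []
    for subject, plan in zip(cohort, optimal_plans):
        conn, ez = _conn_ez(subject)
        bundle = centrality_suite(conn)
        removed = set(plan.edges)
        for i, j in candidate_edges(conn, ez):
            records.append(
                {
                    "removed": (i, j) in removed,
                    "edge_bc": bundle.edge_bc[(min(i, j), max(i, j))],
                    "neighbor_ec": float(bundle.ec[j]),
                    "neighbor_degree": float(bundle.degree[j]),
                    "neighbor_bc": float(bundle.node_bc[j]),
                }
            )
    df = pd.DataFrame(records)
    spared = df[~df["removed"]]
    removed_df = df[df["removed"]]
    if len(spared) < 2 or len(removed_df) < 2:
        raise StatisticsError(
            f"need >= 2 edges per group, got {len(spared)} spared / "
            f"{len(removed_df)} removed"
        )
    rows = []
    for measure in ("edge_bc", "neighbor_ec", "neighbor_degree", "neighbor_bc"):
        res = stats.ttest_ind(spared[measure], removed_df[measure])
        ci = res.confidence_interval(0.95)
        rows.append(
            {
                "measure": measure,
                "mean_spared": float(spared[measure].mean()),
                "mean_removed": float(removed_df[measure].mean()),
                "t": float(res.statistic),
                "df": len(spared) + len(removed_df) - 2,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
                "p": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


def group_compare(
    comparison: StrategyComparison,
    labels: Sequence[int],
    location: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Compare two outcome groups (e.g. seizure-free vs not) on the
    pre-resection propagation I(t0), the seed EC, and the post-optimal
    I(t0); optionally a chi-square test on a binary location label.
    """
    table = comparison.table
    y = np.asarray(labels)
    if len(y) != len(table):
        raise ParameterError("one label per subject required")
    g0 = table[y == 0]
    g1 = table[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise StatisticsError("each outcome group needs at least 2 subjects")
    cols = ["seed_ec"]
    for c in ("i_t0_pre", "i_t0_post_optimal"):
        if c in table.columns:
            cols.append(c)
    rows = []
    for col in cols:
        t, p = stats.ttest_ind(g0[col], g1[col])
        rows.append(
            {
                "measure": col,
                "test": "t",
                "statistic": float(t),
                "df": len(table) - 2,
                "p": float(p),
            }
        )
    if location is not None:
        crosstab = pd.crosstab(np.asarray(location), y)
        chi2, p, dof, _ = stats.chi2_contingency(crosstab, correction=False)
        rows.append(
            {
                "measure": "location",
                "test": "chi2",
                "statistic": float(chi2),
                "df": int(dof),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline

_VALID_KEYS = {
    "output_dir", "master_seed", "density", "fraction", "n_random",
    "cohort", "inputs", "sir", "calibration", "sa",
    "validate_surrogate", "surrogate_runs", "propagation_runs",
    "group_labels", "location_labels",
}
_VALID_SIR_KEYS = {"gamma", "t0"}
_VALID_CAL_KEYS = {"step", "criterion", "beta_start", "beta_max", "n_runs"}


def _check_keys(d: dict, valid: set[str], section: str) -> None:
    unknown = set(d) - valid
    if unknown:
        raise ConfigError(
            f"unknown {section} key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(valid)}"
        )


def _load_subjects(config: dict, density: float) -> list:
    if "cohort" in config:
        spec_kwargs = dict(config["cohort"])
        spec_kwargs.setdefault("density", density)
        spec_kwargs.setdefault("master_seed", config.get("master_seed", 0))
        if "ez_size_range" in spec_kwargs:
            spec_kwargs["ez_size_range"] = tuple(spec_kwargs["ez_size_range"])
        valid = {f.name for f in fields(CohortSpec)}
        _check_keys(spec_kwargs, valid, "cohort")
        return generate_cohort(CohortSpec(**spec_kwargs))
    inputs = config["inputs"]
    _check_keys(inputs, {"matrices", "ez", "labels"}, "inputs")
    labels = inputs.get("labels")
    subjects = []
    for path, ez_nodes in zip(inputs["matrices"], inputs["ez"], strict=True):
        conn = read_connectome(path, labels_path=labels)
        if not conn.is_binary:
            conn = threshold_to_density(conn, density, binarize=True)
        subjects.append((conn, SeedSet(tuple(ez_nodes))))
    return subjects


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the whole virtual-resection workflow from a structured config.

    ``config`` is a YAML file path or an equivalent dict specifying either
    a synthetic ``cohort`` spec or ``inputs`` (matrix paths + EZ node
    lists), plus the tunables; everything defaults to the study values
    (density 0.11, gamma 0.03, calibration step 0.001 / criterion 0.98,
    effect fraction 0.9).  Writes tables (TSV), summaries (JSON) and a run
    manifest into ``output_dir`` and returns the result objects.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    _check_keys(config, _VALID_KEYS, "config")
    if "cohort" not in config and "inputs" not in config:
        raise ConfigError("config needs either a 'cohort' or an 'inputs' section")
    sir_cfg = dict(config.get("sir", {}))
    _check_keys(sir_cfg, _VALID_SIR_KEYS, "sir")
    cal_cfg = dict(config.get("calibration", {}))
    _check_keys(cal_cfg, _VALID_CAL_KEYS, "calibration")
    sa_cfg = dict(config.get("sa", {}))
    _check_keys(sa_cfg, {f.name for f in fields(SAParams)}, "sa")

    density = float(config.get("density", 0.11))
    if not 0 < density <= 1:
        raise ParameterError(f"density must be in (0, 1], got {density}")
    fraction = float(config.get("fraction", 0.9))
    master_seed = int(config.get("master_seed", 0))
    gamma = float(sir_cfg.get("gamma", 0.03))
    t0 = int(sir_cfg.get("t0", 10))
    sa_params = SAParams(**sa_cfg)

    subjects = _load_subjects(config, density)
    n = len(subjects)
    subject_seeds = [
        int(
            np.random.SeedSequence([master_seed, 1_000_000 + i]).generate_state(1)[0]
            % (2**31)
        )
        for i in range(n)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 7]))

    betas = [
        calibrate_beta(
            *_conn_ez(s),
            gamma=gamma,
            step=float(cal_cfg.get("step", 0.001)),
            criterion=float(cal_cfg.get("criterion", 0.98)),
            beta_start=float(cal_cfg.get("beta_start", 0.001)),
            beta_max=float(cal_cfg.get("beta_max", 1.0)),
            n_runs=int(cal_cfg.get("n_runs", 1000)),
            rng=np.random.default_rng(np.random.SeedSequence([seed_i, 1])),
        ).beta
        for s, seed_i in zip(subjects, subject_seeds)
    ]

    comparison = compare_strategies(
        subjects,
        rng,
        sa_params=sa_params,
        fraction=fraction,
        n_random=int(config.get("n_random", 100)),
        gamma=gamma,
        t0=t0,
        propagation_runs=config.get("propagation_runs", 2000),
        betas=betas,
        subject_seeds=subject_seeds,
    )
    results: dict[str, Any] = {"comparison": comparison, "betas": betas}

    if config.get("validate_surrogate", False):
        results["surrogate"] = validate_surrogate(
            subjects,
            np.random.default_rng(np.random.SeedSequence([master_seed, 11])),
            gamma=gamma,
            t0=t0,
            n_runs=int(config.get("surrogate_runs", 1000)),
            betas=betas,
        )
    results["spared_removed"] = spared_removed_stats(
        subjects, comparison.optimal_plans
    )
    if config.get("group_labels") is not None:
        results["groups"] = group_compare(
            comparison,
            config["group_labels"],
            location=config.get("location_labels"),
        )

    out = Path(output_dir or config.get("output_dir", "virtres_output"))
    _write_outputs(out, config, results, subject_seeds)
    return results


def _curve_record(curve: EffectCurve) -> dict:
    return {
        "sizes": list(curve.sizes),
        "best_ec_diff": list(curve.best_ec_diff),
        "normalized": list(curve.normalized),
        "k_star": curve.k_star,
        "effect_fraction": curve.effect_fraction,
        "spared_fraction": curve.spared_fraction,
    }


def _write_outputs(
    out: Path, config: dict, results: dict, subject_seeds: list[int]
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    comparison: StrategyComparison = results["comparison"]
    comparison.table.to_csv(out / "strategy_comparison.tsv", sep="\t", index=False)
    comparison.tests.to_csv(out / "strategy_tests.tsv", sep="\t", index=False)
    results["spared_removed"].to_csv(out / "spared_removed.tsv", sep="\t", index=False)
    if "surrogate" in results:
        sv: SurrogateValidation = results["surrogate"]
        sv.pairs.to_csv(out / "surrogate_pairs.tsv", sep="\t", index=False)
        (out / "surrogate.json").write_text(
            json.dumps(
                {
                    "per_subject_r": list(sv.per_subject_r),
                    "pooled_r": sv.pooled_r,
                    "betas": list(sv.betas),
                },
                indent=2,
            )
        )
    if "groups" in results:
        results["groups"].to_csv(out / "group_compare.tsv", sep="\t", index=False)
    with open(out / "plans.tsv", "w") as fh:
        fh.write("subject\tstrategy\tk\tnode_i\tnode_j\n")
        for s_idx, plans in enumerate(comparison.strategy_plans):
            for strat, plan in sorted(plans.items()):
                for i, j in plan.edges:
                    fh.write(f"{s_idx}\t{strat}\t{plan.k}\t{i}\t{j}\n")
    curves = {
        str(i): _curve_record(c) for i, c in enumerate(comparison.curves)
    }
    (out / "effect_curves.json").write_text(json.dumps(curves, indent=2))
    manifest = {
        "config": _jsonable(config),
        "subject_seeds": subject_seeds,
        "betas": list(results["betas"]),
        "package": "virtres 0.1.0",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
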