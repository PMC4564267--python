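"""Calibration and recovery experiments run entirely on synthetic data.

These routines back the package's validation claims: null calibration of the
meta p-values, BH false-discovery control, hyperparameter recovery for the
variance prior, and end-to-end recovery of planted cross-disease genes with
clustering of same-disease study pairs.  Every experiment takes one base seed
and derives per-replicate seeds from it.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .diffexpr import de_analysis, estimate_hyperparams
from .io import CASE, CONTROL, ExpressionDataset
from .meta import run_meta
from .pipeline import PipelineParams, analyze_collection
from .similarity import first_merges_are
from .simulate import SimConfig, default_config, generate_collection


def _spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def same_disease_pairs(study_to_disease: Mapping[str, str]) -> list[tuple[str, str]]:
    by_disease: dict[str, list[str]] = {}
    for sid, d in study_to_disease.items():
        by_disease.setdefault(d, []).append(sid)
    return [tuple(sorted(studies)) for studies in by_disease.values() if len(studies) == 2]


def recovery_replicate(
    seed: int,
    config: SimConfig | None = None,
    params: PipelineParams | None = None,
    min_diseases: int = 3,
) -> dict:
    """One synthetic collection end-to-end; returns recovery and clustering metrics."""
    config = replace(config or default_config(), seed=int(seed))
    params = params or PipelineParams()
    coll = generate_collection(config)
    probe_maps = {sid: coll.probe_map_for(sid) for sid in coll.datasets}
    result = analyze_collection(coll.datasets, probe_maps, coll.study_to_disease, params)

    union = set(result.common.index)
    truth_common = coll.truth.common_genes(min_diseases)
    tp = len(union & truth_common)
    sensitivity = tp / len(truth_common) if truth_common else float("nan")
    fdp = (len(union) - tp) / max(len(union), 1)
    pairs = same_disease_pairs(coll.study_to_disease)
    clustered = {
        m: first_merges_are(dend, pairs) for m, dend in result.dendrograms.items()
    }
    dead_retained = len(
        set(result.filtered[next(iter(result.filtered))].features)
        & coll.truth.dead_genes()
    )
    return {
        "seed": int(seed),
        "n_retained": result.filter_report.n_retained,
        "union_size": len(union),
        "sensitivity": sensitivity,
        "fdp": fdp,
        "dead_genes_retained": dead_retained,
        **{f"same_disease_first_{m}": bool(v) for m, v in clustered.items()},
    }


def run_recovery(
    n_replicates: int,
    base_seed: int,
    config: SimConfig | None = None,
    params: PipelineParams | None = None,
    min_diseases: int = 3,
) -> pd.DataFrame:
    seeds = _spawn_seeds(base_seed, n_replicates)
    return pd.DataFrame(
        [recovery_replicate(s, config, params, min_diseases) for s in seeds]
    )


def null_meta_calibration(
    n_genes: int = 10_000, k: int = 6, seed: int = 0
) -> dict[str, float]:
    """KS distance to Uniform(0,1) of Fisher and max-P meta p-values under the null."""
    rng = np.random.default_rng(seed)
    tables = {
        f"S{i}": pd.DataFrame(
            {"p": rng.uniform(size=n_genes)},
            index=[f"G{j}" for j in range(n_genes)],
        )
        for i in range(k)
    }
    meta = run_meta(tables)
    return {
        "fisher_ks": float(kstest(meta["fisher_p"], "uniform").statistic),
        "maxp_ks": float(kstest(meta["maxp_p"], "uniform").statistic),
    }


def _two_group_dataset(
    rng: np.random.Generator,
    n_genes: int,
    n_case: int,
    n_control: int,
    d0: float,
    s02: float,
    effect_idx: np.ndarray,
    delta: float,
) -> ExpressionDataset:
    sigma = np.sqrt(s02 * d0 / rng.chisquare(d0, size=n_genes))
    x = 8.0 + sigma[:, None] * rng.standard_normal((n_genes, n_case + n_control))
    x[effect_idx, :n_case] += (delta * sigma[effect_idx])[:, None]
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    values = pd.DataFrame(x, index=[f"G{i:05d}" for i in range(n_genes)], columns=samples)
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    return ExpressionDataset("sim", "D", values, groups)


def fdr_calibration(
    n_replicates: int = 50,
    seed: int = 0,
    n_genes: int = 2000,
    frac_de: float = 0.10,
    delta: float = 2.0,
    n_case: int = 16,
    n_control: int = 16,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Realized false-discovery proportion of BH at ``alpha`` on moderated-t p-values.

    Each replicate is a single two-group study with ``frac_de`` genes shifted
    by ``delta`` sigma; FDP = (false rejections)/(rejections, or 1 if none).
    """
    seeds = _spawn_seeds(seed, n_replicates)
    fdps, any_false = [], []
    n_de = int(frac_de * n_genes)
    for s in seeds:
        rng = np.random.default_rng(int(s))
        effect_idx = np.arange(n_de)
        ds = _two_group_dataset(rng, n_genes, n_case, n_control, 4.0, 0.05, effect_idx, delta)
        de = de_analysis(ds)
        rejected = de.index[de["p_adj"] < alpha]
        truth = {f"G{i:05d}" for i in effect_idx}
        v = len([g for g in rejected if g not in truth])
        fdps.append(v / max(len(rejected), 1))
        any_false.append(v > 0)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "rate_any_false": float(np.mean(any_false)),
        "n_replicates": n_replicates,
    }


def global_null_rejection_fraction(
    n_replicates: int = 20,
    seed: int = 0,
    n_genes: int = 2000,
    n_case: int = 16,
    n_control: int = 16,
    alpha: float = 0.05,
) -> float:
    """Mean fraction of genes with BH-adjusted p < alpha when no effects exist."""
    seeds = _spawn_seeds(seed, n_replicates)
    fractions = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        ds = _two_group_dataset(
            rng, n_genes, n_case, n_control, 4.0, 0.05, np.array([], dtype=int), 0.0
        )
        de = de_analysis(ds)
        fractions.append(float((de["p_adj"] < alpha).mean()))
    return float(np.mean(fractions))


def hyperparam_recovery(
    n_genes: int = 5000,
    d0: float = 4.0,
    s02: float = 0.05,
    residual_df: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Simulate the hierarchical variance model and re-estimate (d0, s0^2).

    True gene variances follow the scaled inverse-chi-square prior
    s0^2 d0 / chi2_{d0}; observed pooled variances are sigma^2 chi2_d / d.
    """
    rng = np.random.default_rng(seed)
    sigma2 = s02 * d0 / rng.chisquare(d0, size=n_genes)
    s2 = sigma2 * rng.chisquare(residual_df, size=n_genes) / residual_df
    summaries = pd.DataFrame(
        {
            "mean_diff": 0.0,
            "s2": s2,
            "df": float(residual_df),
            "v": 0.1,
        },
        index=[f"G{i}" for i in range(n_genes)],
    )
    est = estimate_hyperparams(summaries)
    return {
        "d0_hat": est.d0,
        "s02_hat": est.s02,
        "d0_rel_error": abs(est.d0 - d0) / d0,
        "s02_rel_error": abs(est.s02 - s02) / s02,
    }
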