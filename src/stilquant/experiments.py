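"""Simulation experiments: recovery, calibration and power checks.

These functions are the workhorses behind the numbered analysis scripts
and the acceptance run: each generates its own synthetic data from an
explicit seed, runs the relevant part of the pipeline, and returns plain
numbers/data frames.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, score_tile
from .prognostic import compare_models, delong_test, split_cohort
from .simcohort import CohortSimConfig, SNPSpec, simulate_cohort
from .simtiles import TileSimConfig, render_tile
from .quantize import select_num_classes
from .assoc import snp_sweep
from .survival import cox_fit

MAX_SEED = 2**31 - 1


def _spawn(seed: int, n: int) -> np.ndarray:
    """Independent child seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, MAX_SEED, size=n)


# ---------------------------------------------------------------------------
# imaging


def stil_recovery(
    n_tiles: int = 50,
    stil_range: tuple[float, float] = (5.0, 60.0),
    tile_size: int = 512,
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Score tiles with true sTIL gridded over ``stil_range`` and compare
    against ground truth (expert/ground-truth tumor mask mode)."""
    targets = np.linspace(stil_range[0], stil_range[1], n_tiles)
    seeds = _spawn(seed, n_tiles)
    rows = []
    for i, (target, s) in enumerate(zip(targets, seeds)):
        tile, gt = render_tile(
            TileSimConfig(height=tile_size, width=tile_size, target_stil_percent=float(target)),
            seed=int(s),
        )
        score = score_tile(
            tile,
            tumor_mask=gt.tumor_region,
            tumor_mask_source="ground_truth",
            config=config,
            seed=int(s),
            tile_id=f"tile{i:03d}",
        )
        rows.append(
            {
                "tile": f"tile{i:03d}",
                "target": float(target),
                "true_stil": gt.true_stil_percent,
                "estimated_stil": score.result.stil_percent,
                "K": score.K,
                "n_lymphocytes_true": gt.n_lymphocytes,
                "n_lymphocytes_detected": len(score.lymphocytes),
            }
        )
    df = pd.DataFrame(rows)
    df["abs_error"] = (df.estimated_stil - df.true_stil).abs()
    return df


def dunn_k_selection(
    n_seeds: int = 20, tile_size: int = 256, seed: int = 0
) -> pd.DataFrame:
    """Selected class count on default four-prototype tiles, one per seed."""
    rows = []
    for s in _spawn(seed, n_seeds):
        tile, _ = render_tile(TileSimConfig(height=tile_size, width=tile_size), seed=int(s))
        K, _scheme = select_num_classes(tile, seed=int(s))
        rows.append({"seed": int(s), "K": K})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association statistics


def null_cohort_config(n_patients: int = 969) -> CohortSimConfig:
    """Cohort generator with every genotype effect (sTIL shift and hazard)
    set to zero; clinical covariate effects are retained."""
    cfg = CohortSimConfig(n_patients=n_patients)
    cfg.snps = {
        name: replace(spec, stil_shift=0.0, log_hr=0.0) for name, spec in cfg.snps.items()
    }
    return cfg


def kw_null_calibration(
    n_reps: int = 1000, n_patients: int = 969, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Per-SNP Kruskal-Wallis rejection rate under the null generator."""
    cfg = null_cohort_config(n_patients)
    snps = list(cfg.snps)
    rejections = 0
    total = 0
    for s in _spawn(seed, n_reps):
        sim = simulate_cohort(cfg, seed=int(s))
        sweep = snp_sweep(sim.table, snps, alpha=alpha)
        rejections += len(sweep.significant)
        total += len(sweep.results)
    return {"rejection_rate": rejections / total, "n_tests": total, "alpha": alpha}


def kw_power(
    n_reps: int = 100,
    n_patients: int = 969,
    shift: float = 5.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rate for one SNP with an additive sTIL shift."""
    cfg = null_cohort_config(n_patients)
    target = next(iter(cfg.snps))
    cfg.snps[target] = replace(cfg.snps[target], stil_shift=shift)
    hits = 0
    for s in _spawn(seed, n_reps):
        sim = simulate_cohort(cfg, seed=int(s))
        sweep = snp_sweep(sim.table, [target], alpha=alpha)
        hits += target in sweep.significant
    return {"power": hits / n_reps, "snp": target, "shift": shift}


def stil_shift_recovery(
    n_patients: int = 10_000, shift: float = 5.0, noise_sd: float = 1.0, seed: int = 0
) -> dict:
    """Recover the generator's genotype->sTIL shift from group means."""
    cfg = CohortSimConfig(n_patients=n_patients, stil_sd=noise_sd)
    cfg.snps = {"snpA": SNPSpec(("A", "B"), maf=0.4, stil_shift=shift)}
    sim = simulate_cohort(cfg, seed=seed)
    df = sim.table
    means = df.groupby("snpA")["stil"].mean()
    est = means["A/B"] - means["A/A"]
    return {"true_shift": shift, "estimated_shift": float(est)}


# ---------------------------------------------------------------------------
# survival model calibration


def cox_null_calibration(
    n_reps: int = 2000, n: int = 300, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Wald-test rejection rate for a covariate independent of survival."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        t = rng.exponential(900.0, size=n)
        c = rng.uniform(180.0, 2900.0, size=n)
        df = pd.DataFrame(
            {"dfs_time": np.minimum(t, c), "dfs_event": (t <= c).astype(int), "x": x}
        )
        fit = cox_fit(df, covariates=["x"])
        rejections += fit.p[0] < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def cox_recovery(
    n_reps: int = 200, n: int = 1000, true_loghr: float = 0.5, seed: int = 0
) -> dict:
    """Bias and 95% CI coverage of the Cox log-HR in a two-group
    exponential simulation."""
    rng = np.random.default_rng(seed)
    estimates = []
    covered = 0
    for _ in range(n_reps):
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (1e-3 * np.exp(true_loghr * x)))
        c = rng.uniform(100.0, 3000.0, size=n)
        df = pd.DataFrame(
            {"dfs_time": np.minimum(t, c), "dfs_event": (t <= c).astype(int), "x": x.astype(float)}
        )
        fit = cox_fit(df, covariates=["x"])
        estimates.append(fit.coef[0])
        lo, hi = fit.coef[0] - 1.96 * fit.se[0], fit.coef[0] + 1.96 * fit.se[0]
        covered += lo <= true_loghr <= hi
    estimates = np.asarray(estimates)
    return {
        "true_loghr": true_loghr,
        "mean_estimate": float(estimates.mean()),
        "bias": float(estimates.mean() - true_loghr),
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# prognostic model experiments


DEFAULT_PROGNOSIS_SNPS = ("rs1801131", "rs25487", "rs8030672")


def model_comparison_power(
    n_reps: int = 100, n_patients: int = 969, seed: int = 0
) -> dict:
    """Fraction of replicates where the combined model (clinical + sTIL +
    SNPs) beats the clinical-only model on test-set AUC, under the
    generator's default (nonzero) sTIL and SNP effects."""
    wins = 0
    aucs = []
    for s in _spawn(seed, n_reps):
        sim = simulate_cohort(CohortSimConfig(n_patients=n_patients), seed=int(s))
        cmp = compare_models(sim.table, snp_columns=DEFAULT_PROGNOSIS_SNPS, seed=int(s))
        wins += cmp.auc_combined > cmp.auc_clinical
        aucs.append((cmp.auc_combined, cmp.auc_clinical))
    aucs = np.asarray(aucs)
    return {
        "win_rate": wins / n_reps,
        "mean_auc_combined": float(aucs[:, 0].mean()),
        "mean_auc_clinical": float(aucs[:, 1].mean()),
        "n_reps": n_reps,
    }


def delong_null_calibration(
    n_reps: int = 500, n_patients: int = 969, alpha: float = 0.05, seed: int = 0
) -> dict:
    """DeLong rejection rate when the added covariates (sTIL, SNPs) carry
    no effect: the combined model differs from the clinical one only by
    noise covariates."""
    cfg = null_cohort_config(n_patients)
    cfg.beta_stil = 0.0
    rejections = 0
    for s in _spawn(seed, n_reps):
        sim = simulate_cohort(cfg, seed=int(s))
        cmp = compare_models(sim.table, snp_columns=DEFAULT_PROGNOSIS_SNPS, seed=int(s))
        rejections += cmp.delong_p < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
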