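"""Parameter-recovery and operating-characteristic studies.

These are the package's standard simulation experiments: they generate
data with :mod:`phenoseason.synthetic_data`, run the full extraction
pipeline, and score the results against the analytic ground truth.  They
back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import growth, inference, season, sem, senescence
from . import synthetic_data as synth
from . import trajectory
from .errors import PhenoseasonError


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2**31 - 1)


def extract_records(
    measurements: pd.DataFrame,
    candidates=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Measurements -> per-species phenology records (the full pipeline)."""
    series = trajectory.measurements_to_series(measurements, on_error="skip")
    by_species: Dict[str, list] = {}
    for s in series:
        by_species.setdefault(s.species_id, []).append(s)
    growth_rows, sen_rows = [], []
    for sid in sorted(by_species):
        group = by_species[sid]
        try:
            fit = growth.fit_species_growth(
                group, candidates=candidates, seed=seed
            )
            gp = fit.growth_params()
            growth_rows.append(
                {
                    "species_id": sid,
                    "peak_day": gp.peak_day,
                    "log_b": gp.log_b,
                    "season_start": gp.season_start,
                    "K_hat": fit.params["K"],
                }
            )
        except PhenoseasonError:
            pass
        try:
            sp = senescence.species_senescence(group)
            sen_rows.append(
                {
                    "species_id": sid,
                    "sen_date": sp.sen_date,
                    "sen_pace": sp.sen_pace,
                    "sen_shape": sp.sen_shape,
                    "season_end": sp.season_end,
                    "overwinters": sp.overwinters,
                }
            )
        except PhenoseasonError:
            pass
    return season.assemble(pd.DataFrame(growth_rows), pd.DataFrame(sen_rows))


def truth_phenology(truth_row) -> Dict[str, float]:
    """Analytic phenology vector implied by one species' true parameters."""
    m, s, theta = truth_row.m_true, truth_row.s_true, truth_row.theta_true

    def cross(q):
        return m + math.log(q ** (-1.0 / theta) - 1.0) / s

    t95, t50, t25, t05 = cross(0.95), cross(0.5), cross(0.25), cross(0.05)
    start = truth_row.a_true - math.log(3.0) / truth_row.b_true
    return {
        "peak_day": truth_row.a_true,
        "log_b": math.log(truth_row.b_true),
        "season_start": start,
        "sen_date": t50,
        "sen_pace": 1.0 / (t05 - t95),
        "sen_shape": math.log((t05 - t50) / (t50 - t95)),
        "season_end": t25,
        "season_length": t25 - start,
        "t05": t05,
    }


def recovery_study(
    n_species: int = 20,
    seed: int = 42,
    noise_cv: float = 0.05,
    cadence_days: int = 14,
    candidates=None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Recover phenology from a noisy campaign; score against truth.

    Returns (records, errors): the pipeline's phenology records and a
    per-species error table.  Crossings that fall beyond the observation
    span (very shallow declines) leave their dependent errors missing, as
    they do in the pipeline itself.
    """
    cfg = synth.GenerationConfig(
        n_species=n_species,
        noise_cv=noise_cv,
        cadence_days=cadence_days,
        rng_seed=seed,
    )
    measurements, _, truth = synth.simulate_dataset(cfg)
    records = extract_records(measurements, candidates=candidates, seed=seed)
    merged = records.merge(truth, on="species_id")
    last_day = cfg.sample_days()[-1]
    rows = []
    for _, row in merged.iterrows():
        true = truth_phenology(row)
        pace_ok = true["t05"] < last_day
        rows.append(
            {
                "species_id": row["species_id"],
                "peak_day_err": row["peak_day"] - true["peak_day"],
                "log_b_err": row["log_b"] - true["log_b"],
                "k_rel_err": abs(row["K_hat"] - row["K_true"]) / row["K_true"],
                "sen_date_err": row["sen_date"] - true["sen_date"]
                if pd.notna(row["sen_date"])
                else np.nan,
                "pace_rel_err": (row["sen_pace"] - true["sen_pace"])
                / true["sen_pace"]
                if pace_ok and pd.notna(row["sen_pace"])
                else np.nan,
                "shape_err": row["sen_shape"] - true["sen_shape"]
                if pace_ok and pd.notna(row["sen_shape"])
                else np.nan,
                "season_length_err": row["season_length"]
                - true["season_length"]
                if pd.notna(row["season_length"])
                else np.nan,
            }
        )
    return records, pd.DataFrame(rows)


def recovery_summary(errors: pd.DataFrame) -> Dict[str, float]:
    return {
        "peak_day_rmse": float(
            np.sqrt(np.nanmean(errors["peak_day_err"] ** 2))
        ),
        "log_b_rmse": float(np.sqrt(np.nanmean(errors["log_b_err"] ** 2))),
        "k_rel_err_median": float(np.nanmedian(errors["k_rel_err"])),
        "sen_date_abs_err_median": float(
            np.nanmedian(np.abs(errors["sen_date_err"]))
        ),
        "pace_rel_err_median": float(
            np.nanmedian(np.abs(errors["pace_rel_err"]))
        ),
        "shape_abs_err_median": float(
            np.nanmedian(np.abs(errors["shape_err"]))
        ),
        "season_length_abs_err_median": float(
            np.nanmedian(np.abs(errors["season_length_err"]))
        ),
    }


def zero_noise_study(seed: int = 5) -> pd.DataFrame:
    """Noiseless daily-sampled species: errors against analytic truth."""
    cfg = synth.GenerationConfig(
        n_species=3,
        cadence_days=1,
        first_day=1,
        noise_cv=0.0,
        shoot_k_cv=0.0,
        shoots_per_species=2,
        rng_seed=seed,
    )
    truths = synth.generate_species(cfg)
    for theta, t in zip([0.5, 1.0, 2.0], truths):
        t.theta_true = theta
    measurements = synth.render_measurements(
        truths, cfg, np.random.default_rng(_sub_seed(seed, 1))
    )
    records = extract_records(
        measurements, candidates=growth.BASIC_CANDIDATES, seed=seed
    )
    merged = records.merge(synth.truth_frame(truths), on="species_id")
    rows = []
    for _, row in merged.iterrows():
        true = truth_phenology(row)
        rows.append(
            {
                "species_id": row["species_id"],
                "peak_day_err": abs(row["peak_day"] - true["peak_day"]),
                "b_rel_err": abs(
                    math.exp(row["log_b"]) / math.exp(true["log_b"]) - 1.0
                ),
                "start_err": abs(row["season_start"] - true["season_start"]),
                "sen_date_err": abs(row["sen_date"] - true["sen_date"]),
                "end_err": abs(row["season_end"] - true["season_end"]),
                "pace_rel_err": abs(row["sen_pace"] / true["sen_pace"] - 1.0)
                if true["t05"] < 365 and pd.notna(row["sen_pace"])
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SEM operating characteristics
# ---------------------------------------------------------------------------


def _chain_data(n, rng, direct=0.0, beta=0.6):
    x = rng.normal(size=n)
    m = beta * x + math.sqrt(1 - beta**2) * rng.normal(size=n)
    resid = math.sqrt(max(1 - beta**2 - direct**2, 0.05))
    y = beta * m + direct * x + resid * rng.normal(size=n)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


def _chain_spec():
    return sem.SEMSpec(
        nodes={"X": "niche", "M": "trait", "Y": "phenology"},
        directed_edges=[("X", "M"), ("M", "Y")],
    )


def sem_type1_study(
    n: int = 200, reps: int = 100, seed: int = 0
) -> Dict[str, float]:
    """Fit/refine the generating chain DAG on its own data.

    Under the true structure the global p must be uniform and refinement
    should add nothing.
    """
    p_globals, zero_additions = [], 0
    for k in range(reps):
        rng = np.random.default_rng(_sub_seed(seed, k))
        data = _chain_data(n, rng)
        fit = sem.fit_local(_chain_spec(), data)
        p_globals.append(fit.p_global)
        _, _, audit = sem.refine(_chain_spec(), data)
        zero_additions += not any(
            a["action"].startswith("add") for a in audit
        )
    ks_p = float(stats.kstest(p_globals, "uniform").pvalue)
    return {
        "p_global_ks_pvalue": ks_p,
        "zero_addition_rate": zero_additions / reps,
        "p_globals": p_globals,
    }


def sem_power_study(
    n: int = 200, reps: int = 100, seed: int = 0, direct: float = 0.5
) -> float:
    """Rate at which an omitted direct path is the first edge added."""
    first_hits = 0
    for k in range(reps):
        rng = np.random.default_rng(_sub_seed(seed, 10_000 + k))
        data = _chain_data(n, rng, direct=direct)
        _, _, audit = sem.refine(_chain_spec(), data)
        additions = [a for a in audit if a["action"] == "add_edge"]
        first_hits += bool(additions) and additions[0]["pair"] == ("X", "Y")
    return first_hits / reps


def sem_sign_agreement_study(
    n_species: int = 200, reps: int = 50, seed: int = 0
) -> float:
    """Sign agreement of fitted paths with the generating cascade.

    The SEM nodes are the generator's niche scores, traits and curve
    parameters; its edges are exactly the nonzero default path-matrix
    coefficients.
    """
    pm = synth.PathMatrices.default()
    nodes = {}
    edges, signs = [], {}
    for trait, row in pm.trait_from_niche.items():
        nodes[trait] = "trait"
        for niche_var, coef in row.items():
            nodes[niche_var] = "niche"
            edges.append((niche_var, trait))
            signs[(niche_var, trait)] = math.copysign(1.0, coef)
    for param, row in pm.pheno_from.items():
        nodes[param] = "phenology"
        for var, coef in row.items():
            if var not in nodes:
                nodes[var] = "niche" if var in synth.NICHE_VARS else "trait"
            edges.append((var, param))
            signs[(var, param)] = math.copysign(1.0, coef)
    spec = sem.SEMSpec(nodes=nodes, directed_edges=edges)
    agree = total = 0
    for k in range(reps):
        cfg = synth.GenerationConfig(
            n_species=n_species, rng_seed=_sub_seed(seed, 20_000 + k)
        )
        frame = synth.truth_frame(synth.generate_species(cfg))
        fit = sem.fit_local(spec, frame)
        for _, row in fit.path_coefficients.iterrows():
            expected = signs[(row["source"], row["target"])]
            agree += math.copysign(1.0, row["estimate"]) == expected
            total += 1
    return agree / total


# ---------------------------------------------------------------------------
# multimodel-inference operating characteristics
# ---------------------------------------------------------------------------


def importance_study(
    n: int = 200,
    reps: int = 100,
    seed: int = 0,
    beta: float = 0.5,
    n_predictors: int = 5,
) -> Dict[str, float]:
    """Mean relative importance of a single true predictor vs pure nulls."""
    names = [f"x{i}" for i in range(n_predictors)]
    signal_rows, noise_rows = [], []
    for k in range(reps):
        rng = np.random.default_rng(_sub_seed(seed, 30_000 + k))
        X = rng.normal(size=(n, n_predictors))
        for collector, b0 in ((signal_rows, beta), (noise_rows, 0.0)):
            y = b0 * X[:, 0] + rng.normal(size=n)
            df = pd.DataFrame(X, columns=names)
            df["y"] = y
            out = inference.average_effects(
                inference.all_subsets("y", names, df)
            ).set_index("predictor")["importance"]
            collector.append(out)
    signal = pd.concat(signal_rows, axis=1).mean(axis=1)
    noise = pd.concat(noise_rows, axis=1).mean(axis=1)
    return {
        "true_predictor_mean_importance": float(signal["x0"]),
        "max_null_mean_importance": float(signal.drop("x0").max()),
        "max_pure_noise_mean_importance": float(noise.max()),
    }
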