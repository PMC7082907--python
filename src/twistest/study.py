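"""Power study engine and multi-variant screening with FDR control.

``run_power_study`` estimates rejection rates of the TWIST and the TLRT
over a grid of simulation scenarios (one seed stream per replicate, so
results are reproducible regardless of execution order).
``screen_variants`` applies the TWIST variant-by-variant to a subjects x
variants genotype matrix, filters on minor allele frequency, and selects
associations by Benjamini-Hochberg false-discovery-rate control.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import Dataset, DatasetError, dataset_from_arrays, orient_alleles
from .simulate import Scenario, calibrate_censoring, generate_dataset
from .tlrt import tlrt_test
from .twist import twist_test

__all__ = ["run_power_study", "bh_fdr", "screen_variants", "estimate_power"]

logger = logging.getLogger("twistest")


def estimate_power(
    scenario: Scenario, *, level: float | None = None, tests: Sequence[str] = ("twist", "tlrt")
) -> dict:
    """Rejection rates of the requested tests under one scenario.

    Runs ``scenario.replications`` replicates, each with its own seed
    stream ``seed + replicate index``; rejection is strict (``p < level``).
    Returns a dict row with rates and Monte-Carlo standard errors.
    """
    level = scenario.level if level is None else level
    bound = calibrate_censoring(scenario)
    reject = {t: 0 for t in tests}
    reps = scenario.replications
    for rep in range(reps):
        data = generate_dataset(scenario, scenario.seed + rep, censor_bound=bound)
        if "twist" in tests:
            reject["twist"] += twist_test(data).p_value < level
        if "tlrt" in tests:
            reject["tlrt"] += tlrt_test(data).p_value < level
    row = {
        "label": scenario.label,
        "n": scenario.n,
        "replications": reps,
        "maf": scenario.maf,
        "preimmune_rate": scenario.preimmune_rate,
        "beta": scenario.beta,
        "alpha1": scenario.alpha1,
        "alpha2": scenario.alpha2,
        "gamma1": scenario.gamma1,
        "gamma2": scenario.gamma2,
        "tail": scenario.tail,
        "censoring": scenario.censoring,
        "level": level,
        "censor_bound": np.nan if bound is None else bound,
        "seed": scenario.seed,
    }
    for t in tests:
        p = reject[t] / reps
        row[f"power_{t}"] = p
        row[f"se_{t}"] = float(np.sqrt(p * (1.0 - p) / reps))
    return row


def run_power_study(
    scenarios: Iterable[Scenario], *, level: float | None = None
) -> pd.DataFrame:
    """Tidy power table over a scenario grid (one row per scenario)."""
    rows = []
    for scenario in scenarios:
        logger.info("scenario %s: seed=%d", scenario.label or "?", scenario.seed)
        rows.append(estimate_power(scenario, level=level))
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-adjusted)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_variants(
    genotypes: np.ndarray | pd.DataFrame,
    phenotypes: Dataset | pd.DataFrame,
    *,
    maf_min: float = 0.15,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """TWIST screen of a subjects x variants genotype matrix.

    Each variant is allele-oriented, kept only if its minor allele
    frequency exceeds ``maf_min`` (strictly), tested with the TWIST, and
    the retained variants are selected at FDR level ``fdr`` by
    Benjamini-Hochberg.  Returns one row per retained variant with the
    two score parts, the statistic, p, q and the selection flag.
    """
    if isinstance(genotypes, pd.DataFrame):
        variant_ids = [str(c) for c in genotypes.columns]
        geno = genotypes.to_numpy()
    else:
        geno = np.asarray(genotypes)
        variant_ids = [f"v{j}" for j in range(geno.shape[1])]
    if isinstance(phenotypes, pd.DataFrame):
        time = phenotypes["time"].to_numpy()
        event = phenotypes["event"].to_numpy()
        pre = phenotypes["pre_immune"].to_numpy()
    else:
        time, event, pre = phenotypes.time, phenotypes.event, phenotypes.pre_immune
    if geno.shape[0] != time.shape[0]:
        raise DatasetError(
            f"genotype matrix has {geno.shape[0]} subjects but phenotype "
            f"table has {time.shape[0]}"
        )

    rows = []
    n_filtered = 0
    for j, vid in enumerate(variant_ids):
        counts, maf = orient_alleles(geno[:, j])
        if not maf > maf_min:
            n_filtered += 1
            continue
        data = dataset_from_arrays(time, event, pre, counts)
        res = twist_test(data)
        rows.append(
            {
                "variant_id": vid,
                "maf": maf,
                "n": data.n,
                "n_preimmune": data.n_preimmune,
                "n_events": data.n_events,
                "S1": res.s1,
                "S2": res.s2,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "flags": ";".join(res.flags),
            }
        )
    logger.info("screen: %d variants below MAF %.2f excluded", n_filtered, maf_min)
    if not rows:
        import warnings

        warnings.warn("all variants fell below the MAF threshold", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "variant_id", "maf", "n", "n_preimmune", "n_events",
                "S1", "S2", "statistic", "df", "p_value", "flags",
                "q_value", "selected",
            ]
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table["selected"] = table["q_value"] <= fdr
    return table
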