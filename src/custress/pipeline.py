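"""Orchestration: simulate -> effect sizes -> classic tests -> calls -> signal.

`run_pipeline` takes a validated replicate table (and optionally a
phylogeny) and produces the full analysis bundle as data frames, writing
each as a tidy CSV plus a JSON run log holding the configuration, the
master seed and the package version. All randomness flows from the one
master seed in the config; per-stage streams are derived by stable hashing
so results do not depend on evaluation order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .classic import anova_tukey, pearson_ci
from .effects import EffectSize, bootstrap_ci, compare_es
from .io import RunConfig, write_replicate_table
from .patterns import classify_pattern, classify_strategy, panel_medians
from .physignal import perm_test_k
from .simulate import (
    ExperimentDesign,
    generate_isolate_panel,
    generate_phylogeny,
    simulate_experiment,
)

logger = logging.getLogger("custress")

__all__ = ["run_pipeline", "simulate_run", "stable_seed"]

RESPONSES = ("biomass_g", "cu_mg_per_g")


def stable_seed(master: int, *tags) -> int:
    """Derive an independent substream seed from the master seed and tags."""
    key = "|".join([str(master), *map(str, tags)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "little") % (2**63)


def simulate_run(config: RunConfig):
    """Build the design, panel, replicate table and phylogeny for a config."""
    ids = tuple(f"iso{i:02d}" for i in range(1, config.n_isolates + 1))
    design = ExperimentDesign(
        isolate_ids=ids,
        n_replicates=config.n_replicates,
        pre_incubation_days=config.pre_incubation_days,
        treatment_days=config.treatment_days,
        final_conc=config.final_conc,
        step_day=config.step_day,
    )
    panel = generate_isolate_panel(
        len(ids),
        preset_mix=config.preset_mix,
        seed=stable_seed(config.seed, "panel"),
        noise_sigma=config.noise_sigma,
    )
    table = simulate_experiment(design, panel, seed=stable_seed(config.seed, "experiment"))
    tree, _ = generate_phylogeny(
        ids, seed=stable_seed(config.seed, "tree") % (2**31), trait_mode=config.trait_mode
    )
    return design, panel, table, tree


def _arm_values(table: pd.DataFrame, isolate: str, treatment: str, response: str) -> np.ndarray:
    mask = (table["isolate"] == isolate) & (table["treatment"] == treatment)
    return table.loc[mask, response].to_numpy(dtype=float)


def _effect_tables(table: pd.DataFrame, config: RunConfig):
    """Wide per-isolate ES summary (one row per isolate x response)."""
    rows = []
    es_store: dict[tuple[str, str, str], EffectSize] = {}
    contrast_store = {}
    isolates = list(dict.fromkeys(table["isolate"]))
    for iso in isolates:
        for response in RESPONSES:
            control = _arm_values(table, iso, "control", response)
            gradual = _arm_values(table, iso, "gradual", response)
            abrupt = _arm_values(table, iso, "abrupt", response)
            es_g = bootstrap_ci(
                gradual, control, n_boot=config.n_boot, alpha=config.alpha,
                seed=stable_seed(config.seed, "es", iso, response, "gradual"),
            )
            es_a = bootstrap_ci(
                abrupt, control, n_boot=config.n_boot, alpha=config.alpha,
                seed=stable_seed(config.seed, "es", iso, response, "abrupt"),
            )
            ctr = compare_es(
                gradual, abrupt, control, n_boot=config.n_boot, alpha=config.alpha,
                seed=stable_seed(config.seed, "contrast", iso, response),
            )
            es_store[(iso, response, "gradual")] = es_g
            es_store[(iso, response, "abrupt")] = es_a
            contrast_store[(iso, response)] = ctr
            rows.append(
                dict(
                    isolate=iso, response=response,
                    es_gradual=es_g.point, es_gradual_ci_lo=es_g.ci_low,
                    es_gradual_ci_hi=es_g.ci_high,
                    es_abrupt=es_a.point, es_abrupt_ci_lo=es_a.ci_low,
                    es_abrupt_ci_hi=es_a.ci_high,
                    delta=ctr.delta, delta_ci_lo=ctr.ci_low, delta_ci_hi=ctr.ci_high,
                    p_boot=ctr.p_boot,
                )
            )
    return pd.DataFrame(rows), es_store, contrast_store


def _tukey_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for iso in dict.fromkeys(table["isolate"]):
        for response in RESPONSES:
            groups = {
                arm: _arm_values(table, iso, arm, response)
                for arm in ("control", "gradual", "abrupt")
            }
            res = anova_tukey(groups)
            for pair in res.pairs:
                rows.append(
                    dict(
                        isolate=iso, response=response,
                        group_a=pair.group_a, group_b=pair.group_b,
                        diff=pair.diff, se=pair.se, q=pair.q, p_adj=pair.p_adj,
                        df_error=res.df_error,
                    )
                )
    return pd.DataFrame(rows)


def _correlation_table(table: pd.DataFrame, es_summary: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Isolate-mean correlations mirroring the report's scatter panels."""
    means = table.groupby(["isolate", "treatment"])["biomass_g"].mean().unstack()
    bio = es_summary[es_summary["response"] == "biomass_g"].set_index("isolate")
    cu = es_summary[es_summary["response"] == "cu_mg_per_g"].set_index("isolate")
    control_biomass = means["control"].reindex(bio.index)

    rows = []

    def add(name: str, x, y) -> None:
        res = pearson_ci(np.asarray(x, float), np.asarray(y, float), alpha=alpha)
        rows.append(
            dict(name=name, r=res.r, p=res.p, ci_low=res.ci_low,
                 ci_high=res.ci_high, n=res.n)
        )

    for arm in ("gradual", "abrupt"):
        add(f"es_biomass_vs_control_biomass[{arm}]", control_biomass, bio[f"es_{arm}"])
    add("delta_es_biomass_vs_control_biomass", control_biomass, bio["delta"])
    for arm in ("gradual", "abrupt"):
        add(f"es_biomass_vs_es_copper[{arm}]", bio[f"es_{arm}"], cu[f"es_{arm}"])
    return pd.DataFrame(rows)


def _call_table(es_store, contrast_store, isolates, alpha: float) -> pd.DataFrame:
    med = {
        arm: panel_medians(
            [es_store[(i, "biomass_g", arm)] for i in isolates],
            [es_store[(i, "cu_mg_per_g", arm)] for i in isolates],
        )
        for arm in ("gradual", "abrupt")
    }
    rows = []
    for iso in isolates:
        pattern = classify_pattern(
            es_store[(iso, "biomass_g", "gradual")],
            es_store[(iso, "biomass_g", "abrupt")],
            contrast_store[(iso, "biomass_g")],
            alpha=alpha,
        )
        strategies = {
            arm: classify_strategy(
                es_store[(iso, "biomass_g", arm)],
                es_store[(iso, "cu_mg_per_g", arm)],
                med[arm],
            )
            for arm in ("gradual", "abrupt")
        }
        rows.append(
            dict(
                isolate=iso,
                pattern=pattern.label,
                strategy_gradual=strategies["gradual"].label,
                strategy_abrupt=strategies["abrupt"].label,
                alpha=alpha,
            )
        )
    return pd.DataFrame(rows)


def _phylosignal_table(
    table: pd.DataFrame, tree: dendropy.Tree, config: RunConfig
) -> pd.DataFrame:
    rows = []
    for response in RESPONSES:
        means = table.groupby(["isolate", "treatment"])[response].mean().unstack()
        for arm in ("control", "gradual", "abrupt"):
            traits: Mapping[str, float] = means[arm].to_dict()
            res = perm_test_k(
                tree, traits, n_perm=config.n_perm,
                seed=stable_seed(config.seed, "physig", response, arm),
            )
            rows.append(
                dict(response=response, treatment=arm, k=res.k,
                     p_perm=res.p_perm, n_perm=res.n_perm)
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    table: pd.DataFrame,
    tree: dendropy.Tree | None = None,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis on a replicate table; write the report bundle.

    Returns the bundle as a dict of data frames keyed by output name. When
    ``tree`` is None the phylogenetic-signal stage is skipped with a
    logged notice. Two runs with the same config, table and tree produce
    byte-identical outputs.
    """
    outdir = Path(config.outdir if outdir is None else outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    es_summary, es_store, contrast_store = _effect_tables(table, config)
    isolates = list(dict.fromkeys(table["isolate"]))
    bundle: dict[str, pd.DataFrame] = {
        "es_summary": es_summary,
        "tukey": _tukey_table(table),
        "correlations": _correlation_table(table, es_summary, config.alpha),
        "calls": _call_table(es_store, contrast_store, isolates, config.alpha),
    }
    if tree is not None:
        bundle["phylosignal"] = _phylosignal_table(table, tree, config)
    else:
        logger.info("no phylogeny supplied; phylogenetic-signal stage skipped")

    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    write_replicate_table(table, outdir / "replicates.csv")

    log = {
        "package": "custress",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_rows": int(len(table)),
        "n_isolates": len(isolates),
        "phylosignal_run": tree is not None,
        "note": "no multiplicity correction is applied across isolates",
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    _write_report(bundle, outdir / "report.txt")
    return bundle


def _write_report(bundle: dict[str, pd.DataFrame], path: Path) -> None:
    """Small human-readable summary with display rounding."""
    lines = ["custress report", "=" * 40]
    calls = bundle["calls"]
    counts = calls["pattern"].value_counts()
    lines.append("reaction patterns:")
    lines += [f"  {label}: {int(counts.get(label, 0))}" for label in
              ("no_effect", "uniform_reduction", "gradual_worse", "abrupt_worse")]
    lines.append("")
    lines.append("correlations (isolate means):")
    for _, row in bundle["correlations"].iterrows():
        lines.append(
            f"  {row['name']}: r={row['r']:.3f} p={row['p']:.2e} "
            f"CI[{row['ci_low']:.3f}, {row['ci_high']:.3f}] n={int(row['n'])}"
        )
    if "phylosignal" in bundle:
        lines.append("")
        lines.append("phylogenetic signal (Blomberg's K):")
        for _, row in bundle["phylosignal"].iterrows():
            lines.append(
                f"  {row['response']} [{row['treatment']}]: K={row['k']:.3f} "
                f"p={row['p_perm']:.3f}"
            )
    lines.append("")
    lines.append("note: per-isolate p-values are not multiplicity-corrected")
    path.write_text("\n".join(lines) + "\n")
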