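"""Self-calibration experiments for the statistical machinery.

Because the original wet-lab measurements are not redistributable, the
package validates itself operationally: type-I error of the bootstrap
contrast under a three-arm null, coverage of the percentile CI, recovery
of the generator's reaction-pattern presets by the classifier, Brownian
calibration of Blomberg's K, integrator accuracy against the logistic
closed form, and agreement of the Tukey/Fisher-z machinery with
Monte-Carlo and closed-form oracles. Each function runs the experiment
from scratch and returns the measured quantity.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .classic import anova_tukey, pearson_ci
from .effects import bootstrap_ci, compare_es
from .patterns import classify_pattern
from .physignal import blomberg_k, perm_test_k
from .pipeline import stable_seed
from .schedules import build_control_schedule
from .simulate import (
    ExperimentDesign,
    IsolateParams,
    generate_isolate_panel,
    generate_phylogeny,
    simulate_brownian_traits,
    simulate_experiment,
    simulate_replicate,
    design_schedules,
)

__all__ = [
    "null_contrast_rejection_rate",
    "bootstrap_ci_coverage",
    "pattern_recovery",
    "bm_k_calibration",
    "perm_test_type_one_error",
    "logistic_oracle_max_rel_err",
    "dose_rate_inequalities_hold",
    "tukey_vs_mc_oracle",
    "fisherz_vs_closed_form",
]


def null_contrast_rejection_rate(
    n_isolates: int = 1000,
    n_per_arm: int = 5,
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of three-arm i.i.d.-normal null isolates with p_boot < alpha."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for i in range(n_isolates):
        g, a, c = rng.normal(0.0, 1.0, (3, n_per_arm))
        ctr = compare_es(g, a, c, n_boot=n_boot, seed=stable_seed(seed, "null", i))
        rejected += ctr.p_boot < alpha
    return rejected / n_isolates


def bootstrap_ci_coverage(
    n_sims: int = 1000,
    n_per_arm: int = 30,
    n_boot: int = 1999,
    alpha: float = 0.05,
    mean_diff: float = 1.0,
    seed: int = 0,
) -> float:
    """Fraction of normal simulations whose percentile CI covers the truth."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_sims):
        treated = rng.normal(mean_diff, 1.0, n_per_arm)
        control = rng.normal(0.0, 1.0, n_per_arm)
        es = bootstrap_ci(
            treated, control, n_boot=n_boot, alpha=alpha,
            seed=stable_seed(seed, "cover", i),
        )
        hits += es.ci_low <= mean_diff <= es.ci_high
    return hits / n_sims


def pattern_recovery(
    preset: str,
    n_isolates: int = 40,
    noise_sigma: float = 0.05,
    alpha: float = 0.05,
    n_boot_ci: int = 1999,
    n_boot_contrast: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Label frequencies when classifying a single-preset panel end to end.

    Simulates the default design over ``n_isolates`` isolates all drawn
    from one preset region, runs the bootstrap effect-size machinery and
    the ordered decision rule per isolate, and returns the fraction of
    isolates assigned each label.
    """
    panel = generate_isolate_panel(
        n_isolates, preset_mix={preset: 1.0},
        seed=stable_seed(seed, "panel", preset), noise_sigma=noise_sigma,
    )
    design = ExperimentDesign(
        isolate_ids=tuple(f"p{i:03d}" for i in range(n_isolates))
    )
    table = simulate_experiment(design, panel, seed=stable_seed(seed, "exp", preset))
    counts = {label: 0 for label in
              ("no_effect", "uniform_reduction", "gradual_worse", "abrupt_worse")}
    for iso in design.isolate_ids:
        sub = table[table["isolate"] == iso]
        arms = {
            arm: sub.loc[sub["treatment"] == arm, "biomass_g"].to_numpy()
            for arm in ("control", "gradual", "abrupt")
        }
        es_g = bootstrap_ci(arms["gradual"], arms["control"], n_boot=n_boot_ci,
                            alpha=alpha, seed=stable_seed(seed, iso, "g"))
        es_a = bootstrap_ci(arms["abrupt"], arms["control"], n_boot=n_boot_ci,
                            alpha=alpha, seed=stable_seed(seed, iso, "a"))
        ctr = compare_es(arms["gradual"], arms["abrupt"], arms["control"],
                         n_boot=n_boot_contrast, alpha=alpha,
                         seed=stable_seed(seed, iso, "d"))
        counts[classify_pattern(es_g, es_a, ctr, alpha=alpha).label] += 1
    return {k: v / n_isolates for k, v in counts.items()}


def bm_k_calibration(n_sims: int = 500, n_tips: int = 32, seed: int = 0) -> float:
    """Mean Blomberg's K over Brownian traits on one fixed Yule tree.

    Under the generating model E(K) = 1, so the mean should sit near 1.
    """
    tree, _ = generate_phylogeny(
        [f"t{i:02d}" for i in range(n_tips)], seed=stable_seed(seed, "ktree") % (2**31),
    )
    ks = [
        blomberg_k(tree, simulate_brownian_traits(tree, seed=stable_seed(seed, "bm", i)))
        for i in range(n_sims)
    ]
    return float(np.mean(ks))


def perm_test_type_one_error(
    n_datasets: int = 500,
    n_tips: int = 32,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the K permutation test on signal-free traits."""
    tree, _ = generate_phylogeny(
        [f"t{i:02d}" for i in range(n_tips)], seed=stable_seed(seed, "ktree") % (2**31),
    )
    labels = [lf.taxon.label for lf in tree.leaf_nodes()]
    rng = np.random.default_rng(stable_seed(seed, "iid"))
    rejected = 0
    for i in range(n_datasets):
        traits = dict(zip(labels, rng.standard_normal(n_tips)))
        res = perm_test_k(tree, traits, n_perm=n_perm, seed=stable_seed(seed, "perm", i))
        rejected += res.p_perm < alpha
    return rejected / n_datasets


def logistic_oracle_max_rel_err(seed: int = 0) -> float:
    """Worst relative error of the integrator vs the logistic closed form.

    Probed over growth regimes spanning saturated to purely exponential
    14-day control trajectories.
    """
    design = ExperimentDesign(isolate_ids=("x", "y", "z"))
    sched = build_control_schedule(design.treatment_days)
    worst = 0.0
    for r, k in ((0.8, 0.5), (1.2, 0.8), (0.4, 4.0), (1.0, 0.2), (0.5, 2.0)):
        params = IsolateParams(r_max=r, k_cap=k, ec50=1.0, noise_sigma=0.0)
        biomass, _ = simulate_replicate(params, sched, design, seed=0)
        t_total = design.pre_incubation_days + design.treatment_days
        exact = k / (1.0 + ((k - params.b0) / params.b0) * math.exp(-r * t_total))
        worst = max(worst, abs(biomass - exact) / exact)
    return worst


def dose_rate_inequalities_hold(n_draws: int = 20, seed: int = 0) -> bool:
    """Chronic-damage draws must order gradual <= abrupt biomass; shock
    draws must order abrupt <= gradual (noise off)."""
    rng = np.random.default_rng(seed)
    design = ExperimentDesign(isolate_ids=("x",))
    schedules = design_schedules(design)
    for _ in range(n_draws):
        common = dict(
            r_max=rng.uniform(0.4, 0.55), k_cap=rng.uniform(2.0, 4.0),
            ec50=rng.uniform(2.5, 4.0), noise_sigma=0.0,
        )
        chronic = IsolateParams(damage_rate=rng.uniform(0.15, 0.45), **common)
        bg, _ = simulate_replicate(chronic, schedules["gradual"], design, seed=0)
        ba, _ = simulate_replicate(chronic, schedules["abrupt"], design, seed=0)
        if bg > ba:
            return False
        shocky = IsolateParams(shock_sens=rng.uniform(1.0, 4.0), **common)
        bg, _ = simulate_replicate(shocky, schedules["gradual"], design, seed=0)
        ba, _ = simulate_replicate(shocky, schedules["abrupt"], design, seed=0)
        if ba > bg:
            return False
    return True


def tukey_vs_mc_oracle(
    n_mc: int = 1_000_000, seed: int = 0
) -> float:
    """Max |adjusted p - Monte-Carlo studentized-range p| on a seeded fixture.

    The oracle draws ``n_mc`` independent (range of k normals) / (pooled sd)
    statistics and reads the tail probability empirically.
    """
    rng = np.random.default_rng(seed)
    groups = {
        "control": rng.normal(2.0, 0.5, 5),
        "gradual": rng.normal(1.3, 0.5, 5),
        "abrupt": rng.normal(1.7, 0.5, 5),
    }
    res = anova_tukey(groups)
    k, df = res.k_groups, res.df_error
    oracle_rng = np.random.default_rng(stable_seed(seed, "mc"))
    z = oracle_rng.standard_normal((n_mc, k))
    ranges = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(oracle_rng.chisquare(df, n_mc) / df)
    q_mc = ranges / s
    worst = 0.0
    for pair in res.pairs:
        p_mc = float(np.mean(q_mc >= pair.q))
        worst = max(worst, abs(pair.p_adj - p_mc))
    return worst


def fisherz_vs_closed_form(seed: int = 0) -> float:
    """Max |CI endpoint - direct Fisher-z evaluation| on a seeded fixture."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in (10, 17, 40):
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        res = pearson_ci(x, y, alpha=0.05)
        z = math.atanh(res.r)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        worst = max(
            worst,
            abs(res.ci_low - math.tanh(z - half)),
            abs(res.ci_high - math.tanh(z + half)),
        )
    return worst
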