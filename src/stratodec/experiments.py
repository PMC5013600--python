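"""Validation experiments: pruning-vs-enumeration sweeps, nesting checks,
parameter recovery, model-selection power, constraint semantics and
simulator fidelity.

These drivers define the package's standard self-validation conditions
(problem sizes, replicate counts, seeds derive from a single argument)
and are shared by the test suite and the reproduction script.  Problem
sizes are kept at the smallest scale at which each property is
informative: exhaustive enumeration is exponential in tree size, and the
recovery/power experiments need enough tips (200) for the asymptotics of
ML to bite, but nothing forces large state spaces.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats

from .calibrations import normal_from_ci, truncated_cauchy
from .geography import Area, Geography, build_state_space
from .inference import ancestral_marginals, fit_ml
from .likelihood import PruningEngine, pruning_loglik
from .models import ModelSpec, build_clado_table, build_generator
from .reference import enumeration_loglik
from .simulate import _CladoSampler, _evolve_branch, make_songbird_fixture, simulate_history, simulate_tree
from .tree_io import read_newick

__all__ = [
    "toy_likelihoods",
    "oracle_sweep",
    "nesting_check",
    "parameter_recovery",
    "model_selection_power",
    "constraint_contrast",
    "simulator_fidelity",
    "calibration_summary",
]

_FAMILY_VARIANTS = [
    ("DEC", False),
    ("DEC", True),
    ("DIVALIKE", False),
    ("DIVALIKE", True),
    ("BAYAREALIKE", False),
    ("BAYAREALIKE", True),
]


def _areas(n: int) -> Geography:
    return Geography(areas=[Area(i, chr(ord("A") + i)) for i in range(n)])


def toy_likelihoods() -> dict:
    """Hand-enumerable two-tip DEC cases with d = e = 0.

    With no anagenetic events, a shared singleton tip pattern can only
    arise by sympatry from that singleton root (flat prior over the three
    nonempty two-area states gives likelihood 1/3); distinct singleton
    tips require a widespread root and the matching vicariance event,
    probability 1/6 among the six DEC events (likelihood 1/18).
    """
    tree = read_newick("(A:1,B:1);")
    geo = _areas(2)
    spec = ModelSpec(family="DEC", d=0.0, e=0.0)
    return {
        "same_singleton": float(np.exp(pruning_loglik(tree, {"A": 1, "B": 1}, spec, geo))),
        "split_singletons": float(np.exp(pruning_loglik(tree, {"A": 1, "B": 2}, spec, geo))),
    }


def oracle_sweep(seed: int = 0, n_param_draws: int = 5) -> dict:
    """Max |pruning - enumeration| log-likelihood deviation over a sweep of
    2- and 3-tip trees x 1-3 areas x all six model variants x seeded
    parameter draws."""
    rng = np.random.default_rng(seed)
    trees = [read_newick("(A:1.0,B:1.0);"), read_newick("((A:1.0,B:1.0):0.8,C:1.8);")]
    worst = 0.0
    n_cases = 0
    for tree, n_areas, (family, plus_j) in product(trees, (1, 2, 3), _FAMILY_VARIANTS):
        geo = _areas(n_areas)
        n_states_nonempty = (1 << n_areas) - 1
        for _ in range(n_param_draws):
            d = 10.0 ** rng.uniform(-2, 0)
            e = 10.0 ** rng.uniform(-2, -0.5)
            j = float(rng.uniform(0.0, 2.9)) if plus_j else 0.0
            spec = ModelSpec(family=family, plus_j=plus_j, d=d, e=e, j=j)
            tips = {
                lab: int(rng.integers(1, n_states_nonempty + 1)) for lab in tree.tip_labels
            }
            ll_prune = pruning_loglik(tree, tips, spec, geo)
            ll_enum = enumeration_loglik(tree, tips, spec, geo)
            worst = max(worst, abs(ll_prune - ll_enum))
            n_cases += 1
    return {"max_abs_diff": worst, "n_cases": n_cases}


def nesting_check(seed: int = 0, n_datasets: int = 20) -> dict:
    """Max |logL(family+j, j=0) - logL(family)| over seeded simulated
    datasets, for all three families.  Should be 0 to numerical noise."""
    rng = np.random.default_rng(seed)
    geo = _areas(3)
    worst = 0.0
    for k in range(n_datasets):
        family = ("DEC", "DIVALIKE", "BAYAREALIKE")[k % 3]
        tree = simulate_tree(20, 1.0, 0.0, seed=int(rng.integers(2**31)), root_age=5.0)
        gen = ModelSpec(family=family, d=0.1, e=0.02)
        hist = simulate_history(tree, gen, geo, seed=int(rng.integers(2**31)))
        d, e = 10.0 ** rng.uniform(-2, 0), 10.0 ** rng.uniform(-3, -1)
        eng = PruningEngine(tree, hist.tip_dict(), geo)
        base = eng.loglik(ModelSpec(family=family, d=d, e=e))
        plus = eng.loglik(ModelSpec(family=family, plus_j=True, d=d, e=e, j=0.0))
        worst = max(worst, abs(base - plus))
    return {"max_abs_diff": worst, "n_datasets": n_datasets}


# study conditions of the recovery / power experiments: pure-birth 200-tip
# trees rescaled to a 5-Myr crown depth, so d=0.1/Myr yields a few dispersal
# events per root-tip path while null-range absorption stays survivable
RECOVERY_N_TIPS = 200
RECOVERY_ROOT_AGE = 5.0
RECOVERY_D = 0.1
RECOVERY_E = 0.03


def _one_recovery_rep(seed_tree, seed_hist, seed_fit, spec, fit_plus_j=False, starts=3):
    geo = _areas(3)
    tree = simulate_tree(
        RECOVERY_N_TIPS, 1.0, 0.0, seed=seed_tree, root_age=RECOVERY_ROOT_AGE
    )
    hist = simulate_history(tree, spec, geo, seed=seed_hist, max_tries=5000)
    eng = PruningEngine(tree, hist.tip_dict(), geo)
    fits = {}
    fits["base"] = fit_ml(
        tree, hist.tip_dict(), spec.family, False, geo, starts=starts, seed=seed_fit,
        engine=eng,
    )
    if fit_plus_j:
        fits["plus_j"] = fit_ml(
            tree, hist.tip_dict(), spec.family, True, geo, starts=starts, seed=seed_fit,
            engine=eng,
        )
    return tree, hist, fits


def parameter_recovery(seed: int = 0, n_replicates: int = 20, starts: int = 3) -> dict:
    """DEC parameter recovery under the standard study conditions.

    Returns the fraction of replicates with d-hat (resp. e-hat) within
    +/-50% of truth, plus the per-replicate estimates.
    """
    spec = ModelSpec(family="DEC", d=RECOVERY_D, e=RECOVERY_E)
    d_ok = e_ok = 0
    estimates = []
    for rep in range(n_replicates):
        _, _, fits = _one_recovery_rep(
            seed * 1_000_003 + rep, seed * 7_000_003 + rep, seed + rep, spec, starts=starts
        )
        f = fits["base"].spec
        estimates.append({"d": f.d, "e": f.e})
        if abs(f.d - spec.d) <= 0.5 * spec.d:
            d_ok += 1
        if abs(f.e - spec.e) <= 0.5 * spec.e:
            e_ok += 1
    return {
        "d_within_50pct_rate": d_ok / n_replicates,
        "e_within_50pct_rate": e_ok / n_replicates,
        "n_replicates": n_replicates,
        "estimates": estimates,
        "truth": {"d": spec.d, "e": spec.e},
    }


def model_selection_power(seed: int = 0, n_replicates: int = 20, j: float = 1.5,
                          starts: int = 3) -> dict:
    """Fraction of DEC+j (j = 1.5) datasets for which AIC prefers the +j
    variant over nested DEC, under the standard study conditions."""
    spec = ModelSpec(family="DEC", plus_j=True, d=RECOVERY_D, e=RECOVERY_E, j=j)
    chosen = 0
    rows = []
    for rep in range(n_replicates):
        _, _, fits = _one_recovery_rep(
            seed * 11_000_003 + rep, seed * 13_000_003 + rep, seed + rep, spec,
            fit_plus_j=True, starts=starts,
        )
        aic_base, aic_j = fits["base"].aic, fits["plus_j"].aic
        rows.append({"aic_dec": aic_base, "aic_decj": aic_j, "j_hat": fits["plus_j"].spec.j})
        if aic_j < aic_base:
            chosen += 1
    return {"plus_j_selected_rate": chosen / n_replicates, "n_replicates": n_replicates,
            "replicates": rows}


def constraint_contrast(seed: int = 0, max_range_size: int = 3) -> dict:
    """Constrained vs naive ancestral ranges on the songbird-like fixture.

    At every node older than 15 Myr the constrained run must put exactly
    zero probability on New-Guinea-containing ranges; the naive run's mass
    there is therefore always >= the constrained run's.
    """
    tree, geo, dist_tips, _ = make_songbird_fixture(seed=seed, max_range_size=max_range_size)
    naive_geo = Geography(areas=geo.areas)
    spec = ModelSpec(family="DEC", plus_j=True, d=0.02, e=0.005, j=0.4)
    tips = dist_tips.as_dict()
    est_c = ancestral_marginals(tree, tips, spec, geo, max_range_size)
    est_n = ancestral_marginals(tree, tips, spec, naive_geo, max_range_size)
    space = build_state_space(9, max_range_size)
    ng = np.array([bool(bits & 1) for bits in space.states])
    old_c = [r for r, nid in enumerate(est_c.node_ids) if tree.ages[nid] > 15.0]
    ng_mass_c = est_c.probs[old_c][:, ng].sum(axis=1)
    ng_mass_n = est_n.probs[old_c][:, ng].sum(axis=1)
    return {
        "n_old_nodes": len(old_c),
        "max_constrained_ng_mass_old_nodes": float(ng_mass_c.max()),
        "max_naive_ng_mass_old_nodes": float(ng_mass_n.max()),
        "min_naive_minus_constrained": float((ng_mass_n - ng_mass_c).min()),
    }


def simulator_fidelity(seed: int = 0, n_draws: int = 10_000) -> dict:
    """Empirical checks of the forward simulator against theory.

    (1) cladogenetic event draws for a fixed widespread ancestor under
    DEC+j match the event table's probabilities within 3 binomial
    standard errors per event; (2) the sojourn time of a singleton state
    before its first anagenetic event is exponential with the generator's
    total exit rate (Kolmogorov-Smirnov test).
    """
    geo = _areas(3)
    space = build_state_space(3, None)
    rng = np.random.default_rng(seed)
    # (1) event-class / event frequencies for ancestor {A, B}
    table = build_clado_table(space, "DEC", True, 0.5, geo.strata[0])
    sampler = _CladoSampler(table)
    anc = space.index(0b011)
    left, right, cum, _ = sampler.by_anc[anc]
    probs = np.diff(np.concatenate([[0.0], cum]))
    counts = np.zeros(len(left))
    for _ in range(n_draws):
        l, r, _c = sampler.draw(anc, rng)
        for k in range(len(left)):
            if left[k] == l and right[k] == r:
                counts[k] += 1
                break
    se = np.sqrt(n_draws * probs * (1 - probs))
    max_z = float(np.max(np.abs(counts - n_draws * probs) / se))
    # (2) sojourn of singleton {A} under d=0.1, e=0.03: exit rate 2d + e
    d, e = 0.1, 0.03
    Qs = [build_generator(space, geo, geo.strata[0], d, e)]
    s_idx = space.index(0b001)
    exit_rate = -Qs[0][s_idx, s_idx]
    horizon = 60.0
    waits = []
    for _ in range(n_draws):
        _, evs = _evolve_branch(s_idx, 0.0, horizon, geo, Qs, space, rng)
        if evs:
            waits.append(horizon - evs[0][0])
    ks = stats.kstest(waits, "expon", args=(0.0, 1.0 / exit_rate))
    return {
        "n_draws": n_draws,
        "max_event_freq_z": max_z,
        "sojourn_ks_pvalue": float(ks.pvalue),
        "exit_rate": float(exit_rate),
        "n_uncensored_sojourns": len(waits),
    }


def calibration_summary() -> dict:
    """Worked calibration numbers: the secondary Normal calibrations built
    from their printed means and 95% CIs, and the fossil truncated-Cauchy
    calibration (minimum 24 Myr, offset 1.0, scale 5.0)."""
    cal1 = normal_from_ci(21.0, 17.0, 26.0)
    cal2 = normal_from_ci(28.0, 18.0, 38.0)
    tc = truncated_cauchy(24.0, 1.0, 5.0)
    grid_integral, _ = _integrate(tc.pdf, 24.0)
    return {
        "normal_21_sd": cal1.params["sd"],
        "normal_21_q025": float(cal1.quantile(0.025)),
        "normal_21_q975": float(cal1.quantile(0.975)),
        "normal_28_sd": cal2.params["sd"],
        "normal_28_q025": float(cal2.quantile(0.025)),
        "normal_28_q975": float(cal2.quantile(0.975)),
        "cauchy_mode": tc.params["mode"],
        "cauchy_integral": grid_integral,
        "cauchy_pdf_below_min": float(tc.pdf(23.9)),
        "cauchy_pdf_above_min": float(tc.pdf(24.1)),
    }


def _integrate(f, lo):
    from scipy.integrate import quad

    # the Cauchy tail is heavy (the mass above 1e6 Myr is ~4e-5), so the
    # normalization check must integrate the full semi-infinite support
    a, err_a = quad(f, lo, 500.0, limit=200)
    b, err_b = quad(f, 500.0, np.inf, limit=200)
    return a + b, err_a + err_b
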