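"""End-to-end analysis of one mesocosm experiment.

Chains the stages the way the study design dictates: rarefy water samples to
a common depth, Bray-Curtis, sequential PERMANOVA (burning, loading, time),
binary threshold scan at the first sampling day, NMDS with environmental
vector fitting, environment PC1 vs loading and vs NMDS1 with linear/piecewise
model selection, community-weighted genome traits, and early-vs-late
differential pathways.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import breakpoints as bp
from . import diversity, ordination, traits as tr
from .permanova import permanova as _permanova, threshold_scan as _threshold_scan
from .config import RunConfig
from .simulate import SyntheticExperiment
from .tables import CountTable


def _water_counts(exp: SyntheticExperiment) -> CountTable:
    frames = []
    for day, table in sorted(exp.counts_by_day.items()):
        ids = [s for s in table.sample_ids
               if exp.metadata.loc[s, "source"] == "water"]
        frames.append(table.data.loc[ids])
    return CountTable(pd.concat(frames, axis=0))


def analyze_experiment(exp: SyntheticExperiment,
                       cfg: RunConfig | None = None,
                       include_controls: bool = True) -> dict[str, Any]:
    """Run the full pipeline on a (synthetic or loaded) experiment."""
    cfg = cfg or RunConfig()
    rng_seed = cfg.rng_seed
    meta = exp.metadata

    water = _water_counts(exp)
    if not include_controls:
        keep = [s for s in water.sample_ids
                if meta.loc[s, "treatment"] != "control"]
        water = water.select_samples(keep)
    rare = diversity.rarefy(water, cfg.rarefaction_depth, seed=rng_seed)
    wmeta = meta.loc[rare.sample_ids]
    d_all = diversity.bray_curtis(rare)

    report: dict[str, Any] = {"n_water_samples": len(rare.sample_ids)}

    # --- variance partition: burning + loading + time --------------------
    terms = {
        "burning": wmeta["treatment"].astype(str).to_numpy(),
        "loading": wmeta["loading_g"].to_numpy(),
        "time": wmeta["day"].astype(str).to_numpy(),
    }
    if wmeta["treatment"].nunique() < 2:
        terms.pop("burning")
    if wmeta["day"].nunique() < 2:
        terms.pop("time")
    pm = _permanova(d_all, terms, n_perm=cfg.n_permutations,
                             seed=rng_seed)
    report["permanova"] = {
        "r_squared": pm.r_squared, "p_value": pm.p_value,
        "residual_r_squared": pm.residual_ss / pm.total_ss,
        "table": pm.to_table().to_dict(orient="records"),
    }

    days = sorted(wmeta["day"].unique())
    first_day, last_day = days[0], days[-1]
    first_ids = [s for s in rare.sample_ids
                 if wmeta.loc[s, "day"] == first_day]
    d_first = d_all.submatrix(first_ids)
    load_first = wmeta.loc[first_ids, "loading_g"].to_numpy()

    # --- threshold scan at the first day ---------------------------------
    scan = _threshold_scan(d_first, load_first,
                                    n_perm=cfg.n_permutations, seed=rng_seed)
    report["threshold_scan"] = {
        "best_threshold_g": scan.best_threshold,
        "best_r_squared": scan.best_r_squared,
        "best_p": scan.best_p,
        "profile": scan.profile().to_dict(orient="records"),
    }

    # --- ordination + envfit at the first day ----------------------------
    nm = ordination.nmds(d_first, k=cfg.ordination_dimensions, seed=rng_seed)
    nm = ordination.orient_axes(nm, load_first)
    env_first = exp.environment.loc[first_ids]
    ef = ordination.envfit(nm, env_first, n_perm=cfg.n_permutations,
                           seed=rng_seed)
    report["nmds"] = {"stress": nm.stress, "converged": nm.converged}
    report["envfit"] = ef.table.to_dict(orient="index")

    # --- breakpoint models per day ---------------------------------------
    report["breakpoints"] = {}
    for day in days:
        ids = [s for s in rare.sample_ids if wmeta.loc[s, "day"] == day]
        load = wmeta.loc[ids, "loading_g"].to_numpy()
        pc1 = bp.environment_pc1(exp.environment.loc[ids], orient_by=load)
        lin, pw, cmp_le = bp.select_breakpoint_model(
            load, pc1.to_numpy(), alpha=cfg.alpha_model_selection)
        d_day = d_all.submatrix(ids)
        nm_day = ordination.orient_axes(
            ordination.nmds(d_day, k=cfg.ordination_dimensions,
                            seed=rng_seed), load)
        nmds1 = nm_day.scores[:, 0]
        lin2, pw2, cmp_em = bp.select_breakpoint_model(
            pc1.to_numpy(), nmds1, alpha=cfg.alpha_model_selection)
        report["breakpoints"][int(day)] = {
            "loading_vs_environment": {
                "selected": cmp_le.selected, "f": cmp_le.f_statistic,
                "df": [cmp_le.df1, cmp_le.df2], "p": cmp_le.p_value,
                "breakpoint_g": pw.breakpoint_estimate,
                "slope_below": pw.slope_below, "slope_above": pw.slope_above,
            },
            "environment_vs_microbiome": {
                "selected": cmp_em.selected, "f": cmp_em.f_statistic,
                "p": cmp_em.p_value,
                "breakpoint": pw2.breakpoint_estimate,
            },
        }

    # --- community-weighted genome traits --------------------------------
    trait_tab = exp.traits.copy()
    trait_tab["growth_rate_per_h"] = tr.growth_rate_from_doubling_time(
        trait_tab["doubling_time_h"])
    trait_tab["plasticity"] = tr.relative_genomic_plasticity(
        exp.gene_dissimilarity, exp.proteome_dissimilarity)
    first_rare = rare.select_samples(first_ids)
    cwm = tr.community_weighted_traits(first_rare, trait_tab)
    rho_gs = _stats.spearmanr(load_first,
                              cwm.values["genome_size_bp"]).statistic
    rho_gr = _stats.spearmanr(load_first,
                              cwm.values["growth_rate_per_h"]).statistic
    report["traits"] = {
        "cwm_first_day": cwm.values.mean().to_dict(),
        "genome_size_loading_spearman": float(rho_gs),
        "growth_rate_loading_spearman": float(rho_gr),
    }

    # --- differential pathways early vs late -----------------------------
    filters = tr.PathwayFilters(cfg.pathway_p_threshold,
                                cfg.pathway_min_abs_log2fc,
                                cfg.pathway_min_taxa)
    n_member = exp.pathway_incidence.sum(axis=1)
    sig = {}
    for tag, day in (("early", first_day), ("late", last_day)):
        ids = [s for s in rare.sample_ids if wmeta.loc[s, "day"] == day]
        ab = tr.pathway_abundance(rare.select_samples(ids),
                                  exp.pathway_incidence)
        res = tr.differential_pathways(
            ab, wmeta.loc[ids, "loading_g"].to_numpy(), n_member,
            n_perm=cfg.n_permutations, seed=rng_seed, filters=filters)
        sig[tag] = set(res.significant())
    cats = tr.categorize_by_day(sig["early"], sig["late"])
    counts = cats["category"].value_counts()
    report["pathways"] = {
        "n_significant_early": len(sig["early"]),
        "n_significant_late": len(sig["late"]),
        "n_only_early": int(counts.get("only_early", 0)),
        "n_only_late": int(counts.get("only_late", 0)),
        "n_both": int(counts.get("both", 0)),
        "n_total": int(len(cats)),
    }

    # --- ground-truth recovery summary (synthetic runs) ------------------
    gt = exp.ground_truth
    report["ground_truth_recovery"] = {
        "true_threshold_g": gt["true_threshold_g"],
        "recovered_threshold_g": scan.best_threshold,
        "true_env_breakpoint_g": gt["env_breakpoint_g"],
        "recovered_env_breakpoint_g":
            report["breakpoints"][int(first_day)]
            ["loading_vs_environment"]["breakpoint_g"],
    }
    return report
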