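"""Dataset assembly and end-to-end orchestration.

Assembly follows the conventions of comparative neuron-count datasets:
individuals are averaged per species before the log10 transform,
endocranial volumes are converted to brain mass with the density of brain
tissue (1.036 g/cm^3), neuron densities are recomputed as neurons per gram
of structure, and every imputed or converted value carries a provenance
flag. The full analysis chains shift detection, the grade cascade, fold
changes, relative measures and rate comparisons into one seeded,
reproducible report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asr_rates, ou_shifts, pgls
from .phylo import Phylogeny, match_tree_to_table, parse_newick

__all__ = [
    "BRAIN_TISSUE_DENSITY",
    "AssembledDataset",
    "assemble_dataset",
    "impute_ob_striatum",
    "run_full_analysis",
]

#: g/cm^3; endocranial volume -> brain mass conversion factor
BRAIN_TISSUE_DENSITY = 1.036


# ----------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------

@dataclass
class AssembledDataset:
    """Species-averaged, log10-transformed traits matched to a tree."""

    traits: pd.DataFrame  # log10 columns, one row per species
    provenance: pd.DataFrame  # same shape: measured/converted/imputed
    tree: Phylogeny
    dropped_species: list
    dropped_tips: list


def assemble_dataset(
    table: pd.DataFrame,
    units: dict,
    tree: Phylogeny,
    log_before_average: bool = False,
) -> AssembledDataset:
    """Convert units, average individuals per species, log10-transform and
    match to the tree.

    ``units`` maps every trait column to one of ``"g"``, ``"cm3"``
    (endocranial volume, converted to g by the brain-tissue density) or
    ``"count"``; a column without a unit is a hard error. Averaging
    precedes the log transform by default (``log_before_average`` flips
    the convention). If both a ``<part>_neurons`` and ``<part>_mass``
    column exist alongside a ``<part>_density`` column, the density is
    recomputed as neurons per gram and cross-checked.
    """
    if "species" not in table.columns:
        raise ValueError("table needs a 'species' column")
    trait_cols = [c for c in table.columns if c != "species"]
    missing_units = [c for c in trait_cols if c not in units]
    if missing_units:
        raise ValueError(f"columns without units metadata: {missing_units}")
    bad = {c: u for c, u in units.items()
           if c in trait_cols and u not in ("g", "cm3", "count", "per_g")}
    if bad:
        raise ValueError(f"unknown units: {bad}")
    work = table.copy()
    prov_unit = {}
    for c in trait_cols:
        if units[c] == "cm3":
            work[c] = work[c] * BRAIN_TISSUE_DENSITY
            prov_unit[c] = "converted-from-volume"
        else:
            prov_unit[c] = "measured"
    if log_before_average:
        for c in trait_cols:
            work[c] = np.log10(work[c])
        sp = work.groupby("species")[trait_cols].mean()
    else:
        sp = np.log10(work.groupby("species")[trait_cols].mean())
    # density cross-check
    for c in trait_cols:
        if c.endswith("_density"):
            part = c[: -len("_density")]
            ncol, mcol = f"{part}_neurons", f"{part}_mass"
            if ncol in sp.columns and mcol in sp.columns:
                recomputed = sp[ncol] - sp[mcol]
                if not np.allclose(recomputed, sp[c], atol=1e-6):
                    warnings.warn(
                        f"provided {c} disagrees with {ncol}/{mcol}; "
                        "using the recomputed values",
                        stacklevel=2,
                    )
                sp[c] = recomputed
                prov_unit[c] = "recomputed"
    subtree, matched, drop_tab, drop_tre = match_tree_to_table(
        tree, list(sp.index)
    )
    sp = sp.loc[matched]
    prov = pd.DataFrame(
        {c: [prov_unit[c]] * len(sp) for c in trait_cols}, index=sp.index
    )
    return AssembledDataset(
        traits=sp, provenance=prov, tree=subtree,
        dropped_species=drop_tab, dropped_tips=drop_tre,
    )


def impute_ob_striatum(
    table: pd.DataFrame,
    ob_rules: dict | None = None,
    striatal_proportion: dict | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Fill missing olfactory-bulb values from clade allometries and move
    the striatum from the rest of brain into the telencephalon.

    Operates on natural-scale columns ``brain_mass``,
    ``telencephalon_mass``, ``telencephalon_neurons``, ``rest_mass``,
    ``rest_neurons`` and optionally ``ob_mass`` / ``ob_neurons``.

    * OB: where ``ob_mass``/``ob_neurons`` is missing and the species'
      group has a rule ``(intercept, slope)`` (log10 OB trait on log10
      brain mass), the value is imputed and *added to the telencephalon*
      (published mammalian telencephalic counts exclude it). Species with
      measured OB are untouched.
    * Striatum: striatal mass = brain mass x the group's mean striatal
      proportion; striatal neurons = striatal mass x the species' own
      telencephalic neuron density; both are added to the telencephalon
      and subtracted from the rest of brain.

    Species lacking both a rule and a proportion are left missing and
    flagged. Returns a copy with ``*_corrected`` columns and boolean audit
    flags; no silent edits.
    """
    out = table.copy()
    ob_rules = ob_rules or {}
    striatal_proportion = striatal_proportion or {}
    tel_m = out["telencephalon_mass"].astype(float).copy()
    tel_n = out["telencephalon_neurons"].astype(float).copy()
    rest_m = out["rest_mass"].astype(float).copy()
    rest_n = out["rest_neurons"].astype(float).copy()
    ob_imputed = pd.Series(False, index=out.index)
    striatum_moved = pd.Series(False, index=out.index)
    unresolved = pd.Series(False, index=out.index)
    for i in out.index:
        grp = out.at[i, group_col]
        brain = float(out.at[i, "brain_mass"])
        # -- olfactory bulb
        has_ob = (
            "ob_mass" in out.columns
            and np.isfinite(out.at[i, "ob_mass"])
        )
        if not has_ob:
            if grp in ob_rules:
                am, bm = ob_rules[grp]["ob_mass"]
                an, bn = ob_rules[grp]["ob_neurons"]
                obm = 10.0 ** (am + bm * np.log10(brain))
                obn = 10.0 ** (an + bn * np.log10(brain))
                tel_m.at[i] += obm
                tel_n.at[i] += obn
                ob_imputed.at[i] = True
            elif ob_rules:
                unresolved.at[i] = True
        # -- striatum reassignment
        if grp in striatal_proportion:
            smass = brain * striatal_proportion[grp]
            dens = tel_n.at[i] / tel_m.at[i]
            sneur = smass * dens
            tel_m.at[i] += smass
            tel_n.at[i] += sneur
            rest_m.at[i] -= smass
            rest_n.at[i] -= sneur
            striatum_moved.at[i] = True
        elif striatal_proportion:
            unresolved.at[i] = True
    out["telencephalon_mass_corrected"] = tel_m
    out["telencephalon_neurons_corrected"] = tel_n
    out["rest_mass_corrected"] = rest_m
    out["rest_neurons_corrected"] = rest_n
    out["ob_imputed"] = ob_imputed
    out["striatum_moved"] = striatum_moved
    out["imputation_unresolved"] = unresolved
    return out


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

_DEFAULTS = dict(
    n_iter=200_000,
    thin=100,
    burn_in=0.2,
    n_chains=4,
    pp_threshold=0.7,
    min_clade=4,
    alpha_level=0.05,
    n_sim_rates=1_000,
    seed=1,
)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv().encode()
    ).hexdigest()[:16]


def run_full_analysis(config: dict) -> dict:
    """Shift detection -> grade cascade -> fold changes -> relative
    measures -> rate comparison for each response/predictor pair.

    ``config`` names the tree (path or Phylogeny), the trait table (path
    or DataFrame, log10 columns, species index), ``pairs`` as a list of
    ``[response, predictor]`` column names, and any of the sampler /
    threshold settings (defaults: 4 chains x 200k iterations thin 100,
    burn-in 0.2, pp > 0.7, clades of > 3 species, alpha 0.05). The report
    is a pure function of (inputs, config, seed).
    """
    cfg = dict(_DEFAULTS)
    cfg.update({k: v for k, v in config.items()
                if k not in ("tree", "traits", "pairs")})
    if cfg["n_iter"] <= 0:
        raise ValueError("n_iter must be positive")
    if not config.get("pairs"):
        raise ValueError("config must name at least one (response, predictor) pair")
    tree = config["tree"]
    if not isinstance(tree, Phylogeny):
        with open(tree) as fh:
            tree = parse_newick(fh.read())
    traits = config["traits"]
    if not isinstance(traits, pd.DataFrame):
        traits = pd.read_csv(traits, sep=None, engine="python",
                             index_col="species")
    tree, matched, _, _ = match_tree_to_table(tree, list(traits.index))
    traits = traits.loc[tree.tip_labels]
    report = dict(
        config={k: v for k, v in cfg.items()},
        inputs=dict(n_species=len(matched), traits_hash=_hash_frame(traits)),
        analyses={},
    )
    for y_col, x_col in config["pairs"]:
        stage = f"{y_col}~{x_col}"
        try:
            res = _analyze_pair(tree, traits, y_col, x_col, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["analyses"][stage] = res
    return report


def _analyze_pair(tree, traits, y_col, x_col, cfg):
    x, y = traits[x_col], traits[y_col]
    chains = ou_shifts.rjmcmc_run(
        x, y, tree,
        n_iter=cfg["n_iter"], thin=cfg["thin"],
        burn_in_fraction=cfg["burn_in"], n_chains=cfg["n_chains"],
        seed=cfg["seed"],
    )
    summary = ou_shifts.summarize_shifts(
        chains, tree, pp_threshold=cfg["pp_threshold"],
        min_clade=cfg["min_clade"],
    )
    groups = summary.grade_labels(tree)
    if groups.nunique() > 1:
        model = pgls.merge_grades_cascade(
            x, y, tree, groups, ancestral="ancestral",
            alpha=cfg["alpha_level"],
        )
    else:
        model = pgls.fit_grade_model(x, y, groups, tree)
    lines = {g: model.line(g) for g in model.group_names}
    folds = {}
    pts = x.to_numpy(float)
    names = model.group_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            fc = pgls.fold_change(lines[names[i]], lines[names[j]], pts)
            folds[f"{names[i]}/{names[j]}"] = fc.fold
    relative = pgls.relative_measure(x, y, tree)
    rate_cmp = None
    final_groups = model.groups
    if final_groups.nunique() > 1 and final_groups.value_counts().min() >= 3:
        rc = asr_rates.compare_group_rates(
            tree, relative, final_groups,
            n_sim=cfg["n_sim_rates"], seed=cfg["seed"],
        )
        rate_cmp = dict(rates=rc.rates, ratio=rc.ratio, p=rc.p_value)
    return dict(
        accepted_shifts=[int(b) for b in summary.accepted],
        shift_pp={int(b): float(summary.pp[b]) for b in summary.accepted},
        converged=summary.converged,
        diagnostics={
            k: dict(rhat=float(v["rhat"]), ess=float(v["ess"]))
            for k, v in summary.diagnostics.items()
        },
        grades={g: dict(intercept=l[0], slope=l[1])
                for g, l in lines.items()},
        grade_members={
            g: sorted(final_groups.index[final_groups == g])
            for g in model.group_names
        },
        lambda_=float(model.fit.lam),
        fold_changes=folds,
        merge_audit=[
            dict(stage=m["stage"], merge=list(map(str, m["merge"])),
                 p=float(m["p"]), adopted=bool(m["adopted"]))
            for m in model.merges
        ],
        rate_comparison=rate_cmp,
        seed=cfg["seed"],
    )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
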