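"""End-to-end pipeline driver.

Sequences the analysis stages on either a synthetic cohort (generated
in-process) or a study directory written by :func:`stratnet.simulate.write_study`:

    ingest -> edge-wise association -> CPM predictions + similarity ->
    edge taxonomy + permutation reliability -> factor scores ->
    specificity -> longitudinal -> summary

All randomness flows from one root seed through named substreams, so a
rerun with the same config is byte-identical.  Per-stage tables are written
as TSV, the machine-readable roll-up as ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brain_behavior, factors, longitudinal, specificity
from .longitudinal import _partial_corr
from .simulate import (
    DOMAIN_OF,
    EXTERNALIZING_SYMPTOMS,
    INTERNALIZING_SYMPTOMS,
    SYMPTOMS,
    SimulationConfig,
    SyntheticStudy,
    generate_cohort,
    read_study,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML-loadable)."""

    out_dir: str = "stratnet_out"
    input_dir: str | None = None  # read a written study; None -> simulate
    simulation: dict = field(default_factory=dict)
    alpha: float = 0.05
    n_perm: int = 200
    k_folds: int = 10
    seed: int = 0
    complete_cases: bool = False
    fdr_mode: bool = False
    welch: bool = False
    covariate_columns: tuple[str, ...] = ("site", "sex", "age")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.covariate_columns = tuple(cfg.covariate_columns)
        return cfg


def _seed_streams(seed: int) -> dict[str, int]:
    """Named integer substreams (< 2**31) derived from the root seed."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "cv", "perm", "similarity")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def validate_inputs(config: PipelineConfig, study: SyntheticStudy) -> list[str]:
    """Cross-table consistency checks; returns the list of violations."""
    problems: list[str] = []
    wave1 = study.config.wave_labels[0]
    subjects = study._present(wave1)
    sym = study.symptoms_at(wave1)
    cov = study.covariates_at(wave1)
    if not sym.index.equals(subjects):
        problems.append("symptoms.tsv: subject ids misaligned with connectomes")
    if not cov.index.equals(subjects):
        problems.append("covariates.tsv: subject ids misaligned with connectomes")
    n_edges = {m.shape[1] for m in study.connectomes.values()}
    if len(n_edges) > 1:
        problems.append(
            f"connectome_*.tsv: inconsistent edge counts {sorted(n_edges)}"
        )
    elif n_edges and n_edges.pop() != study.parcellation.n_edges:
        problems.append("connectome_*.tsv: edge count does not match parcellation")
    missing = [s for s in SYMPTOMS if s not in study.symptoms.columns]
    if missing:
        problems.append(f"symptoms.tsv: missing symptom columns {missing}")
    else:
        n_ext = sum(DOMAIN_OF[s] == "externalizing" for s in SYMPTOMS)
        if n_ext != len(SYMPTOMS) - n_ext:
            logger.warning("symptom domains are not split evenly (%d/%d)",
                           n_ext, len(SYMPTOMS) - n_ext)
    for col in config.covariate_columns:
        if col not in study.covariates.columns:
            problems.append(f"covariates.tsv: missing column {col!r}")
    return problems


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = _seed_streams(config.seed)
    summary: dict = {"seed": config.seed, "alpha": config.alpha}

    # --- stage: ingest ----------------------------------------------------
    try:
        if config.input_dir is not None:
            study = read_study(config.input_dir)
        else:
            sim = dict(config.simulation)
            sim.setdefault("seed", streams["simulate"])
            study = generate_cohort(SimulationConfig(**sim))
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed: {exc}") from exc
    problems = validate_inputs(config, study)
    if problems:
        raise RuntimeError("stage validate failed: " + "; ".join(problems))
    wave_labels = study.config.wave_labels
    wave1 = wave_labels[0]
    conditions = study.config.conditions
    sym1 = study.symptoms_at(wave1)
    cov1 = study.covariates_at(wave1)[list(config.covariate_columns)]
    conn1 = {c: study.connectome_at(c, wave1) for c in conditions}
    summary["n_subjects"] = int(len(sym1))
    summary["conditions"] = list(conditions)

    # --- stage: edge-wise association ------------------------------------
    maps = []
    for cond in conditions:
        for s in SYMPTOMS:
            maps.append(
                brain_behavior.edgewise_association(
                    conn1[cond],
                    sym1[s].to_numpy(),
                    cov1,
                    alpha=config.alpha,
                    condition=cond,
                    symptom_name=s,
                    fdr=config.fdr_mode,
                )
            )
    assoc_frames = []
    for m in maps:
        df = m.to_frame()
        df.insert(0, "symptom", m.symptom)
        df.insert(0, "condition", m.condition)
        assoc_frames.append(df[df["selected"]])
    pd.concat(assoc_frames, ignore_index=True).to_csv(
        out / "selected_edges.tsv", sep="\t", index=False
    )

    # --- stage: CPM predictions + similarity ------------------------------
    x_all = np.hstack([conn1[c] for c in conditions])
    predicted = {}
    for s in SYMPTOMS:
        cv = brain_behavior.predict_symptom_cv(
            x_all,
            sym1[s].to_numpy(),
            cov1,
            alpha=config.alpha,
            k_folds=config.k_folds,
            seed=streams["cv"],
            symptom_name=s,
        )
        predicted[s] = cv.predicted
    pred_df = pd.DataFrame(predicted, index=sym1.index)
    pred_df.to_csv(out / "brain_predicted_symptoms.tsv", sep="\t")
    sim_cmp = {}
    for name, cols in [
        ("externalizing", EXTERNALIZING_SYMPTOMS),
        ("internalizing", INTERNALIZING_SYMPTOMS),
    ]:
        cmp_ = brain_behavior.compare_mean_similarity(
            sym1[list(cols)],
            pred_df[list(cols)],
            [name] * len(cols),
            n_perm=max(100, config.n_perm),
            seed=streams["similarity"],
        )
        sim_cmp[name] = {
            "r_mean_observed": cmp_.r_mean_obs,
            "r_mean_predicted": cmp_.r_mean_pred,
            "p_perm": cmp_.p_perm,
        }
    summary["similarity"] = sim_cmp

    # --- stage: taxonomy + permutation reliability ------------------------
    taxonomy = factors.classify_edges(maps)
    perm = factors.count_permutation_test(
        conn1,
        sym1,
        cov1,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=streams["perm"],
    )
    summary["permutation"] = {
        f"{cond}|{cat}": {"observed": res.observed_count, "p_perm": res.p_perm}
        for (cond, cat), res in perm.items()
    }

    ext_members, int_members, gen_members = [], [], []
    ext_support, int_support, gen_support = {}, {}, {}
    for cond, tax in taxonomy.items():
        groups = factors.split_sign_groups(tax.externalizing)
        ext_members += groups[factors.SIGN_POS].members
        ext_support.update(groups[factors.SIGN_POS].support)
        groups = factors.split_sign_groups(tax.internalizing)
        int_members += groups[factors.SIGN_NEG].members
        int_support.update(groups[factors.SIGN_NEG].support)
        gen_members += tax.general.members
        gen_support.update(tax.general.support)
    factor_sets = {
        "externalizing": factors.CrossDisorderEdgeSet(
            factors.CATEGORY_EXT, ext_members, ext_support, factors.SIGN_POS
        ),
        "internalizing": factors.CrossDisorderEdgeSet(
            factors.CATEGORY_INT, int_members, int_support, factors.SIGN_NEG
        ),
        "NP": factors.CrossDisorderEdgeSet(
            factors.CATEGORY_GENERAL, gen_members, gen_support, "none"
        ),
    }
    pd.concat(
        [es.to_frame(study.parcellation) for es in factor_sets.values()],
        ignore_index=True,
    ).to_csv(out / "factor_edges.tsv", sep="\t", index=False)
    summary["factor_edge_counts"] = {k: v.n_edges for k, v in factor_sets.items()}

    # factor scores per wave on complete rows of each wave
    scores = {}
    for name, es in factor_sets.items():
        per_wave = {}
        for wave in wave_labels:
            conn_w = {c: study.connectomes[(c, wave)] for c in conditions}
            sc = factors.factor_score(conn_w, es)["score"].to_numpy()
            mask = study.wave_present[wave].to_numpy()
            sc = np.where(mask, sc, np.nan)
            per_wave[wave] = sc
        scores[name] = pd.DataFrame(per_wave, index=study.subjects)
        scores[name].to_csv(out / f"factor_scores_{name}.tsv", sep="\t")

    # --- stage: specificity ----------------------------------------------
    parc = study.parcellation
    try:
        norm_region = {
            k: specificity.normalize_degree(specificity.node_degree(es, parc))
            for k, es in factor_sets.items()
        }
        norm_network = {
            k: specificity.normalize_degree(specificity.network_pair_counts(es, parc))
            for k, es in factor_sets.items()
        }
        region_table = specificity.specificity_scores(
            norm_region["NP"],
            norm_region["externalizing"],
            norm_region["internalizing"],
        )
        network_table = specificity.specificity_scores(
            norm_network["NP"],
            norm_network["externalizing"],
            norm_network["internalizing"],
            unit_ids=specificity.network_pair_labels(parc),
        )
        region_table.to_csv(out / "specificity_regions.tsv", sep="\t", index=False)
        network_table.to_csv(out / "specificity_networks.tsv", sep="\t", index=False)
        summary["specificity"] = _jsonable(
            specificity.compare_specificity_levels(region_table, network_table)
        )
        for key in ("region", "network"):
            summary["specificity"][key].pop("pairwise_t", None)
    except ValueError as exc:
        logger.warning("specificity stage skipped: %s", exc)
        summary["specificity"] = {"skipped": str(exc)}

    # --- stage: longitudinal ---------------------------------------------
    if len(wave_labels) >= 2:
        ages = study.covariates.pivot(
            index="subject_id", columns="wave", values="age"
        ).loc[study.subjects, list(wave_labels)]
        ages = ages.where(study.wave_present)
        longi = {}
        base = {
            "externalizing": sym1[list(EXTERNALIZING_SYMPTOMS)].mean(axis=1),
            "internalizing": sym1[list(INTERNALIZING_SYMPTOMS)].mean(axis=1),
        }
        for name in ("externalizing", "internalizing"):
            traj = longitudinal.subject_slopes(
                scores[name], ages, complete_cases=config.complete_cases
            )
            traj.slopes.to_csv(out / f"trajectories_{name}.tsv", sep="\t")
            entry = {
                "beta_mean": traj.mean_slope,
                "t": traj.t_stat,
                "p_two_tailed": traj.p_two_tailed,
                "cohens_d": traj.cohens_d,
                "n": traj.n,
            }
            sl = traj.slopes["slope"].loc[sym1.index]
            ok = sl.notna()
            assoc = longitudinal.slope_symptom_association(
                sl[ok], base[name][ok], cov1[ok]
            )
            entry["slope_symptom_r"] = assoc.r
            entry["slope_symptom_t"] = assoc.t_stat
            entry["slope_symptom_p"] = assoc.p
            direction = "greater" if name == "externalizing" else "less"
            for wave in wave_labels[1:]:
                symw = study.symptoms_at(wave)
                cols = (
                    EXTERNALIZING_SYMPTOMS
                    if name == "externalizing"
                    else INTERNALIZING_SYMPTOMS
                )
                comp = symw[list(cols)].mean(axis=1)
                sc1 = scores[name][wave1].loc[comp.index]
                covw = study.covariates_at(wave)[list(config.covariate_columns)]
                pred = longitudinal.crosswave_prediction(
                    sc1, comp, covw, direction=direction
                )
                entry[f"crosswave_{wave}"] = {
                    "r": pred.r,
                    "t": pred.t_stat,
                    "p_one_tailed": pred.p,
                    "n": pred.n,
                }
            longi[name] = entry
        summary["longitudinal"] = longi

    # --- stage: genetic covariate associations ----------------------------
    prs = {}
    covg = study.covariates_at(wave1)
    for name, col in [("externalizing", "prs_ext"), ("internalizing", "prs_int")]:
        res = _partial_corr(
            scores[name][wave1].loc[covg.index],
            covg[col],
            cov1,
            tail="two",
        )
        prs[f"{name}_factor_vs_{col}"] = {"r": res.r, "t": res.t_stat, "p": res.p}
    summary["prs"] = prs

    # --- ground-truth recovery (synthetic runs only) ----------------------
    if study.truth is not None:
        truth = study.truth
        planted_ext = {(c, int(e)) for c, v in truth.ext_edges.items() for e in v}
        planted_int = {(c, int(e)) for c, v in truth.int_edges.items() for e in v}
        got_ext = set(factor_sets["externalizing"].members)
        got_int = set(factor_sets["internalizing"].members)
        n_found = len(got_ext) + len(got_int)
        n_false = len(got_ext - planted_ext) + len(got_int - planted_int)
        summary["recovery"] = {
            "ext_sensitivity": len(got_ext & planted_ext) / max(len(planted_ext), 1),
            "int_sensitivity": len(got_int & planted_int) / max(len(planted_int), 1),
            "false_discovery_proportion": n_false / max(n_found, 1),
        }

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True))
    logger.info("pipeline complete; summary at %s", summary_path)
    return summary
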