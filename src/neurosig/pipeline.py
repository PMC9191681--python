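"""End-to-end pipeline driver: simulate -> match -> case-control GLMs ->
disorder similarity -> brain-cognition PLS -> group comparison -> PRS.

A single :class:`PipelineConfig` (loadable from YAML) toggles stages,
fixes every seed, and sets the alpha levels.  Sensitivity analyses
(active-symptom-only, unmedicated-only) are plain row filters feeding the
identical stage code.  Every run writes a provenance record (config hash,
seeds, package version) next to its TSV outputs, and re-running the same
config reproduces all numeric outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neurosig import io
from neurosig.compare import groupwise_correlation_scan, pca_first_component
from neurosig.glm import cognitive_glm, fit_feature_glm, permute_group_effect, posthoc_contrasts
from neurosig.matching import match_controls
from neurosig.pls import bootstrap_weights, holdout_evaluate, permute_pls_variance, pls_fit, residualize_confounds
from neurosig.similarity import compare_similarity_settings, permutation_null_similarity
from neurosig.simulate import CASE_GROUPS, SimulationConfig, generate_cohort

log = logging.getLogger("neurosig")


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    # inputs: either simulate (None paths) or load from TSVs
    cohort_path: str | None = None
    connectivity_path: str | None = None
    thickness_path: str | None = None
    cognition_path: str | None = None
    simulation: dict = field(default_factory=dict)

    # stage toggles
    run_matching: bool = True
    run_casecontrol: bool = True
    run_similarity: bool = True
    run_pls: bool = True
    run_compare: bool = True

    # analysis knobs
    subset: str = "all"                 # all | active_only | unmedicated_only
    covariate_sets: tuple = ("no_prs", "with_prs")
    n_perm: int = 1000
    n_boot: int = 5000
    n_components: int = 3
    seed: int = 0
    alpha_f_perm: float = 0.05
    alpha_posthoc: float = 0.0125
    alpha_similarity: float = 0.01
    fdr_q: float = 0.05
    bootstrap_z: float = 3.0
    z_crit: float = 1.96
    compare_groups: tuple = ("MDD", "ANX")

    def __post_init__(self):
        for name in ("alpha_f_perm", "alpha_posthoc", "alpha_similarity", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} = {v} outside (0, 1)")
        if self.subset not in ("all", "active_only", "unmedicated_only"):
            raise ValueError(f"unknown subset policy {self.subset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("covariate_sets", "compare_groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.cohort_path is not None:
        cohort = io.read_table(cfg.cohort_path)
        conn = io.read_table(cfg.connectivity_path)
        thick = io.read_table(cfg.thickness_path)
        cog = io.read_table(cfg.cognition_path)
        return cohort, conn, thick, cog
    sim = SimulationConfig(**cfg.simulation) if cfg.simulation else SimulationConfig(seed=cfg.seed)
    return generate_cohort(sim)


def _apply_subset(cfg: PipelineConfig, cohort: pd.DataFrame) -> pd.Index:
    """Row filter implementing the sensitivity-analysis policies.

    ``active_only`` keeps controls plus cases with the active-symptom flag;
    ``unmedicated_only`` drops medicated participants everywhere.
    """
    if cfg.subset == "all":
        return cohort.index
    if cfg.subset == "active_only":
        keep = (cohort["group"] == "CTRL") | (cohort["active_symptom_flag"] == 1)
    else:
        keep = cohort["medicated_flag"] == 0
    return cohort.index[keep]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the toggled stages and write a TSV report bundle.

    Returns a dict of in-memory results keyed by stage.  Any stage error
    aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "load"
    try:
        cohort, conn, thick, cog = _load_or_simulate(config)
        idx = _apply_subset(config, cohort)
        cohort, conn, thick, cog = (
            cohort.loc[idx], conn.loc[idx], thick.loc[idx], cog.loc[idx]
        )
        report["n_analysis"] = len(cohort)
        log.info("analysis sample: %d participants (subset=%s)", len(cohort), config.subset)

        if config.run_matching:
            stage = "matching"
            cases = cohort[cohort["group"] != "CTRL"]
            controls = cohort[cohort["group"] == "CTRL"]
            match = match_controls(cases, controls, seed=config.seed)
            report["matching"] = match
            matched_idx = cases.index.append(pd.Index(match.matched_control_ids))
            io.write_table(
                pd.DataFrame({"participant_id": match.matched_control_ids}),
                out / "matched_control_ids.tsv", index=False,
            )
        else:
            matched_idx = cohort.index

        analysis = cohort.loc[matched_idx]
        if config.run_casecontrol:
            stage = "casecontrol"
            report["casecontrol"] = {}
            for setting in config.covariate_sets:
                with_prs = setting == "with_prs"
                for panel, feats in (("connectivity", conn), ("thickness", thick)):
                    fit = fit_feature_glm(
                        analysis, feats.loc[matched_idx], panel=panel, with_prs=with_prs
                    )
                    perm = permute_group_effect(
                        analysis, feats.loc[matched_idx], panel=panel,
                        with_prs=with_prs, n_perm=config.n_perm, seed=config.seed,
                    )
                    flags = posthoc_contrasts(fit, alpha=config.alpha_posthoc)
                    tab = fit.results_table()
                    tab["p_perm_F"] = np.tile(perm.p_perm, len(fit.case_groups_))
                    tab["flag_posthoc"] = flags.T.to_numpy().ravel(order="F")
                    io.write_table(tab, out / f"casecontrol_{panel}_{setting}.tsv", index=False)
                    report["casecontrol"][(panel, setting)] = fit
            stage = "cognitive_glm"
            cg = cognitive_glm(analysis, cog.loc[matched_idx])
            cg_tab = pd.concat(
                {"beta": cg.beta, "t": cg.t, "p": cg.p, "fdr_flag": cg.fdr_flags(config.fdr_q)},
                axis=0,
            )
            io.write_table(cg_tab, out / "cognitive_glm.tsv")
            report["cognitive_glm"] = cg

        if config.run_similarity:
            stage = "similarity"
            report["similarity"] = {}
            for panel, feats in (("connectivity", conn), ("thickness", thick)):
                mats = {}
                for setting in config.covariate_sets:
                    sm = permutation_null_similarity(
                        analysis, feats.loc[matched_idx], panel=panel,
                        with_prs=(setting == "with_prs"),
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    mats[setting] = sm
                    io.write_table(sm.r, out / f"similarity_{panel}_{setting}_r.tsv")
                    io.write_table(sm.p_perm, out / f"similarity_{panel}_{setting}_pperm.tsv")
                report["similarity"][panel] = mats
                if len(mats) > 1:
                    for name, delta in compare_similarity_settings(mats).items():
                        safe = name.replace(" ", "")
                        io.write_table(delta, out / f"similarity_{panel}_delta_{safe}.tsv")

        if config.run_pls:
            stage = "pls"
            complete = cog.notna().all(axis=1)
            case_rows = cohort.index[(cohort["group"] != "CTRL") & complete]
            sub = cohort.loc[case_rows]
            X = residualize_confounds(
                conn.loc[case_rows], sub, confounds=["age", "sex", "site", "motion"]
            )
            Y = residualize_confounds(cog.loc[case_rows], sub, confounds=["age", "sex", "site"])
            model = pls_fit(X, Y, config.n_components)
            perm = permute_pls_variance(
                X, Y, config.n_components, n_perm=config.n_perm, seed=config.seed
            )
            boot = bootstrap_weights(
                X, Y, config.n_components, n_boot=config.n_boot, seed=config.seed,
                threshold=config.bootstrap_z, feature_ids=list(conn.columns),
            )
            hold = holdout_evaluate(X, Y, config.n_components, seed=config.seed)
            wt = boot.weights.copy()
            wt.columns = [f"weight_{c}" for c in wt.columns]
            zt = boot.z.copy()
            zt.columns = [f"z_{c}" for c in zt.columns]
            io.write_table(pd.concat([wt, zt], axis=1), out / "pls_weights.tsv")
            io.write_table(
                pd.DataFrame(
                    {"pct_var_y": model.pct_var_y_},
                    index=[f"PLS{c + 1}" for c in range(config.n_components)],
                ),
                out / "pls_variance.tsv",
            )
            io.write_table(hold.r_pred_obs, out / "pls_holdout.tsv")
            report["pls"] = {
                "model": model, "perm": perm, "bootstrap": boot, "holdout": hold,
                "n": len(case_rows),
            }

        if config.run_compare:
            stage = "compare"
            g1, g2 = config.compare_groups
            complete = cog.notna().all(axis=1)
            rows = cohort.index[cohort["group"].isin([g1, g2]) & complete]
            sub = cohort.loc[rows]
            Yr = residualize_confounds(cog.loc[rows], sub, confounds=["age", "sex", "site"])
            pca = pca_first_component(Yr)
            scan = groupwise_correlation_scan(
                conn.loc[rows], pca.pc1_scores, sub["group"], (g1, g2),
                z_crit=config.z_crit,
            )
            io.write_table(scan, out / f"compare_{g1}_vs_{g2}.tsv")
            report["compare"] = {"pca": pca, "scan": scan}

        stage = "provenance"
        from neurosig import __version__

        prov = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "subset": config.subset,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "version": __version__,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        _write_summary(out, config, report)
        report["provenance"] = prov
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return report


def _write_summary(out: Path, config: PipelineConfig, report: dict) -> None:
    lines = [
        "neurosig pipeline summary",
        f"subset policy: {config.subset}",
        f"analysis n: {report.get('n_analysis', 'NA')}",
    ]
    if "matching" in report:
        m = report["matching"]
        lines.append(
            f"matching: {m.n_matched} controls matched, "
            f"{len(m.unmatched_case_ids)} cases unmatched"
        )
    if "similarity" in report:
        for panel, mats in report["similarity"].items():
            for setting, sm in mats.items():
                k = len(sm.contrasts)
                iu = np.triu_indices(k, 1)
                lines.append(
                    f"similarity[{panel}/{setting}]: mean off-diagonal r = "
                    f"{sm.r.to_numpy()[iu].mean():.3f}"
                )
    if "pls" in report:
        p = report["pls"]
        lines.append(
            f"pls: pct_var_y = {np.round(p['model'].pct_var_y_, 2).tolist()}, "
            f"p_perm = {p['perm'].p_perm:.4g}, n = {p['n']}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
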