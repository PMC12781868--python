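"""End-to-end run orchestration: simulate/ingest -> CAI -> analyses -> bundle.

A single :class:`RunConfig` (YAML-serializable) drives one reproducible run.
All randomness flows from named seeds recorded into the output manifest;
reruns with the same config produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .associations import association_battery, results_to_frame
from .cai import CAIConfig, compute_cai_table
from .cohort import CohortTable, ValidationError
from .inference import (
    adjusted_permutation_test,
    ancova_group_test,
    demographics_table,
    pairwise_permutation_report,
    roc_battery,
)
from .io import build_analysis_table, read_metadata, read_thickness_wide, write_metadata, write_thickness
from .simulate import SyntheticConfig, default_config, generate_cohort
from .trajectories import fit_trajectory_model

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of (``thickness_path`` + ``metadata_path``) or ``synthetic``
    must be supplied.
    """

    output_dir: str = "cai_run"
    thickness_path: Optional[str] = None
    thickness_dialect: str = "aparcstats2table_lh_rh_merged"
    metadata_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    cai: CAIConfig = field(default_factory=CAIConfig)
    cross_sectional: bool = True
    associations: bool = True
    longitudinal: bool = True
    apoe_stratified: bool = True
    n_permutations: int = 9999
    seed: int = 0

    def validate(self) -> None:
        real = self.thickness_path is not None or self.metadata_path is not None
        if real and self.synthetic is not None:
            raise ValidationError("supply either real input paths or a synthetic config, not both")
        if not real and self.synthetic is None:
            raise ValidationError("supply real input paths or a synthetic config")
        if real and (self.thickness_path is None or self.metadata_path is None):
            raise ValidationError("real input needs both thickness_path and metadata_path")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be at least 99")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_from_yaml(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    cai_raw = raw.pop("cai", None)
    cfg = RunConfig(**raw)
    if syn is not None:
        template = syn.pop("cohort_template", "dian_like")
        from .simulate import BiomarkerLink, MMSELink

        for key, cls in (("csf_nfl_link", BiomarkerLink), ("plasma_nfl_link", BiomarkerLink),
                         ("mmse_link", MMSELink)):
            if key in syn and isinstance(syn[key], dict):
                syn[key] = cls(**syn[key])
        cfg.synthetic = default_config(template, **syn)
    if cai_raw is not None:
        if "fixed_range_mm" in cai_raw:
            cai_raw["fixed_range_mm"] = tuple(cai_raw["fixed_range_mm"])
        cfg.cai = CAIConfig(**cai_raw)
    return cfg


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_to_plain(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "config": _to_plain(config),
        "seeds": {"root": config.seed},
        "stages": {},
    }
    stage = "ingest"
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            manifest["seeds"]["synthetic"] = config.synthetic.seed
            write_metadata(cohort.records, out / "metadata.csv")
            write_thickness(cohort.profiles, out / "thickness_long.csv", dialect="long_csv")
        else:
            profiles = read_thickness_wide(config.thickness_path, config.thickness_dialect)
            records = read_metadata(config.metadata_path)
            cohort = CohortTable(records=records, profiles=profiles)
        manifest["stages"][stage] = {
            "n_records": len(cohort.records),
            "n_participants": cohort.n_participants,
        }

        stage = "cai"
        cai_frame = compute_cai_table(cohort, config.cai)
        table = build_analysis_table(cohort, cai_frame)
        manifest["stages"][stage] = {"n_rows": _write_csv(table, out / "analysis_table.csv")}

        baseline = table[table["visit"] == 0].reset_index(drop=True)
        template = baseline["cohort"].iloc[0]
        covars = baseline[["age_years", "sex", "eyo_years"]].rename(
            columns={"age_years": "age", "eyo_years": "eyo"})

        if config.cross_sectional:
            stage = "demographics"
            demo = demographics_table(
                baseline,
                continuous_test="kruskal_wallis" if template == "barcelona_like" else "anova",
                seed=config.seed + 11,
            )
            manifest["stages"][stage] = {"n_rows": _write_csv(demo, out / "demographics.csv")}

            stage = "cross_sectional"
            rows = []
            carriers = baseline["group"].map(lambda g: "CTR" if g == "CTR" else "carrier")
            res = adjusted_permutation_test(
                baseline["cai"], carriers, covars,
                n_permutations=config.n_permutations, seed=config.seed + 21,
            )
            rows.append({"analysis": "carriers_vs_ctr", "contrast": "carrier vs CTR",
                         "method": "permutation", "statistic": res.statistic_observed,
                         "p_raw": res.p_value, "p_adjusted": res.p_value})
            if template == "barcelona_like":
                rep = pairwise_permutation_report(
                    baseline["cai"], baseline["group"], covars,
                    n_permutations=config.n_permutations, seed=config.seed + 31,
                )
                for c in rep.contrasts:
                    rows.append({"analysis": "three_group", "method": "permutation",
                                 "contrast": f"{c['group_b']} vs {c['group_a']}",
                                 "statistic": c["statistic"], "p_raw": c["p_raw"],
                                 "p_adjusted": c["p_adjusted"]})
            else:
                anc = ancova_group_test(baseline["cai"], baseline["group"], covars)
                rows.append({"analysis": "three_group", "method": "ancova",
                             "contrast": "group (omnibus)", "statistic": anc["F"],
                             "p_raw": anc["p"], "p_adjusted": anc["p"]})
                for c in anc["pairwise"].contrasts:
                    rows.append({"analysis": "three_group", "method": "ancova_pairwise",
                                 "contrast": f"{c['group_b']} vs {c['group_a']}",
                                 "statistic": c["statistic"], "p_raw": c["p_raw"],
                                 "p_adjusted": c["p_adjusted"]})
            group_tests = pd.DataFrame(rows)
            manifest["stages"][stage] = {"n_rows": _write_csv(group_tests, out / "group_tests.csv")}

            stage = "roc"
            roc_rows = []
            for pos, neg in (("SMC", "CTR"), ("SMC", "AMC"), ("AMC", "CTR")):
                for r in roc_battery(baseline, pos, neg):
                    roc_rows.append({"positive": pos, "negative": neg, "marker": r.marker,
                                     "auc": r.auc, "n_pos": r.n_pos, "n_neg": r.n_neg})
            manifest["stages"][stage] = {
                "n_rows": _write_csv(pd.DataFrame(roc_rows), out / "roc.csv")}

        if config.apoe_stratified and template == "dian_like":
            stage = "apoe_stratified"
            carriers_tbl = baseline[baseline["group"].isin(["AMC", "SMC"])].reset_index(drop=True)
            cov4 = carriers_tbl[["age_years", "sex", "eyo_years", "cdr"]].rename(
                columns={"age_years": "age", "eyo_years": "eyo"})
            apoe_rows = []
            if carriers_tbl["apoe_genotype"].nunique() >= 2:
                counts = carriers_tbl["apoe_genotype"].value_counts()
                keep = counts[counts >= 2].index
                mask = carriers_tbl["apoe_genotype"].isin(keep).to_numpy()
                res = adjusted_permutation_test(
                    carriers_tbl.loc[mask, "cai"], carriers_tbl.loc[mask, "apoe_genotype"],
                    cov4.loc[mask].reset_index(drop=True),
                    n_permutations=config.n_permutations, seed=config.seed + 41,
                )
                apoe_rows.append({"analysis": "apoe_genotype_omnibus", "stratum": "carriers",
                                  "statistic": res.statistic_observed, "p_raw": res.p_value})
            # CDR defines the AMC/SMC split (AMC -> CDR 0), so it would alias the
            # group factor in these contrasts and is omitted from their covariates
            for i, geno in enumerate(sorted(carriers_tbl["apoe_genotype"].dropna().unique())):
                sub = carriers_tbl[carriers_tbl["apoe_genotype"] == geno]
                if sub["group"].nunique() < 2 or sub["group"].value_counts().min() < 3:
                    continue
                cov_sub = sub[["age_years", "sex", "eyo_years"]].rename(
                    columns={"age_years": "age", "eyo_years": "eyo"}).reset_index(drop=True)
                res = adjusted_permutation_test(
                    sub["cai"], sub["group"], cov_sub,
                    n_permutations=config.n_permutations, seed=config.seed + 51 + i,
                )
                apoe_rows.append({"analysis": "amc_vs_smc_within_genotype", "stratum": geno,
                                  "statistic": res.statistic_observed, "p_raw": res.p_value})
            apoe_df = pd.DataFrame(apoe_rows)
            if len(apoe_df):
                from .inference import bh_adjust

                within = apoe_df["analysis"] == "amc_vs_smc_within_genotype"
                apoe_df["p_adjusted"] = apoe_df["p_raw"]
                if within.sum() > 0:
                    apoe_df.loc[within, "p_adjusted"] = bh_adjust(apoe_df.loc[within, "p_raw"])
            manifest["stages"][stage] = {
                "n_rows": _write_csv(apoe_df, out / "apoe_tests.csv")}

        if config.associations:
            stage = "associations"
            corr = results_to_frame(association_battery(table))
            manifest["stages"][stage] = {
                "n_rows": _write_csv(corr, out / "correlations.csv")}

        if config.longitudinal and table["visit"].max() > 0:
            stage = "longitudinal"
            interactions = {}
            traj_frames = []
            for grouping in ("carriers_vs_ctr", "three_group", "four_group"):
                fit = fit_trajectory_model(table, grouping=grouping)
                interactions[grouping] = {
                    "interaction_tests": fit.interaction_tests,
                    "alpha": fit.alpha, "gcv": fit.gcv, "edf": fit.edf,
                    "n_observations": fit.n_observations,
                    "n_participants": fit.n_participants,
                }
                lo, hi = fit.eyo_range
                grid = np.linspace(lo, hi, 50)
                pred = fit.predict_trajectories(grid)
                pred.insert(0, "grouping", grouping)
                traj_frames.append(pred)
            with open(out / "gam_interactions.json", "w") as fh:
                json.dump(_to_plain(interactions), fh, indent=2, sort_keys=True)
            manifest["stages"][stage] = {
                "n_rows": _write_csv(pd.concat(traj_frames, ignore_index=True),
                                     out / "trajectories.csv")}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(_to_plain(manifest), fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(_to_plain(manifest), fh, indent=2, sort_keys=True)
    return manifest
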