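"""End-to-end orchestration: simulate -> extract -> score -> infer -> report.

``run_pipeline`` composes the stage modules into the study's analysis
shape: a per-parameter comparison of the parkinsonian OFF state against
controls (percent difference, gated test, ROC AUC with CI, Spearman
correlation with the UPDRS motor total), a responder-only medication-
effect table, laterality indices, and the cumulative Z-score block.

``reproduce_clinical_fixture`` recomputes the clinical arithmetic of the
packaged cohort table (descriptives, the strict >6-point responder
partition, the paired OFF/ON t statistic).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, normative, stats, synthetic
from .config import CohortSpec, RunConfig
from .io_clinical import mcd_filter, packaged_cohort_path, read_cohort_table

__all__ = [
    "AnalysisReport",
    "run_pipeline",
    "reproduce_clinical_fixture",
    "TABLE2_DIRECTIONS",
    "DEFAULT_CUMULATIVE_PARAMETERS",
]

log = logging.getLogger("exopark")

#: Expected sign of (PD OFF minus control) group means for the parameters
#: with a significant group difference: -1 lower in PD, +1 higher in PD.
TABLE2_DIRECTIONS = {
    "oh_mean_hand_speed": -1,
    "oh_movement_area": -1,
    "oh_total_hits": -1,
    "oha_mean_hand_speed": -1,
    "oha_movement_area": -1,
    "oha_total_hits": -1,
    "ps_end_total_torque": -1,
    "ps_total_torque_difference": +1,
    "ps_hold_torque": +1,
    "ps_peak_speed": -1,
    "ul_deceleration_time": -1,
    "ul_max_displacement": -1,
}

#: Frozen six-parameter component set for the cumulative score: the
#: parameters of this battery that move under dopamine replacement
#: (hit counts in both hitting tasks, hand speed and movement area under
#: distractor load, baseline hold torque, unloading maximum displacement).
DEFAULT_CUMULATIVE_PARAMETERS = [
    "oh_total_hits",
    "oha_total_hits",
    "oha_mean_hand_speed",
    "oha_movement_area",
    "ps_hold_torque",
    "ul_max_displacement",
]

#: Parameters whose laterality index is analyzed (highest-ROC bilateral ones).
LATERALITY_PARAMETERS = ["oh_mean_hand_speed", "oha_mean_hand_speed", "ps_end_total_torque"]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance; serializable to a directory."""

    table2_like: pd.DataFrame
    table3_like: pd.DataFrame
    laterality: pd.DataFrame
    cumulative: dict
    clinical_summary: dict
    selected_parameters: list[str]
    provenance: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def report_hash(self) -> str:
        parts = [
            self.table2_like.round(10).to_csv(),
            self.table3_like.round(10).to_csv(),
            self.laterality.round(10).to_csv(),
            json.dumps(self.cumulative, sort_keys=True, default=float),
            json.dumps(self.clinical_summary, sort_keys=True, default=float),
            json.dumps(self.selected_parameters),
        ]
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table2_like.to_csv(out / "table2_like.csv", index=False)
        self.table3_like.to_csv(out / "table3_like.csv", index=False)
        self.laterality.to_csv(out / "laterality.csv", index=False)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv")
        (out / "report.json").write_text(
            json.dumps(
                {
                    "cumulative": self.cumulative,
                    "clinical_summary": self.clinical_summary,
                    "selected_parameters": self.selected_parameters,
                    "provenance": self.provenance,
                    "report_hash": self.report_hash(),
                },
                sort_keys=True,
                indent=1,
                default=float,
            ),
            encoding="utf-8",
        )


def _clean(series: pd.Series) -> np.ndarray:
    a = series.to_numpy(dtype=float)
    return a[np.isfinite(a)]


def run_pipeline(config: RunConfig, tasks=None) -> AnalysisReport:
    """Run the full synthetic-cohort analysis described by ``config``."""
    if config.cohort.n_pd <= 0:
        raise ValueError("no PD subjects in cohort spec")
    tasks = tasks or config.tasks
    log.info("stage=simulate n_controls=%d n_pd=%d seed=%d",
             config.cohort.n_controls, config.cohort.n_pd, config.seed)
    cohort = synthetic.generate_cohort(config.cohort, config.seed, tasks)

    tidy = features.extract_parameters(cohort)
    wide = features.parameter_table(tidy, arm="mean")
    log.info("stage=extract sessions=%d parameters=%d", len(wide), wide.shape[1])

    models = normative.fit_normative_models(wide, cohort.subjects, min_controls=min(
        20, config.cohort.n_controls))
    z = normative.z_table(wide, models, cohort.subjects)

    by_id = {s.subject_id: s for s in cohort.subjects}
    controls = wide.xs("baseline", level="session")
    pd_off = wide.xs("off", level="session")
    pd_on = wide.xs("on", level="session")
    n_tests = 0

    # ---- per-parameter OFF-vs-control block: % difference, test, ROC, rho ----
    t2_rows = []
    updrs_off = np.array([by_id[s].updrs3_off for s in pd_off.index], dtype=float)
    for param in wide.columns:
        x = _clean(pd_off[param])
        y = _clean(controls[param])
        if x.size < 3 or y.size < 3:
            continue
        cmp_res = stats.gated_compare(x, y, gate_alpha=config.gate_alpha)
        roc = stats.roc_auc(x, y)
        ok = np.isfinite(pd_off[param].to_numpy(dtype=float))
        rho, rho_p = stats.spearman(pd_off[param].to_numpy(dtype=float)[ok], updrs_off[ok])
        n_tests += 3
        t2_rows.append({
            "parameter": param,
            "percent_difference": round(cmp_res.percent_difference, 1),
            "test_used": cmp_res.test_used,
            "statistic": cmp_res.statistic,
            "p": cmp_res.p,
            "significant": cmp_res.p < config.group_alpha,
            "auc": round(roc.auc, 2),
            "auc_ci_lo": round(roc.ci95[0], 2),
            "auc_ci_hi": round(roc.ci95[1], 2),
            "spearman_updrs": round(rho, 2),
            "spearman_p": rho_p,
            "result_id": f"t2:{param}",
        })
    table2 = pd.DataFrame(t2_rows)

    # ---- responder partition and paired medication-effect block ----
    responders, nonresponders = mcd_filter(cohort.subjects)
    resp = sorted(responders)
    d_updrs = np.array([by_id[s].updrs3_off - by_id[s].updrs3_on for s in pd_off.index],
                       dtype=float)
    t3_rows = []
    for param in wide.columns:
        xo = pd_off.loc[resp, param].to_numpy(dtype=float)
        xn = pd_on.loc[resp, param].to_numpy(dtype=float)
        ok = np.isfinite(xo) & np.isfinite(xn)
        if ok.sum() < 5:
            continue
        eff = stats.gated_compare(xn[ok], xo[ok], paired=True, gate_alpha=config.gate_alpha)
        delta = (pd_on[param] - pd_off[param]).to_numpy(dtype=float)
        okd = np.isfinite(delta)
        rho, rho_p = stats.spearman(delta[okd], d_updrs[okd])
        n_tests += 2
        t3_rows.append({
            "parameter": param,
            "n_responders": int(ok.sum()),
            "test_used": eff.test_used,
            "statistic": eff.statistic,
            "p": eff.p,
            "drt_percent_change": round(eff.percent_difference, 1),
            "spearman_delta_updrs": round(rho, 2),
            "spearman_p": rho_p,
            "result_id": f"t3:{param}",
        })
    table3 = pd.DataFrame(t3_rows)

    # ---- laterality ----
    right = features.parameter_table(tidy, arm="right")
    left = features.parameter_table(tidy, arm="left")
    lat_rows = []
    for param in LATERALITY_PARAMETERS:
        if param not in right.columns:
            continue
        li = {}
        for session in ("off", "baseline"):
            r = right.xs(session, level="session")[param]
            l = left.xs(session, level="session")[param]
            li[session] = np.array([
                normative.laterality_index(rv, lv, param).li
                for rv, lv in zip(r, l)
                if np.isfinite(rv) and np.isfinite(lv)
            ])
        if min(li["off"].size, li["baseline"].size) < 3:
            continue
        roc = stats.roc_auc(li["off"], li["baseline"])
        n_tests += 1
        lat_rows.append({
            "parameter": param,
            "li_pd_off_mean": float(np.mean(li["off"])),
            "li_control_mean": float(np.mean(li["baseline"])),
            "auc": round(roc.auc, 2),
            "auc_ci_lo": round(roc.ci95[0], 2),
            "auc_ci_hi": round(roc.ci95[1], 2),
            "result_id": f"li:{param}",
        })
    laterality = pd.DataFrame(lat_rows)

    # ---- cumulative score ----
    if config.frozen_parameters is not None:
        selected = list(config.frozen_parameters)
    else:
        z_off_resp = z.loc[[(s, "off") for s in resp]].droplevel("session")
        z_on_resp = z.loc[[(s, "on") for s in resp]].droplevel("session")
        selected = normative.select_drt_sensitive(
            z_off_resp, z_on_resp, alpha=config.selection_alpha,
            gate_alpha=config.gate_alpha)
        n_tests += len(z.columns)
    missing = [p for p in selected if p not in z.columns]
    if missing:
        raise ValueError(f"cumulative components not in parameter table: {missing}")

    def rss(session: str, subjects_) -> np.ndarray:
        vals = []
        for s in subjects_:
            comp = z.loc[(s, session), selected]
            if comp.notna().all():
                vals.append(normative.cumulative_score(comp.to_dict()).value)
        return np.array(vals)

    cum_off = rss("off", resp)
    cum_on = rss("on", resp)
    cum_ctrl = rss("baseline", [s.subject_id for s in cohort.subjects
                                if s.group == "control"])
    cum_pair = stats.gated_compare(cum_off, cum_on, paired=True,
                                   gate_alpha=config.gate_alpha)
    all_pd = list(pd_off.index)
    cum_all_off = rss("off", all_pd)
    cum_all_on = rss("on", all_pd)
    d_cum = cum_all_on - cum_all_off
    d_updrs_all = np.array([by_id[s].updrs3_on - by_id[s].updrs3_off for s in all_pd],
                           dtype=float)
    rho_cum, rho_cum_p = stats.spearman(d_cum, d_updrs_all)
    n_tests += 2
    cumulative = {
        "parameters": selected,
        "off_mean": float(np.mean(cum_off)),
        "on_mean": float(np.mean(cum_on)),
        "control_mean": float(np.mean(cum_ctrl)),
        "paired_test": cum_pair.test_used,
        "paired_statistic": cum_pair.statistic,
        "paired_p": cum_pair.p,
        "spearman_delta_updrs": round(rho_cum, 2),
        "spearman_p": rho_cum_p,
        "result_id": "cum:score",
    }

    clinical_summary = {
        "n_pd": int(config.cohort.n_pd),
        "n_controls": int(config.cohort.n_controls),
        "n_responders": len(responders),
        "n_nonresponders": len(nonresponders),
    }
    provenance = {
        "config_hash": config.config_hash(),
        "task_config_hash": tasks.config_hash(),
        "cohort_manifest_hash": cohort.manifest_hash(),
        "seed": config.seed,
        "package_version": _version(),
        "n_statistical_tests": n_tests,
        "multiple_testing_correction": "none",
    }
    report = AnalysisReport(
        table2_like=table2,
        table3_like=table3,
        laterality=laterality,
        cumulative=cumulative,
        clinical_summary=clinical_summary,
        selected_parameters=selected,
        provenance=provenance,
        tables={"parameters_tidy": tidy.set_index(["subject", "session"]),
                "z_scores": z},
    )
    if config.out_dir:
        report.write(config.out_dir)
    log.info("stage=report hash=%s tests=%d", report.report_hash()[:12], n_tests)
    return report


def planted_cohort_check(
    seed: int,
    spec: CohortSpec | None = None,
    tasks=None,
    components: list[str] | None = None,
) -> dict:
    """Group-effect summary of one simulated cohort.

    Returns the sign of every (PD OFF minus control) group-mean difference
    for the parameters with an expected direction, plus the mean cumulative
    score (over the frozen component set) for PD OFF, PD ON and controls.
    Used by the Monte-Carlo self-checks that verify the planted effects
    propagate through extraction and scoring.
    """
    from .config import reduced_task_config

    spec = spec or CohortSpec(n_controls=8, n_pd=8)
    tasks = tasks or reduced_task_config(100.0)
    components = components or DEFAULT_CUMULATIVE_PARAMETERS
    cohort = synthetic.generate_cohort(spec, seed, tasks)
    tidy = features.extract_parameters(cohort)
    wide = features.parameter_table(tidy, arm="mean")
    ctrl = wide.xs("baseline", level="session").mean()
    off = wide.xs("off", level="session").mean()
    directions = {
        p: int(np.sign(off[p] - ctrl[p])) for p in TABLE2_DIRECTIONS if p in wide
    }
    models = normative.fit_normative_models(
        wide, cohort.subjects, min_controls=min(20, spec.n_controls))
    z = normative.z_table(wide, models, cohort.subjects)
    means = {}
    for session, label in (("off", "off"), ("on", "on"), ("baseline", "control")):
        zz = z.xs(session, level="session")[components].dropna()
        means[label] = float(np.mean([
            normative.cumulative_score(row.to_dict()).value
            for _, row in zz.iterrows()
        ]))
    return {"directions": directions, "cumulative": means}


def _version() -> str:
    from . import __version__

    return __version__


def reproduce_clinical_fixture(table_path: str | Path | None = None) -> dict:
    """Clinical summary block recomputed from a cohort table.

    Uses the packaged 26-subject fixture when no path is given.  All
    quantities are recomputed from the per-subject rows: descriptives,
    the strict >6-point responder partition, OFF/ON means overall and in
    responders, the MoCA range, and the paired t test OFF vs ON.
    """
    path = Path(table_path) if table_path else packaged_cohort_path()
    records = read_cohort_table(path)
    pd_recs = [r for r in records if r.group == "PD"]
    responders, nonresponders = mcd_filter(pd_recs)
    off = np.array([r.updrs3_off for r in pd_recs], dtype=float)
    on = np.array([r.updrs3_on for r in pd_recs], dtype=float)
    ages = np.array([r.age for r in pd_recs], dtype=float)
    dur = np.array([r.disease_duration for r in pd_recs], dtype=float)
    moca = np.array([r.moca for r in pd_recs], dtype=float)
    r_off = np.array([r.updrs3_off for r in pd_recs if r.subject_id in responders],
                     dtype=float)
    r_on = np.array([r.updrs3_on for r in pd_recs if r.subject_id in responders],
                    dtype=float)
    paired = stats.gated_compare(off, on, paired=True)
    return {
        "n": len(pd_recs),
        "age_mean": round(float(ages.mean()), 1),
        "age_sd": round(float(ages.std(ddof=1)), 1),
        "disease_duration_mean": round(float(dur.mean()), 1),
        "disease_duration_sd": round(float(dur.std(ddof=1)), 1),
        "updrs_off_mean": round(float(off.mean()), 1),
        "updrs_on_mean": round(float(on.mean()), 1),
        "responders": sorted(responders),
        "nonresponders": sorted(nonresponders),
        "n_responders": len(responders),
        "n_nonresponders": len(nonresponders),
        "responder_off_mean": round(float(r_off.mean()), 2),
        "responder_on_mean": round(float(r_on.mean()), 2),
        "moca_min": int(moca.min()),
        "moca_max": int(moca.max()),
        "paired_test": paired.test_used,
        "paired_t": round(paired.statistic, 3),
        "paired_p": paired.p,
        "n_right_handed": sum(r.handedness == "right" for r in pd_recs),
        "n_left_handed": sum(r.handedness == "left" for r in pd_recs),
    }
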