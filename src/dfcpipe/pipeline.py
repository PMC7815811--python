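"""End-to-end orchestration: simulate/QC -> connectivity -> null -> statistics.

A single validated configuration drives the whole analysis so that every
parameter of the emulated protocol (window scheme, motion rule, filter
cutoff, surrogate count, fatigue cutoff, entry p) has exactly one home and
a run is fully reproducible from the config plus its seed.
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

from . import synthetic
from .connectivity import (
    SubnetworkSpec,
    WindowSpec,
    dfc_coefficient_of_variation,
    dfc_summed_difference,
    global_mean,
    static_fc,
    subnetwork_value,
    windowed_fc,
)
from .io import write_matrix_csv
from .preprocess import (
    discard_initial_volumes,
    framewise_displacement,
    highpass_filter,
    motion_exclusion,
)
from .stats import (
    RegressionBlocks,
    classify_severe_fatigue,
    hierarchical_forward_regression,
    score_cis20r,
    spearman_profile,
    three_group_compare,
    two_group_compare,
)
from .surrogate import real_vs_surrogate_test, surrogate_dfc_full
from .synthetic import SimulationConfig, default_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Resolved pipeline settings with protocol defaults filled in."""

    seed: int = 0
    output_dir: str = "dfcpipe_out"
    save_matrices: bool = False
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    subnetwork: SubnetworkSpec = field(default_factory=default_subnetwork)
    n_discard: int = 5
    fd_threshold_mm: float = 0.5
    max_fd_fraction: float = 0.20
    head_radius_mm: float = 50.0
    highpass_cutoff_hz: float = 0.01
    apply_highpass: bool = True
    n_surrogates: int = 100
    surrogates_enabled: bool = True
    fatigue_cutoff: float = 76.0
    p_enter: float = 0.05

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "save_matrices": self.save_matrices,
            "simulate": dataclasses.asdict(self.simulate),
            "window": dataclasses.asdict(self.window),
            "subnetwork": {
                "set_a": list(self.subnetwork.set_a),
                "set_b": list(self.subnetwork.set_b),
                "mode": self.subnetwork.mode,
            },
            "qc": {
                "n_discard": self.n_discard,
                "fd_threshold_mm": self.fd_threshold_mm,
                "max_fd_fraction": self.max_fd_fraction,
                "head_radius_mm": self.head_radius_mm,
            },
            "highpass": {
                "cutoff_hz": self.highpass_cutoff_hz,
                "apply": self.apply_highpass,
            },
            "surrogate": {
                "n_surrogates": self.n_surrogates,
                "enabled": self.surrogates_enabled,
            },
            "stats": {"fatigue_cutoff": self.fatigue_cutoff, "p_enter": self.p_enter},
        }
        return d


_TOP_KEYS = {
    "seed", "output_dir", "save_matrices", "simulate", "window", "subnetwork",
    "qc", "highpass", "surrogate", "stats",
}
_QC_KEYS = {"n_discard", "fd_threshold_mm", "max_fd_fraction", "head_radius_mm"}
_HP_KEYS = {"cutoff_hz", "apply"}
_SURR_KEYS = {"n_surrogates", "enabled"}
_STATS_KEYS = {"fatigue_cutoff", "p_enter"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {section}: {sorted(unknown)}")


def validate_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Resolve a YAML file / dict into a fully defaulted PipelineConfig.

    An empty source yields the protocol defaults (27/5/9 window, 0.5 mm /
    20% motion rule, 0.01 Hz high-pass, 100 surrogates, fatigue cutoff 76,
    entry p 0.05). Unknown keys are rejected by name; cross-field
    consistency (window fits the usable volumes) is checked before any
    computation.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys("top level", raw, _TOP_KEYS)
    sim_raw = dict(raw.get("simulate") or {})
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)} - {"seed"}
    _check_keys("simulate", sim_raw, sim_fields)
    win_raw = dict(raw.get("window") or {})
    _check_keys("window", win_raw, {"length_volumes", "step_volumes", "taper_sd_volumes"})
    sub_raw = raw.get("subnetwork")
    qc_raw = dict(raw.get("qc") or {})
    _check_keys("qc", qc_raw, _QC_KEYS)
    hp_raw = dict(raw.get("highpass") or {})
    _check_keys("highpass", hp_raw, _HP_KEYS)
    surr_raw = dict(raw.get("surrogate") or {})
    _check_keys("surrogate", surr_raw, _SURR_KEYS)
    stats_raw = dict(raw.get("stats") or {})
    _check_keys("stats", stats_raw, _STATS_KEYS)

    seed = int(raw.get("seed", 0))
    n_discard = int(qc_raw.get("n_discard", 5))
    sim = SimulationConfig(seed=seed, n_discard=n_discard, **sim_raw)
    window = WindowSpec(**win_raw)
    if isinstance(sub_raw, dict):
        subnet = SubnetworkSpec(
            set_a=tuple(sub_raw["set_a"]),
            set_b=tuple(sub_raw["set_b"]),
            mode=sub_raw.get("mode", "between-sets-plus-within"),
        )
    elif isinstance(sub_raw, str):
        from .io import read_subnetwork_spec

        subnet = read_subnetwork_spec(sub_raw)
    else:
        subnet = default_subnetwork()
    cfg = PipelineConfig(
        seed=seed,
        output_dir=str(raw.get("output_dir", "dfcpipe_out")),
        save_matrices=bool(raw.get("save_matrices", False)),
        simulate=sim,
        window=window,
        subnetwork=subnet,
        n_discard=n_discard,
        fd_threshold_mm=float(qc_raw.get("fd_threshold_mm", 0.5)),
        max_fd_fraction=float(qc_raw.get("max_fd_fraction", 0.20)),
        head_radius_mm=float(qc_raw.get("head_radius_mm", 50.0)),
        highpass_cutoff_hz=float(hp_raw.get("cutoff_hz", 0.01)),
        apply_highpass=bool(hp_raw.get("apply", True)),
        n_surrogates=int(surr_raw.get("n_surrogates", 100)),
        surrogates_enabled=bool(surr_raw.get("enabled", True)),
        fatigue_cutoff=float(stats_raw.get("fatigue_cutoff", 76.0)),
        p_enter=float(stats_raw.get("p_enter", 0.05)),
    )
    usable = cfg.simulate.n_volumes - cfg.n_discard
    if usable < cfg.window.length_volumes:
        raise ValueError(
            f"window length {cfg.window.length_volumes} exceeds the "
            f"{usable} usable volumes"
        )
    nyquist = 0.5 / cfg.simulate.tr_seconds
    if cfg.apply_highpass and cfg.highpass_cutoff_hz >= nyquist:
        raise ValueError("high-pass cutoff at or above Nyquist")
    return cfg


def _subscale_columns(clin: pd.DataFrame) -> pd.DataFrame:
    item_cols = [f"cis20r_item_{i:02d}" for i in range(1, 21)]
    rows = []
    for _, row in clin.iterrows():
        score = score_cis20r([row[c] for c in item_cols])
        rows.append(
            {
                "cis20r_subjective": score.subjective_complaints,
                "cis20r_motivation": score.motivation,
                "cis20r_physical": score.physical_activity,
                "cis20r_concentration": score.concentration,
            }
        )
    return pd.concat([clin.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Per subject: motion QC, volume discarding, optional high-pass, static
    and windowed connectivity, both dFC measures, global and subnetwork
    (raw and normalized) values. Cohort level: real-vs-surrogate paired
    tests, patient/control comparisons, the hierarchical forward
    regression, the post-hoc Spearman profile and the cutoff-based
    three-group comparison. Returns the bundle as a dict and writes every
    table under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        with open(out / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)

        stage = "simulate"
        cohort = synthetic.simulate_cohort(config.simulate, config.window)
        clin = _subscale_columns(synthetic.clinical_table(cohort))

        stage = "qc"
        qc_rows = []
        retained = []
        for subj in cohort:
            fd = framewise_displacement(subj.motion, config.head_radius_mm)
            decision = motion_exclusion(
                fd, config.fd_threshold_mm, config.max_fd_fraction
            )
            qc_rows.append(
                {
                    "subject_id": subj.timeseries.subject_id,
                    "mean_fd_mm": float(fd.mean()),
                    "max_fd_mm": float(fd.max()),
                    "fraction_above_threshold": float(
                        np.mean(fd > config.fd_threshold_mm)
                    ),
                    "decision": decision,
                }
            )
            if decision == "retain":
                retained.append(subj)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc_rows, fh, indent=2)

        stage = "connectivity"
        conn_rows = []
        for subj in retained:
            ts = discard_initial_volumes(subj.timeseries, config.n_discard)
            if config.apply_highpass:
                ts = highpass_filter(ts, config.highpass_cutoff_hz)
            sfc = static_fc(ts)
            wc = windowed_fc(ts, config.window)
            diff = dfc_summed_difference(wc)
            cv = dfc_coefficient_of_variation(wc)
            row = {"subject_id": ts.subject_id}
            for name, res in (("sfc", sfc), ("dfc_diff", diff), ("dfc_cv", cv)):
                row[f"global_{name}"] = global_mean(res)
                row[f"bd_{name}_raw"] = subnetwork_value(res, config.subnetwork, False)
                row[f"bd_{name}"] = subnetwork_value(res, config.subnetwork, True)
            conn_rows.append(row)
            subj.analysis_series = ts  # retained for the surrogate stage
            if config.save_matrices:
                mdir = out / "matrices"
                mdir.mkdir(exist_ok=True)
                for name, res in (("sfc", sfc), ("dfc_diff", diff), ("dfc_cv", cv)):
                    mat = res.values if name == "sfc" else res.matrix
                    write_matrix_csv(
                        mdir / f"{ts.subject_id}_{name}.csv", mat, ts.region_labels
                    )
        conn = pd.DataFrame(conn_rows)
        table = clin.merge(conn, on="subject_id", how="inner")
        table.to_csv(out / "subject_table.csv", index=False)

        stage = "surrogate-null"
        surrogate_summary = {}
        if config.surrogates_enabled:
            master = np.random.SeedSequence([config.seed, 0x5EED])
            streams = master.spawn(len(retained))
            per_key: dict[str, list] = {}
            for subj, stream in zip(retained, streams):
                ens = surrogate_dfc_full(
                    subj.analysis_series,
                    config.window,
                    subnetwork=config.subnetwork,
                    n_surrogates=config.n_surrogates,
                    seed=np.random.default_rng(stream),
                )
                for key, e in ens.items():
                    per_key.setdefault(key, []).append(e)
            for key, ensembles in per_key.items():
                t, p, d = real_vs_surrogate_test(ensembles)
                surrogate_summary[key] = {
                    "t": t,
                    "p": p,
                    "mean_difference": d,
                    "n_subjects": len(ensembles),
                    "n_surrogates": config.n_surrogates,
                }
            with open(out / "surrogate_tests.json", "w") as fh:
                json.dump(surrogate_summary, fh, indent=2)

        stage = "group-comparisons"
        patients = table[table["group"] == "patient"]
        controls = table[table["group"] == "control"]
        comparison_cols = [
            "global_sfc", "global_dfc_diff", "global_dfc_cv",
            "bd_sfc", "bd_dfc_diff", "bd_dfc_cv",
            "cis20r_total", "hads_anxiety", "hads_depression",
        ]
        comp_rows = []
        for col in comparison_cols:
            res = two_group_compare(patients[col], controls[col])
            comp_rows.append(
                {
                    "variable": col,
                    "test": res.name,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "patient_mean": float(patients[col].mean()),
                    "control_mean": float(controls[col].mean()),
                }
            )
        comparisons = pd.DataFrame(comp_rows)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)

        stage = "regression"
        pat = patients.copy()
        pat["sex_male"] = (pat["sex"] == "male").astype(float)
        pat["medication_second_line"] = (pat["medication"] == "second-line").astype(float)
        blocks = RegressionBlocks(
            block1=("age", "sex_male", "education", "medication_second_line",
                    "disease_duration", "edss"),
            block2=("norm_gm_volume", "norm_wm_volume", "log_lesion_volume"),
            block3=("global_dfc_diff", "global_dfc_cv", "bd_dfc_diff", "bd_dfc_cv"),
            outcome="cis20r_total",
        )
        regression = hierarchical_forward_regression(pat, blocks, config.p_enter)
        reg_payload = {
            "selected": regression.selected,
            "r2": regression.r2,
            "adjusted_r2": regression.adjusted_r2,
            "delta_r2": regression.delta_r2,
            "standardized_beta": regression.standardized_beta,
            "t": regression.t_values,
            "p": regression.p_values,
            "F": regression.f_statistic,
            "F_df": list(regression.f_df),
            "F_p": regression.f_p,
            "n": regression.n,
        }
        with open(out / "regression.json", "w") as fh:
            json.dump(reg_payload, fh, indent=2)

        stage = "post-hoc"
        fatigue_cols = [
            "cis20r_total", "cis20r_subjective", "cis20r_motivation",
            "cis20r_physical", "cis20r_concentration",
        ]
        spearman = pd.DataFrame()
        if regression.selected:
            spearman = spearman_profile(pat[regression.selected], pat[fatigue_cols])
            spearman.to_csv(out / "spearman_posthoc.csv", index=False)
        severity = pat["cis20r_total"].apply(
            lambda t: classify_severe_fatigue(t, config.fatigue_cutoff)
        )
        groups = {
            "control": controls["bd_dfc_cv"].to_numpy(),
            "non-fatigued": pat.loc[severity == "non-severe", "bd_dfc_cv"].to_numpy(),
            "fatigued": pat.loc[severity == "severe", "bd_dfc_cv"].to_numpy(),
        }
        three_group = None
        if all(len(v) >= 2 for v in groups.values()):
            omnibus, pairwise = three_group_compare(groups)
            three_group = {
                "omnibus": {"H": omnibus.statistic, "df": omnibus.df, "p": omnibus.p},
                "pairwise": pairwise.to_dict(orient="records"),
                "group_sizes": {k: int(len(v)) for k, v in groups.items()},
            }
            with open(out / "three_group.json", "w") as fh:
                json.dump(three_group, fh, indent=2)

        stage = "report"
        manifest = {
            "n_subjects": len(cohort),
            "n_retained": len(retained),
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return {
        "config": config,
        "qc": qc_rows,
        "subject_table": table,
        "surrogate_tests": surrogate_summary,
        "group_comparisons": comparisons,
        "regression": regression,
        "spearman": spearman,
        "three_group": three_group,
    }
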