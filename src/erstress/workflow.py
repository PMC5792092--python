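"""End-to-end pipeline: simulate -> quantify -> morphometry -> composition
-> model, with a single summary table of the headline quantities.

The run is driven by a :class:`RunConfig` (YAML-loadable, schema-validated,
unknown keys rejected).  One shared seed is expanded into independent
per-module streams by the synthetic-data generator, so enabling or
disabling a stage never perturbs another stage's random draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, proteomics, quantitation, sensing, synthetic

__all__ = ["RunConfig", "run_report"]


@dataclass
class StageToggles:
    simulate: bool = True
    quantify: bool = True
    morphometry: bool = True
    composition: bool = True
    model: bool = True


@dataclass
class QuantifyParams:
    standard_masses_ng: list[float] = field(
        default_factory=lambda: [5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
    replicates: int = 5
    cells_per_lane: float = 7e4
    reference_time_hr: float = 64.0


@dataclass
class MorphometryParams:
    cytoplasm_volume_fl: float = morphometry.DEFAULT_CYTOPLASM_VOLUME_FL
    n_cells: int = 10


@dataclass
class CompositionParams:
    top_n: int = 500
    n_proteins: int = 1000


@dataclass
class ModelParams:
    K_TB: float = 1e-3
    K_TC: float = 1e-3
    K_BC: float = 1e-2
    T_tot: float = 1e-3
    k_syn0: float = 0.025
    k_upr: float = 0.2
    k_deg: float = 0.05
    horizon_hr: float = 168.0


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    stages: StageToggles = field(default_factory=StageToggles)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    composition: CompositionParams = field(default_factory=CompositionParams)
    model: ModelParams = field(default_factory=ModelParams)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return _build(cls, raw, path="")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def _build(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at {where}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        sub = {"stages": StageToggles, "quantify": QuantifyParams,
               "morphometry": MorphometryParams,
               "composition": CompositionParams,
               "model": ModelParams}.get(name)
        kwargs[name] = _build(sub, value, f"{path}.{name}".lstrip(".")) \
            if sub is not None else value
    return cls(**kwargs)


def run_report(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Execute the enabled stages in dependency order.

    Writes TSV outputs and a manifest JSON under ``config.output_dir`` and
    returns (summary table, manifest).  Any stage failure propagates with a
    stage-tagged error; outputs written before the failure are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = synthetic.default_truth(seed=config.seed)
    rows: list[tuple[str, float, str]] = []
    manifest: dict = {"seed": config.seed, "outputs": {}}

    def emit(name: str, value: float, units: str) -> None:
        rows.append((name, float(value), units))

    def write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"][name] = hashlib.sha256(
            path.read_bytes()).hexdigest()

    bip_tc = mus_tc = None
    try:
        if config.stages.simulate or config.stages.quantify:
            q = config.quantify
            standards, lanes = synthetic.gen_blot_dataset(
                truth, tuple(q.standard_masses_ng),
                replicates=q.replicates, cells_per_lane=q.cells_per_lane,
            )
            if config.stages.simulate:
                write("lanes.tsv", lanes)
        if config.stages.quantify:
            courses = {}
            for analyte, series in standards.items():
                cal = quantitation.fit_standard_curve(series)
                with_copies = quantitation.lanes_to_copies(
                    lanes[lanes["analyte"] == analyte], cal,
                    purity=series.purity,
                    molecular_weight_kda=synthetic.ANALYTE_MW_KDA[analyte],
                )
                courses[analyte] = quantitation.timecourse_from_lanes(
                    with_copies, analyte)
            bip_tc, mus_tc = courses["BiP"], courses["mu_s"]
            t0, t_ref = bip_tc.times_hr[0], config.quantify.reference_time_hr
            fold = bip_tc.value_at(t_ref) / bip_tc.value_at(t0)
            emit("bip_copies_resting", bip_tc.value_at(t0), "copies/cell")
            emit("bip_copies_adapted", bip_tc.value_at(t_ref), "copies/cell")
            emit("bip_fold_change", fold, "fold")
            write("abundance.tsv", pd.DataFrame({
                "analyte": (["BiP"] * len(bip_tc.times_hr)
                            + ["mu_s"] * len(mus_tc.times_hr)),
                "time_hr": bip_tc.times_hr + mus_tc.times_hr,
                "copies_per_cell": bip_tc.copies + mus_tc.copies,
            }))
    except Exception as exc:
        raise RuntimeError(f"[quantify] stage failed: {exc}") from exc

    vol_rest = vol_exp = None
    try:
        if config.stages.morphometry:
            m = config.morphometry
            areas = pd.concat([
                synthetic.gen_em_areas(truth, cond, m.n_cells)
                for cond in sorted(truth.em_params)
            ])
            write("em_areas.tsv", areas)
            summary, anova_p = morphometry.condition_summary(areas)
            write("em_summary.tsv", summary.assign(anova_p=anova_p))
            means = summary.set_index("condition")["mean"]
            vol_rest = morphometry.volume_estimate(
                means["resting"], m.cytoplasm_volume_fl)
            vol_exp = morphometry.volume_estimate(
                means["induced"], m.cytoplasm_volume_fl)
            emit("er_volume_resting", vol_rest.er_volume_fl, "fl")
            emit("er_volume_expanded", vol_exp.er_volume_fl, "fl")
            if bip_tc is not None:
                resting = morphometry.lumenal_concentration(
                    bip_tc.value_at(bip_tc.times_hr[0]),
                    vol_rest.er_volume_fl, 70.0)
                emit("bip_molar_resting", resting.molar_mm, "mM")
                emit("bip_mass_resting", resting.mass_mg_ml, "mg/ml")
                adapted = morphometry.lumenal_concentration(
                    bip_tc.value_at(config.quantify.reference_time_hr),
                    3.0 * vol_rest.er_volume_fl, 70.0)
                emit("bip_molar_adapted", adapted.molar_mm, "mM")
                emit("bip_mass_adapted", adapted.mass_mg_ml, "mg/ml")
    except Exception as exc:
        raise RuntimeError(f"[morphometry] stage failed: {exc}") from exc

    try:
        if config.stages.composition:
            c = config.composition
            table = synthetic.gen_proteome_table(
                truth, n_proteins=c.n_proteins)
            write("proteome.tsv", table)
            comp = proteomics.composition_summary(table, top_n=c.top_n)
            frac = comp.compartment_fractions
            er_total = frac["ER_resident"] + frac["client_mus"]
            for day in frac.index:
                emit(f"er_mass_fraction_day{day}", 100 * er_total[day], "%")
            emit("bip_share_of_er_day7",
                 100 * comp.er_shares.loc[7, "BiP"], "%")
            emit("top_selection_coverage_day0",
                 100 * comp.coverage[0], "%")
            write("composition.tsv", frac.reset_index())
            write("er_shares.tsv", comp.er_shares.reset_index())
    except Exception as exc:
        raise RuntimeError(f"[composition] stage failed: {exc}") from exc

    try:
        if config.stages.model:
            p = config.model
            sensors = sensing.SensorSystem(
                T_tot=p.T_tot, K_TB=p.K_TB, K_TC=p.K_TC, K_BC=p.K_BC)
            if bip_tc is not None and vol_rest is not None:
                # evaluate on fitted curves: replicate noise on a sparse
                # grid would otherwise decide the argmax comparisons
                bip_fit = quantitation.fit_sigmoid(bip_tc)
                mus_fit = quantitation.fit_sigmoid(mus_tc)
                grid = np.linspace(0.5, bip_tc.times_hr[-1], 128)
                smooth_b = quantitation.AbundanceTimeCourse(
                    "BiP", tuple(grid), tuple(bip_fit.predict(grid)))
                smooth_c = quantitation.AbundanceTimeCourse(
                    "mu_s", tuple(grid), tuple(mus_fit.predict(grid)))
                day = grid / 24.0
                # ER expands between days 1 and 3; interpolate the volume
                vols = np.interp(day, [0.0, 1.0, 3.0],
                                 [vol_rest.er_volume_fl,
                                  vol_rest.er_volume_fl,
                                  vol_exp.er_volume_fl])
                traj = sensing.predict_amplitude_timecourse(
                    smooth_b, smooth_c, vols, sensors)
                emit("model_peak_activity_time",
                     traj.times_hr[traj.argmax_activity], "hr")
                emit("model_peak_ratio_time",
                     traj.times_hr[traj.argmax_ratio], "hr")
                emit("model_peak_client_time",
                     traj.times_hr[traj.argmax_client], "hr")
            fb = sensing.default_feedback_params(
                k_syn0=p.k_syn0, k_upr=p.k_upr, k_deg=p.k_deg,
                sensors=sensors)
            fb_traj = sensing.simulate_feedback(fb, p.horizon_hr)
            act = np.asarray(fb_traj.activity)
            emit("feedback_peak_activity", act.max(), "fraction")
            emit("feedback_chronic_activity", act[-1], "fraction")
            write("feedback_trajectory.tsv", pd.DataFrame({
                "time_hr": fb_traj.times_hr, "B_tot_mM": fb_traj.B_tot,
                "C_tot_mM": fb_traj.C_tot, "activity": fb_traj.activity,
            }))
    except Exception as exc:
        raise RuntimeError(f"[model] stage failed: {exc}") from exc

    summary = pd.DataFrame(rows, columns=["quantity", "value", "units"])
    summary_path = outdir / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
    from . import __version__
    manifest["version"] = __version__
    manifest["config"] = dataclasses.asdict(config)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return summary, manifest
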