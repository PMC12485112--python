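"""End-to-end orchestration: simulate -> fractions -> proteomics -> imaging -> stats.

A single YAML-able config dict drives all stages; every stage persists its
intermediate artifacts (CSV / TIFF / JSON) under the output directory and the
final report echoes the full configuration and seed, so identical
config + seed reproduce identical artifacts and report.  Per-stage seeds are
child streams of the run seed (see :mod:`corona_quant._random`).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, fractionation, imaging, io, proteomics, stats, synthetic
from ._random import substream

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fractions", "proteomics", "imaging", "stats")

DEFAULT_IMAGING_CONDITIONS: dict[str, dict] = {
    "no_corona": {"puncta_per_cell_inner": 2.0},
    "apoe_corona": {"puncta_per_cell_inner": 10.0},
}


def _stage_seed(seed: int, *labels: str) -> int:
    return int(substream(seed, "pipeline", *labels).integers(2**31))


def _cfg(cls, overrides: dict | None, seed: int) -> Any:
    kwargs = dict(overrides or {})
    kwargs.setdefault("seed", seed)
    if "image_shape" in kwargs:
        kwargs["image_shape"] = tuple(kwargs["image_shape"])
    return cls(**kwargs)


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "corona_quant_run",
    seed: int = 0,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Execute the requested stages in order; returns the run report dict.

    Stage failures abort with the failing stage named; artifacts written by
    earlier stages are retained.
    """
    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict[str, Any] = {
        "software_version": __version__,
        "seed": seed,
        "config": config,
        "stages": list(stages),
    }
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out, seed, report)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    io.write_json(report, out / "report.json")
    return report


def _simulate(config: dict, out: Path, seed: int, report: dict) -> None:
    sim_report: dict[str, Any] = {}

    fcfg = _cfg(synthetic.FractionSimConfig, config.get("fractions_sim"), _stage_seed(seed, "fractions"))
    profile, ftruth = synthetic.gen_fraction_profile(fcfg)
    io.write_fraction_profile(profile, out / "fraction_profile.csv")
    io.write_json(ftruth.to_dict(), out / "fraction_truth.json")
    sim_report["fraction_profile"] = str(out / "fraction_profile.csv")

    pcfg = _cfg(synthetic.ProteomeSimConfig, config.get("proteome_sim"), _stage_seed(seed, "proteome"))
    peptides, ptruth = synthetic.gen_peptide_table(pcfg)
    io.write_peptide_table(peptides, out / "peptides.csv")
    io.write_json(ptruth.to_dict(), out / "proteome_truth.json")
    sim_report["peptides"] = str(out / "peptides.csv")

    img_cfg = dict(config.get("imaging_sim") or {})
    conditions = img_cfg.pop("conditions", DEFAULT_IMAGING_CONDITIONS)
    n_bio = img_cfg.pop("n_bio", 3)
    n_tech = img_cfg.pop("n_tech", 2)
    fovs_per_tech = img_cfg.pop("fovs_per_tech", 3)
    fov_dir = out / "fovs"
    fov_dir.mkdir(exist_ok=True)
    fov_truths = {}
    idx = 0
    for cond, overrides in conditions.items():
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                for f in range(fovs_per_tech):
                    cfg = _cfg(
                        synthetic.FovSimConfig,
                        {**img_cfg, **overrides},
                        _stage_seed(seed, "fov", cond, str(b), str(t), str(f)),
                    )
                    fov, truth = synthetic.gen_fov(cfg, fov_index=idx)
                    fov.condition = cond
                    fov.biological_replicate = f"bio{b}"
                    fov.technical_replicate = f"tech{t}"
                    path = fov_dir / f"fov_{idx:04d}.tiff"
                    io.write_fov(fov, path)
                    fov_truths[path.name] = truth.to_dict()
                    idx += 1
    io.write_json(fov_truths, out / "fov_truth.json")
    sim_report["n_fovs"] = idx

    flow_cfg = dict(config.get("flow_sim") or {})
    control, treated, flow_truth = synthetic.gen_flow_sample(
        seed=_stage_seed(seed, "flow"), **flow_cfg
    )
    pd.DataFrame({"intensity": control}).to_csv(out / "flow_control.csv", index=False)
    pd.DataFrame({"intensity": treated}).to_csv(out / "flow_treated.csv", index=False)
    io.write_json(flow_truth.to_dict(), out / "flow_truth.json")
    sim_report["flow"] = [str(out / "flow_control.csv"), str(out / "flow_treated.csv")]
    report["simulate"] = sim_report


def _fractions(config: dict, out: Path, seed: int, report: dict) -> None:
    fr_cfg = config.get("fractions") or {}
    profile = io.read_fraction_profile(out / "fraction_profile.csv")
    qc = fractionation.check_gradient_linearity(
        profile,
        measure=fr_cfg.get("qc_measure", "refractive_index"),
        r2_min=fr_cfg.get("r2_min", 0.98),
    )
    window = tuple(fr_cfg.get("window", (2, 6)))
    recovery = fractionation.compute_window_recovery(profile, window)
    selected = fractionation.select_fractions(profile, k=fr_cfg.get("k", 5))
    result = {
        "linearity": dataclasses.asdict(qc),
        "window": list(window),
        "recovery_pct": recovery,
        "selected_window": dataclasses.asdict(selected),
    }
    io.write_json(result, out / "fractions_result.json")
    report["fractions"] = result


def _proteomics(config: dict, out: Path, seed: int, report: dict) -> None:
    pr_cfg = config.get("proteomics") or {}
    peptides = io.read_peptide_table(out / "peptides.csv")
    standard = pr_cfg.get("standard_accession", "P63284")
    spike = pr_cfg.get("spike_fmol", 50.0)
    abundances = proteomics.hi3_quantify(peptides, standard, spike)
    abundances.to_csv(out / "protein_abundance.csv", index=False)
    cv = proteomics.peptide_cv_summary(peptides)
    enr = proteomics.enrichment_analysis(
        abundances,
        q_threshold=pr_cfg.get("q_threshold", 0.05),
        exclude_accessions=[standard],
    )
    enr.records.to_csv(out / "enrichment.csv", index=False)
    result = {
        "median_cv_pct": cv.median_cv_pct,
        "n_tested": int(len(enr.records)),
        "n_enriched": int(len(enr.enriched)),
        "n_depleted": int(len(enr.depleted)),
        "lnp_only": enr.lnp_only,
        "plasma_only": enr.plasma_only,
    }
    io.write_json(result, out / "proteomics_result.json")
    report["proteomics"] = result


def _imaging(config: dict, out: Path, seed: int, report: dict) -> None:
    img_cfg = config.get("imaging") or {}
    fov_dir = out / "fovs"
    measurements = []
    for path in sorted(fov_dir.glob("fov_*.tiff")):
        fov = io.read_fov(path)
        m = imaging.measure_fov(
            fov,
            erosion_n=img_cfg.get("erosion_n", 10),
            nuclei_min_area_px=img_cfg.get("nuclei_min_area_px", 50),
        )
        if m is not None:
            measurements.append(m)
    table = imaging.aggregate_replicates(measurements)
    table.to_csv(out / "imaging_measurements.csv", index=False)
    per_condition = (
        table[table["is_bio_mean"]]
        .groupby("condition")["cy5_per_cell"]
        .mean()
        .to_dict()
    )
    result = {"n_fovs_retained": len(measurements), "cy5_per_cell_by_condition": per_condition}
    io.write_json(result, out / "imaging_result.json")
    report["imaging"] = result


def _stats(config: dict, out: Path, seed: int, report: dict) -> None:
    st_cfg = config.get("stats") or {}
    result: dict[str, Any] = {}

    table = pd.read_csv(out / "imaging_measurements.csv")
    tech = table[~table["is_bio_mean"]].rename(columns={"cy5_per_cell": "value"})
    control = st_cfg.get("control_condition") or sorted(tech["condition"].unique())[0]
    anova = stats.nested_anova_dunnett(tech, control=control)
    result["nested_anova"] = {
        "control": control,
        "f": anova.f_statistic,
        "p": anova.p_value,
        "comparisons": [dataclasses.asdict(c) for c in anova.comparisons],
    }

    control_events = pd.read_csv(out / "flow_control.csv")["intensity"].to_numpy()
    treated_events = pd.read_csv(out / "flow_treated.csv")["intensity"].to_numpy()
    gate = stats.flow_gate(
        control_events, treated_events, gate_quantile=st_cfg.get("gate_quantile", 0.995)
    )
    result["flow"] = dataclasses.asdict(gate)
    io.write_json(result, out / "stats_result.json")
    report["stats"] = result


_STAGE_FUNCS = {
    "simulate": _simulate,
    "fractions": _fractions,
    "proteomics": _proteomics,
    "imaging": _imaging,
    "stats": _stats,
}
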