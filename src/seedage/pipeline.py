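"""End-to-end pipeline: redox → viability → qPCR → arrays → consolidated report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arrays as _arrays
from . import qpcr as _qpcr
from . import redox as _redox
from . import viability as _viability
from .errors import SchemaError, SeedageError, StageError
from .io import PipelineConfig, read_table, write_table

log = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline"]

STAGES = ("redox", "viability", "qpcr", "array")


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "skipped": sorted(self.skipped),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _samples_from_table(df: pd.DataFrame, config: PipelineConfig) -> list[_redox.RedoxSample]:
    from .simulate import DEFAULT_SPECIES_MAP

    species_map = {k: tuple(v) for k, v in config.species_map.items()} or DEFAULT_SPECIES_MAP
    species_to_couple = {}
    for couple, (thiol, dis) in species_map.items():
        species_to_couple[thiol] = (couple, 0)
        species_to_couple[dis] = (couple, 1)
    samples = []
    for (t, rep), grp in df.groupby(["time_days", "replicate"], sort=True):
        amounts: dict[str, list[float]] = {}
        for row in grp.itertuples():
            if row.species not in species_to_couple:
                log.warning("species '%s' not mapped to any couple; ignored", row.species)
                continue
            couple, pos = species_to_couple[row.species]
            pair = amounts.setdefault(couple, [0.0, 0.0])
            pair[pos] = row.amount_umol_per_gDW
        samples.append(
            _redox.RedoxSample(
                time_days=float(t),
                replicate_id=str(rep),
                amounts={c: (v[0], v[1]) for c, v in amounts.items()},
                hydration_mL_per_gDW=config.hydration_mL_per_gDW,
            )
        )
    return samples


def _stage_redox(config: PipelineConfig, outdir: Path) -> dict:
    df = read_table(config.redox_table, "redox")
    registry = _redox.default_couple_registry(config.couple_potentials_mV)
    log.info(
        "redox stage: hydration=%.4f mL/gDW, T=%.2f K, pH=%.2f, registry=%s",
        config.hydration_mL_per_gDW,
        config.temperature_K,
        config.pH,
        {k: v.standard_potential_mV for k, v in registry.items()},
    )
    samples = _samples_from_table(df, config)
    potentials = _redox.potentials_table(
        samples,
        registry,
        temperature_K=config.temperature_K,
        pH=config.pH,
        detection_limit_M=config.detection_limit_M,
    )
    env = _redox.redox_environment_table(potentials)
    write_table(potentials, outdir / "redox_potentials.csv")
    write_table(env, outdir / "redox_environment.csv")
    e_summary = _redox.summarize_by_time(potentials, "E_mV", by=("time_days", "couple"))
    env_summary = _redox.summarize_by_time(env, "redox_environment_mV_M")
    write_table(e_summary, outdir / "redox_potentials_summary.csv")
    write_table(env_summary, outdir / "redox_environment_summary.csv")
    return {
        "n_samples": len(samples),
        "couples": sorted(potentials["couple"].unique()),
        "redox_environment_by_time": {
            f"{r.time_days:g}": round(float(r.mean), 6) for r in env_summary.itertuples()
        },
    }


def _stage_viability(config: PipelineConfig, outdir: Path) -> dict:
    df = read_table(config.germination_table, "germination")
    records = [
        _viability.GerminationRecord(dose=r.dose, n_tested=int(r.n_tested), n_germinated=int(r.n_germinated))
        for r in df.itertuples()
    ]
    model = _viability.fit_probit(records)
    summary: dict = {
        "alpha": model.alpha,
        "beta": model.beta,
        "converged": model.converged,
        "n_obs": model.n_obs,
    }
    if model.converged:
        summary["se_alpha"] = model.se_alpha
        summary["se_beta"] = model.se_beta
        zone = _viability.dose_at_quantile(
            model, p=0.5, level=config.probit_level, method=config.probit_ci_method
        )
        summary["zone"] = {
            "dose50": zone.dose50,
            "lower": zone.lower,
            "upper": zone.upper,
            "level": zone.level,
            "method": zone.method,
        }
    else:
        summary["diagnostics"] = model.diagnostics
    with open(outdir / "viability_probit.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
    return summary


def _stage_qpcr(config: PipelineConfig, outdir: Path) -> dict:
    df = read_table(config.qpcr_table, "qpcr")
    curves = []
    rows = []
    for (sample_id, gene), grp in df.groupby(["sample_id", "gene"], sort=True):
        grp = grp.sort_values("cycle")
        curve = _qpcr.AmplificationCurve(
            sample_id=str(sample_id),
            gene=str(gene),
            cycles=grp["cycle"].to_numpy(dtype=float),
            fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            spiked=bool(grp["spiked"].iloc[0]),
        )
        curves.append(curve)
        fit = _qpcr.fit_amplification_sigmoid(curve)
        ec = _qpcr.estimate_efficiency_ct(curve, fit, method=config.efficiency_method)
        rows.append(
            {
                "gene": gene,
                "time_days": float(grp["time_days"].iloc[0]),
                "replicate": str(grp["replicate"].iloc[0]),
                "efficiency": ec.efficiency,
                "ct": ec.ct,
            }
        )
    eff_ct = pd.DataFrame(rows)
    write_table(eff_ct, outdir / "qpcr_efficiency_ct.csv")
    ratios = _qpcr.expression_ratios_table(eff_ct, config.reference_gene, config.control_time_days)
    write_table(ratios, outdir / "qpcr_ratios.csv")
    ratio_summary = (
        ratios.groupby(["gene", "time_days"])["ratio"].agg(["mean", "count"]).reset_index()
    )
    spike = _qpcr.spike_in_check(curves, config.reference_gene)
    stability = {}
    gene_eff = eff_ct.groupby("gene")["efficiency"].median()
    ct_ctrl = eff_ct[eff_ct["time_days"] == config.control_time_days].groupby("gene")["ct"].mean()
    for gene, grp in eff_ct.groupby("gene"):
        # non-normalised expression per reaction: E^(Ct_ctrl - Ct); the
        # regression runs over every replicate so the slope test sees the
        # replicate-to-replicate error, not just the time-point means
        rel = gene_eff[gene] ** (ct_ctrl[gene] - grp["ct"])
        if grp["time_days"].nunique() >= 3:
            rep = _qpcr.reference_stability(
                grp["time_days"].to_numpy(), rel.to_numpy(), gene=str(gene),
                p_threshold=config.stability_p_threshold,
            )
            stability[str(gene)] = {
                "slope_per_day": rep.slope_per_day,
                "p_value": rep.slope_p_value,
                "r_squared": rep.r_squared,
                "stable": rep.stable,
            }
    with open(outdir / "qpcr_stability.json", "w") as fh:
        json.dump(stability, fh, sort_keys=True, indent=2)
    return {
        "n_reactions": len(rows),
        "reference_gene": config.reference_gene,
        "spike_in_ok": spike.ok,
        "spike_in_violations": spike.violations,
        "ratios_by_gene_time": {
            f"{r.gene}@{r.time_days:g}": round(float(r.mean), 6) for r in ratio_summary.itertuples()
        },
        "stability": stability,
    }


def _stage_array(config: PipelineConfig, outdir: Path) -> dict:
    df = read_table(config.array_table, "array")
    df = df.rename(columns={"block": "print_tip_block"})
    normalized = []
    for (t, a), grp in df.groupby(["time_days", "array_id"], sort=True):
        normalized.append(
            _arrays.normalize_within_array(
                grp, span=config.loess_span, min_block_spots=config.min_block_spots
            )
        )
    norm_df = pd.concat(normalized, ignore_index=True)
    # between-array scaling within each time point's replicate set
    scaled_parts = []
    for t, grp in norm_df.groupby("time_days", sort=True):
        arrays_m = {a: g["M"].to_numpy() for a, g in grp.groupby("array_id", sort=True)}
        scaled = _arrays.scale_between_arrays(arrays_m)
        for a, g in grp.groupby("array_id", sort=True):
            part = g.copy()
            part["M"] = scaled[a]
            scaled_parts.append(part)
    scaled_df = pd.concat(scaled_parts, ignore_index=True)
    per_array = _arrays.average_replicate_spots(scaled_df)
    results = _arrays.moderated_tests(per_array, min_reps=config.min_replicates)
    calls, counts = _arrays.call_de(
        results,
        fdr_level=config.fdr_level,
        lfc_threshold=config.fold_threshold_log2,
        min_reps=config.min_replicates,
    )
    write_table(results, outdir / "array_moderated_tests.csv")
    write_table(calls, outdir / "array_de_calls.csv")

    summary: dict = {
        "n_probes_tested": int(results["probe_id"].nunique()),
        "de_counts": {
            f"{r.time_days:g}": {"up": int(r.up), "down": int(r.down)} for r in counts.itertuples()
        },
    }
    times = sorted(calls["time_days"].unique())
    if len(times) == 3:
        venns = {}
        for direction in ("up", "down"):
            sets = {
                f"{t:g}": set(calls[(calls["time_days"] == t) & (calls["direction"] == direction)]["probe_id"])
                for t in times
            }
            venn = _arrays.venn_partition(sets)
            venns[direction] = {"+".join(k) if isinstance(k, tuple) else k: v for k, v in venn.items()}
        summary["venn"] = venns
        with open(outdir / "array_venn.json", "w") as fh:
            json.dump(venns, fh, sort_keys=True, indent=2)
    de_probes = sorted(set(calls[calls["direction"] != "none"]["probe_id"]))
    if de_probes:
        profiles = (
            results[results["probe_id"].isin(de_probes)]
            .pivot_table(index="probe_id", columns="time_days", values="mean_M")
        )
        k = min(config.cluster_k, len(profiles.dropna()))
        if k >= 1 and len(profiles.dropna()) >= 1:
            model = _arrays.cluster_profiles(profiles, K=k)
            assign = pd.DataFrame(
                {"probe_id": list(model.assignments), "cluster": list(model.assignments.values())}
            )
            write_table(assign, outdir / "array_clusters.csv")
            sizes = assign["cluster"].value_counts().sort_index()
            summary["clusters"] = {"K": model.K, "sizes": {int(k_): int(v) for k_, v in sizes.items()}}
    return summary


_STAGE_FN = {
    "redox": (_stage_redox, "redox_table"),
    "viability": (_stage_viability, "germination_table"),
    "qpcr": (_stage_qpcr, "qpcr_table"),
    "array": (_stage_array, "array_table"),
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> RunReport:
    """Execute the requested stages and write outputs plus the consolidated report.

    Stages whose input table is not configured are skipped with a logged
    notice.  Any stage error aborts the run with :class:`StageError` naming
    the stage.  The report is byte-for-byte reproducible for a fixed config
    and inputs (no timestamps).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    for stage in stages:
        fn, input_attr = _STAGE_FN[stage]
        if getattr(config, input_attr) is None:
            log.info("stage '%s' skipped: no %s configured", stage, input_attr)
            report.skipped.append(stage)
            continue
        try:
            report.stages[stage] = fn(config, outdir)
        except SchemaError:
            raise  # input-validation errors keep their identity (exit code 2)
        except SeedageError as exc:
            raise StageError(stage, str(exc)) from exc
    config.to_yaml(outdir / "config_used.yaml")
    with open(outdir / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
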