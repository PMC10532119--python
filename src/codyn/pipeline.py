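"""End-to-end orchestration of the coculture analysis stages.

``run_all`` reads the three input CSVs, fits every growth curve, runs the
monoculture species/strain ANOVA, classifies every coculture, assembles
and clusters the four interaction matrices with bootstrap stability, and
computes cytometry fold changes.  Every output file starts with a ``#``
comment carrying the configuration hash, so a rerun with the identical
configuration is byte-identical.  Logs go to stderr only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, foldchange, growth, interactions, io_plate, monoculture
from .config import PipelineConfig
from .errors import AnalysisError, CodynError

log = logging.getLogger(__name__)

__all__ = ["RunResult", "fit_dataset", "run_all", "report"]


@dataclass
class RunResult:
    """Bundle of all stage outputs of one pipeline run."""

    config: PipelineConfig
    config_hash: str
    outdir: Path
    files: dict
    growth_params: pd.DataFrame
    monoculture_stats: pd.DataFrame
    species_groups: pd.DataFrame
    records: list
    summary: pd.DataFrame
    matrices: dict
    stabilities: dict
    fold_changes: pd.DataFrame
    fold_records: list


def _sub_seed(seed: int, *key: int) -> int:
    state = np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0]
    return int(state % (2**31))


def fit_dataset(joined, config: PipelineConfig) -> pd.DataFrame:
    """Extract the four kinetic parameters for every joined well."""
    fit_config = growth.FitConfig(
        latency_threshold=config.latency_threshold,
        window_h=config.window_h,
        interpolate_latency=config.interpolate_latency,
        od_offset=config.od_offset,
        restart_seed=_sub_seed(config.seed, 4),
    )
    rows = []
    for desc, curve in joined:
        gp = growth.extract_growth_parameters(curve, fit_config, replicate=desc.replicate)
        rows.append({
            "culture_id": desc.culture_id, "kind": desc.kind,
            "strain_a": desc.strain_a, "strain_b": desc.strain_b,
            "species_a": desc.species_a, "species_b": desc.species_b,
            "replicate": desc.replicate, "run": desc.run,
            "latency": gp.latency_h, "r": gp.r, "max_od": gp.max_od, "auc": gp.auc,
            "K": gp.K, "N0": gp.N0, "rss": gp.rss, "converged": gp.converged,
            "auc_trapezoid": gp.auc_trapezoid,
        })
    df = pd.DataFrame(rows)
    n_fail = int((~df["converged"]).sum())
    if n_fail:
        log.warning("%d of %d curves did not converge", n_fail, len(df))
    return df


def _monoculture_stage(params: pd.DataFrame, config: PipelineConfig):
    mono = params[params["kind"] == "monoculture"].rename(
        columns={"strain_a": "strain", "species_a": "species"})
    stats_rows, group_rows = [], []
    for parameter in interactions.PARAMETERS:
        sub = mono[["species", "strain", parameter]].dropna()
        try:
            res = monoculture.nested_anova(sub[parameter].to_numpy(),
                                           sub["species"].to_numpy(),
                                           sub["strain"].to_numpy(), parameter)
        except AnalysisError as exc:
            log.warning("monoculture ANOVA skipped for %s: %s", parameter, exc)
            continue
        stats_rows.append({
            "parameter": parameter,
            "species_F": res.species_F, "species_p": res.species_p,
            "strain_F": res.strain_F, "strain_p": res.strain_p,
        })
        letters = res.letter_groups(config.alpha)
        for sp in sorted(res.species_means):
            group_rows.append({
                "parameter": parameter, "species": sp,
                "mean": res.species_means[sp], "sd": res.species_sds[sp],
                "n": res.species_n[sp], "group": letters[sp],
            })
    return pd.DataFrame(stats_rows), pd.DataFrame(group_rows)


def run_all(config: PipelineConfig) -> RunResult:
    """Run every stage; deterministic given the configuration (incl. seed)."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    header = f"codyn output\nconfig_hash={chash}"
    log.info("configuration:\n%s", config.to_yaml())

    curves = io_plate.read_timeseries(indir / "timeseries.csv")
    layout = io_plate.read_layout(indir / "layout.csv")
    cyto_path = indir / "cytometry.csv"
    samples = io_plate.read_cytometry(cyto_path) if cyto_path.exists() else []
    joined = io_plate.join(curves, layout)
    log.info("stage io: %d wells joined, %d cytometry samples", len(joined), len(samples))

    params = fit_dataset(joined, config)
    files = {}
    files["growth_parameters"] = _write(params.rename(columns={
        "latency": "latency_h", "r": "r_per_h", "auc": "auc_odh"}),
        outdir / "growth_parameters.csv", header)

    mono_stats, species_groups = _monoculture_stage(params, config)
    files["monoculture_stats"] = _write(mono_stats, outdir / "monoculture_stats.csv", header)
    files["species_groups"] = _write(species_groups, outdir / "species_groups.csv", header)

    records = interactions.analyze_all(params, alpha=config.alpha, bh_correct=config.bh_correct)
    summary = interactions.outcome_summary(records)
    files["interactions"] = _write(interactions.records_to_frame(records),
                                   outdir / "interactions.csv", header)
    files["outcome_summary"] = _write(summary, outdir / "outcome_summary.csv", header)

    matrices, stabilities = {}, {}
    for p_i, parameter in enumerate(interactions.PARAMETERS):
        try:
            mat = clustering.build_matrix(records, parameter)
        except CodynError as exc:
            log.warning("matrix stage skipped for %s: %s", parameter, exc)
            continue
        k = min(config.cluster_k, mat.n)
        assignments, Z = clustering.cluster_matrix(mat, k)
        stab = clustering.bootstrap_stability(
            mat, k, config.bootstrap_B, method=config.bootstrap_method,
            seed=_sub_seed(config.seed, 10, p_i), subset_fraction=config.subset_fraction)
        matrices[parameter] = mat
        stabilities[parameter] = stab
        mdf = pd.DataFrame(mat.values, index=list(mat.strains), columns=list(mat.strains))
        files[f"matrix_{parameter}"] = _write(mdf.reset_index(names="strain"),
                                              outdir / f"matrix_{parameter}.csv", header)
        cdf = pd.DataFrame({"strain": list(mat.strains), "species": list(mat.species),
                            "cluster": [assignments[s] for s in mat.strains]})
        files[f"clusters_{parameter}"] = _write(cdf, outdir / f"clusters_{parameter}.csv", header)
        sdf = pd.DataFrame([
            {"cluster": c, "jaccard": j, "method": stab.method, "B": stab.B,
             "n_members": sum(1 for v in stab.assignments.values() if v == c),
             "dissolved": j < clustering.DISSOLVED_THRESHOLD}
            for c, j in sorted(stab.jaccard.items())
        ])
        files[f"stability_{parameter}"] = _write(sdf, outdir / f"stability_{parameter}.csv", header)
        tree_path = outdir / f"tree_{parameter}.nwk"
        tree_path.write_text(f"# {header.replace(chr(10), ' | ')}\n"
                             + clustering.linkage_to_newick(Z, list(mat.strains)) + "\n",
                             encoding="utf-8")
        files[f"tree_{parameter}"] = tree_path

    fc_df, fc_records = (pd.DataFrame(), [])
    if samples:
        fc_df, fc_records = foldchange.fold_change_table(samples, layout,
                                                         alpha=config.alpha,
                                                         scale=config.foldchange_scale)
        agg = pd.DataFrame([
            {"focal": r.focal, "partner": r.partner, "mean_fc": r.mean, "sd_fc": r.sd,
             "p_value": r.p_value, "n": r.n, "significant": r.significant(config.alpha)}
            for r in fc_records
        ])
        merged = fc_df.merge(agg, on=["focal", "partner"], how="left")
        files["fold_changes"] = _write(merged, outdir / "fold_changes.csv", header)

    files["config_echo"] = outdir / "config_echo.yaml"
    config.to_yaml(files["config_echo"])

    result = RunResult(config=config, config_hash=chash, outdir=outdir, files=files,
                       growth_params=params, monoculture_stats=mono_stats,
                       species_groups=species_groups, records=records, summary=summary,
                       matrices=matrices, stabilities=stabilities,
                       fold_changes=fc_df, fold_records=fc_records)
    report_path = outdir / "report.txt"
    report_path.write_text(report(result), encoding="utf-8")
    files["report"] = report_path
    return result


def _write(df: pd.DataFrame, path: Path, header: str) -> Path:
    io_plate._write_frame(df, path, header)
    return path


def report(result: RunResult) -> str:
    """Human-readable run summary (outcome table, clusters, fold changes)."""
    lines = [
        "codyn pipeline report",
        f"config_hash: {result.config_hash}",
        "",
        "== Coculture outcome classes (count / %) ==",
    ]
    if len(result.summary):
        piv = result.summary.pivot(index="parameter", columns="outcome", values="count")
        n_tot = result.summary.groupby("parameter")["n_total"].first()
        lines.append(f"{'parameter':<10}" + "".join(f"{o:>8}" for o in "ABCD") + f"{'total':>8}")
        for parameter in piv.index:
            row = "".join(f"{int(piv.loc[parameter, o]):>8d}" for o in "ABCD")
            lines.append(f"{parameter:<10}{row}{int(n_tot[parameter]):>8d}")
    else:
        lines.append("(no interaction records)")
    lines += ["", "== Monoculture species/strain effects =="]
    if len(result.monoculture_stats):
        for _, r in result.monoculture_stats.iterrows():
            lines.append(f"{r['parameter']:<10} species p={r['species_p']:.3g}   "
                         f"strain p={r['strain_p']:.3g}")
    else:
        lines.append("(not computed)")
    lines += ["", "== Cluster stability (mean Jaccard; <0.5 dissolved) =="]
    for parameter, stab in result.stabilities.items():
        jac = "  ".join(f"c{c}={j:.2f}" for c, j in sorted(stab.jaccard.items()))
        lines.append(f"{parameter:<10} k={stab.k} method={stab.method} B={stab.B}: {jac}")
    if not result.stabilities:
        lines.append("(not computed)")
    lines += ["", "== Significant fold changes (vs 1) =="]
    sig = [r for r in result.fold_records if r.significant(result.config.alpha)]
    for r in sorted(sig, key=lambda r: r.p_value)[:25]:
        lines.append(f"{r.focal:<10} with {r.partner:<10} fc={r.mean:.2f}±{r.sd:.2f} p={r.p_value:.3g}")
    if not sig:
        lines.append("(none)")
    lines.append("")
    return "\n".join(lines)
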