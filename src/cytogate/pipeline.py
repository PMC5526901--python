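"""Config-driven orchestration: generate -> gate -> cluster -> annotate ->
evaluate, with a click CLI (console script ``cytogate``).

A single YAML/JSON config document drives every stage; all randomness
derives from one seed, and every report carries the config hash and seed,
so (config, seed) determines all outputs byte-for-byte.

Stages write plain-text artifacts into the output directory:

* ``samples.csv``      manifest (sample_id, duplicate, file, truth)
* ``*.fcs``            simulated samples (+ ``*_labels.csv`` sidecars)
* ``retention.csv``    per-sample, per-step DAG retention
* ``gated_*.fcs``      prefiltered events
* ``model_*.json``     cluster models (or ``template.json``)
* ``assignment_*.csv`` per-event cluster assignment
* ``population_calls.csv``, ``summary.csv``, ``lod.csv``
* ``pipeline.log``     stage counts, warnings, rule-based exclusions
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .annotate import call_multimer_population, categorize_expression, compute_frequencies, mean_of_duplicates
from .cluster import ClusterModel, GridDensityCluster, assign_to_centroids
from .io import EventTable, arcsinh_transform, read_fcs, read_label_sidecar, write_fcs, write_label_sidecar
from .prefilter import DAGPrefilter
from .simulate import (
    DONOR_PRESETS,
    SPIKEIN_DESIGNS,
    make_dilution_series,
    preset_populations,
    preset_profile,
    simulate_donor,
    true_frequencies,
)
from .stats import cv, lod_report
from .workflow import AutoGatingPipeline, analyze_with_template, two_stage_analyze

logger = logging.getLogger(__name__)

MODES = ("single-stage", "two-stage", "template")

#: Negative-control exclusion rule: a sample whose called multimer+
#: frequency exceeds this share of live single lymphocytes while its truth
#: is zero is flagged as an extreme outlier in the log.
NEGATIVE_CONTROL_EXCLUSION_PCT = 20.0

DEFAULT_CONFIG = {
    "mode": "single-stage",
    "seed": 0,
    "simulate": {
        "kind": "donor",
        "donor": "spikein1-positive",
        "design": "spikein1",
        "n_events": 200_000,
        "duplicates": 2,
    },
    "analysis": {
        "multimer_role": "multimer-PE",
        "cofactor": 150.0,
        "cluster_roles": None,
        "bins": 16,
        "min_density": None,
        "max_clusters": 100,
        "threshold_events": 10,
        "n_per_sample": 250_000,  # template-mode consensus share
    },
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config document must be a mapping")
    return cfg


def _merged(cfg: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def validate_config(cfg: dict) -> dict:
    """Schema-check a config; returns the merged config or raises
    ConfigError naming the offending field."""
    cfg = _merged(cfg)
    if cfg["mode"] not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {cfg['mode']!r}")
    sim = cfg["simulate"]
    if sim["kind"] not in ("donor", "spikein"):
        raise ConfigError(f"simulate.kind must be donor|spikein, got {sim['kind']!r}")
    if sim["kind"] == "donor" and sim["donor"] not in DONOR_PRESETS:
        raise ConfigError(f"unknown donor preset {sim['donor']!r}")
    if sim["kind"] == "spikein" and sim["design"] not in SPIKEIN_DESIGNS:
        raise ConfigError(f"unknown spike-in design {sim['design']!r}")
    if int(sim["n_events"]) < 1 or int(sim["duplicates"]) < 1:
        raise ConfigError("simulate.n_events and simulate.duplicates must be >= 1")
    ana = cfg["analysis"]
    roles = ana.get("cluster_roles")
    if roles is not None:
        if sim["kind"] == "donor":
            panel = set(DONOR_PRESETS[sim["donor"]]["panel"])
        else:
            donor = "spikein1-positive" if sim["design"] == "spikein1" else "spikein2-positive"
            panel = set(DONOR_PRESETS[donor]["panel"])
        for role in roles:
            if role not in panel:
                raise ConfigError(
                    f"analysis.cluster_roles references role {role!r} absent "
                    f"from the panel {sorted(panel)}"
                )
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------


def _log(outdir: Path, lines: list[str]) -> None:
    with open(outdir / "pipeline.log", "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def stage_simulate(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Generate samples per config; write FCS + label sidecars + manifest."""
    cfg = validate_config(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    rows = []
    if sim["kind"] == "donor":
        pops = preset_populations(sim["donor"])
        profile = preset_profile(sim["donor"])
        for dup in range(int(sim["duplicates"])):
            sub_seed = (seed * 9_973 + dup) % (2**31)
            table = simulate_donor(pops, profile, int(sim["n_events"]), sub_seed)
            truth = true_frequencies(table)
            stem = f"sample_{sim['donor']}_{dup}"
            write_fcs(table, outdir / f"{stem}.fcs")
            write_label_sidecar(table, outdir / f"{stem}_labels.csv")
            rows.append(dict(sample_id=sim["donor"], duplicate=dup,
                             file=f"{stem}.fcs", theoretical_pct=float("nan"),
                             true_pct_lsl=truth["pct_of_live_single"],
                             true_pct_cd8=truth["pct_of_cd8"], seed=sub_seed))
    else:
        design = SPIKEIN_DESIGNS[sim["design"]]
        design = type(design)(**{**design.__dict__, "seed": seed,
                                 "n_events_per_sample": int(sim["n_events"]),
                                 "duplicates": int(sim["duplicates"])})
        pos_name = f"{sim['design']}-positive"
        neg_name = f"{sim['design']}-negative"
        pos = simulate_donor(preset_populations(pos_name), preset_profile(pos_name),
                             int(sim["n_events"]), (seed * 7_919 + 1) % (2**31))
        neg = simulate_donor(preset_populations(neg_name), preset_profile(neg_name),
                             int(sim["n_events"]), (seed * 7_919 + 2) % (2**31))
        for s in make_dilution_series(design, pos, neg):
            stem = f"sample_step{s.step}_{s.duplicate}"
            write_fcs(s.table, outdir / f"{stem}.fcs")
            write_label_sidecar(s.table, outdir / f"{stem}_labels.csv")
            truth = true_frequencies(s.table)
            rows.append(dict(sample_id=f"step{s.step}", duplicate=s.duplicate,
                             file=f"{stem}.fcs", theoretical_pct=s.theoretical_pct,
                             true_pct_lsl=truth["pct_of_live_single"],
                             true_pct_cd8=truth["pct_of_cd8"], seed=s.seed))
    manifest = pd.DataFrame(rows)
    manifest.insert(0, "config_hash", config_hash(cfg))
    manifest.to_csv(outdir / "samples.csv", index=False)
    _log(outdir, [f"simulate: {len(rows)} samples, config {config_hash(cfg)}, "
                  f"seed {seed}"])
    return manifest


def _load_sample(outdir: Path, filename: str) -> EventTable:
    panel_map = {
        "FSC-A": "FSC-A", "FSC-H": "FSC-H", "SSC-A": "SSC-A",
        "LiveDead": "viability", "Dump": "dump", "CD3": "CD3", "CD8": "CD8",
        "Multimer-PE": "multimer-PE", "Multimer-APC": "multimer-APC",
    }
    table = read_fcs(outdir / filename, role_map=panel_map)
    sidecar = outdir / (Path(filename).stem + "_labels.csv")
    if sidecar.exists():
        table = read_label_sidecar(table, sidecar)
    return table


def stage_gate(cfg: dict, outdir: Path) -> pd.DataFrame:
    """DAG-prefilter every sample in the manifest; write gated FCS files
    and the per-step retention report."""
    cfg = validate_config(cfg)
    ana = cfg["analysis"]
    manifest = pd.read_csv(outdir / "samples.csv")
    reports = []
    for _, row in manifest.iterrows():
        table = _load_sample(outdir, row["file"])
        prepared = arcsinh_transform(table, ana["cofactor"])
        pre = DAGPrefilter().fit(prepared)
        gated = pre._fit_result
        stem = "gated_" + Path(row["file"]).stem
        write_fcs(gated, outdir / f"{stem}.fcs")
        if gated.labels is not None:
            write_label_sidecar(gated, outdir / f"{stem}_labels.csv")
        rep = pre.report_.copy()
        rep.insert(0, "sample_id", row["sample_id"])
        rep.insert(1, "duplicate", row["duplicate"])
        reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    report.insert(0, "config_hash", config_hash(cfg))
    report.to_csv(outdir / "retention.csv", index=False)
    _log(outdir, [f"gate: {len(manifest)} samples prefiltered"])
    return report


def stage_cluster(cfg: dict, outdir: Path) -> None:
    """Cluster gated samples (per mode); write models and assignments."""
    cfg = validate_config(cfg)
    ana = cfg["analysis"]
    manifest = pd.read_csv(outdir / "samples.csv")
    if cfg["mode"] == "template":
        gated = [_load_sample(outdir, "gated_" + Path(f).stem + ".fcs")
                 for f in manifest["file"]]
        for g in gated:
            g.transform_state = "arcsinh"  # FCS stores no transform keyword
        result = analyze_with_template(
            gated, n_per_sample=int(ana["n_per_sample"]), seed=int(cfg["seed"]),
            cluster_roles=ana["cluster_roles"], bins=int(ana["bins"]),
            min_density=ana["min_density"], max_clusters=int(ana["max_clusters"]),
            multimer_role=ana["multimer_role"],
            threshold_events=int(ana["threshold_events"]),
        )
        result.template.to_json(outdir / "template.json")
        for (_, row), g in zip(manifest.iterrows(), gated):
            assignment, _ = assign_to_centroids(g, result.template)
            pd.DataFrame({"event_id": g.event_ids, "cluster": assignment}).to_csv(
                outdir / f"assignment_{Path(row['file']).stem}.csv", index=False)
        _log(outdir, [f"cluster: template with {result.template.n_clusters} "
                      "clusters"])
        return
    for _, row in manifest.iterrows():
        stem = Path(row["file"]).stem
        g = _load_sample(outdir, f"gated_{stem}.fcs")
        g.transform_state = "arcsinh"
        clusterer = GridDensityCluster(
            roles=ana["cluster_roles"], bins=int(ana["bins"]),
            min_density=ana["min_density"], max_clusters=int(ana["max_clusters"]),
        ).fit(g)
        clusterer.model_.to_json(outdir / f"model_{stem}.json")
        pd.DataFrame({"event_id": g.event_ids, "cluster": clusterer.labels_}).to_csv(
            outdir / f"assignment_{stem}.csv", index=False)
    _log(outdir, [f"cluster: {len(manifest)} per-sample models"])


def stage_annotate(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Apply the cutoff rule to every model; write population_calls.csv."""
    cfg = validate_config(cfg)
    ana = cfg["analysis"]
    manifest = pd.read_csv(outdir / "samples.csv")
    rows = []
    template = None
    if cfg["mode"] == "template":
        template = ClusterModel.from_json(outdir / "template.json")
        categories = categorize_expression(template)
        ids = call_multimer_population(categories, ana["multimer_role"])
    for _, row in manifest.iterrows():
        stem = Path(row["file"]).stem
        g = _load_sample(outdir, f"gated_{stem}.fcs")
        g.transform_state = "arcsinh"
        assignment = pd.read_csv(outdir / f"assignment_{stem}.csv")["cluster"].to_numpy()
        if template is None:
            model = ClusterModel.from_json(outdir / f"model_{stem}.json")
            categories = categorize_expression(model)
            ids = call_multimer_population(categories, ana["multimer_role"])
            n_clusters = model.n_clusters
        else:
            n_clusters = template.n_clusters
        counts = np.bincount(assignment, minlength=n_clusters)
        cd8 = None
        if g.labels is not None:
            from .simulate import CD8_LABELS
            n_cd8 = int(np.isin(g.labels, list(CD8_LABELS)).sum())
            cd8 = n_cd8 if n_cd8 > 0 else None
        call = compute_frequencies(ids, counts, live_single_count=g.n_events,
                                   cd8_count=cd8,
                                   threshold_events=int(ana["threshold_events"]))
        rows.append(dict(
            sample_id=row["sample_id"], duplicate=row["duplicate"],
            event_count=call.event_count,
            denominator_live_single=call.denominator_live_single,
            denominator_cd8=call.denominator_cd8,
            freq_of_lymphocytes=call.freq_of_lymphocytes,
            freq_of_cd8=call.freq_of_cd8, detected=call.detected,
            clusters_selected=";".join(map(str, sorted(call.multimer_cluster_ids))),
            threshold_events=call.threshold_events,
        ))
    calls = pd.DataFrame(rows)
    calls.insert(0, "config_hash", config_hash(cfg))
    calls.to_csv(outdir / "population_calls.csv", index=False)
    _log(outdir, [f"annotate: {len(rows)} calls"])
    return calls


def stage_evaluate(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Duplicate-average the calls; write summary.csv (and lod.csv for
    spike-in runs).  Flags rule-based negative-control exclusions."""
    cfg = validate_config(cfg)
    manifest = pd.read_csv(outdir / "samples.csv")
    calls = pd.read_csv(outdir / "population_calls.csv")
    merged = calls.merge(
        manifest[["sample_id", "duplicate", "theoretical_pct", "true_pct_lsl"]],
        on=["sample_id", "duplicate"],
    )
    exclusions = []
    for _, r in merged.iterrows():
        if (r["true_pct_lsl"] == 0 or r["theoretical_pct"] == 0) and \
                r["freq_of_lymphocytes"] > NEGATIVE_CONTROL_EXCLUSION_PCT:
            exclusions.append(f"exclude {r['sample_id']}/{r['duplicate']}: "
                              f"negative control called at "
                              f"{r['freq_of_lymphocytes']:.2f}% of live single "
                              "lymphocytes")
    summary_rows = []
    for sid, grp in merged.groupby("sample_id", sort=False):
        freqs = grp["freq_of_lymphocytes"].tolist()
        summary_rows.append(dict(
            sample_id=sid,
            n_duplicates=len(freqs),
            mean_freq_of_lymphocytes=mean_of_duplicates(freqs),
            cv_pct=cv(freqs) if len(freqs) >= 2 and np.mean(freqs) > 0 else float("nan"),
            theoretical_pct=grp["theoretical_pct"].iloc[0],
            true_pct_lsl=grp["true_pct_lsl"].mean(),
            all_detected=bool(grp["detected"].all()),
        ))
    summary = pd.DataFrame(summary_rows)
    summary.insert(0, "config_hash", config_hash(cfg))
    summary.to_csv(outdir / "summary.csv", index=False)
    if cfg["simulate"]["kind"] == "spikein":
        series = [
            (grp["theoretical_pct"].iloc[0],
             grp["freq_of_lymphocytes"].tolist(),
             grp["detected"].tolist())
            for _, grp in merged.groupby("sample_id", sort=False)
        ]
        rep = lod_report(series)
        rep.table.to_csv(outdir / "lod.csv", index=False)
        _log(outdir, [f"evaluate: limit of detection "
                      f"{rep.lowest_detected_pct}% of live single lymphocytes"])
    _log(outdir, [f"evaluate: {len(summary_rows)} samples summarized"]
         + exclusions)
    return summary


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None) -> pd.DataFrame:
    """Execute the configured mode end to end; returns the summary table."""
    cfg = validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pipeline.log").write_text(
        f"cytogate run: mode={cfg['mode']} config={config_hash(cfg)} "
        f"seed={cfg['seed']}\n")
    stage_simulate(cfg, outdir)
    stage_gate(cfg, outdir)
    if cfg["mode"] == "two-stage":
        # two-stage clusters scatter first; it runs on the raw samples
        manifest = pd.read_csv(outdir / "samples.csv")
        ana = cfg["analysis"]
        rows = []
        for _, row in manifest.iterrows():
            table = _load_sample(outdir, row["file"])
            call = two_stage_analyze(
                table, cofactor=ana["cofactor"], min_density=ana["min_density"],
                multimer_role=ana["multimer_role"],
                threshold_events=int(ana["threshold_events"]),
            )
            rows.append(dict(
                sample_id=row["sample_id"], duplicate=row["duplicate"],
                event_count=call.event_count,
                denominator_live_single=call.denominator_live_single,
                denominator_cd8=call.denominator_cd8,
                freq_of_lymphocytes=call.freq_of_lymphocytes,
                freq_of_cd8=call.freq_of_cd8, detected=call.detected,
                clusters_selected=";".join(map(str, sorted(call.multimer_cluster_ids))),
                threshold_events=call.threshold_events,
            ))
        calls = pd.DataFrame(rows)
        calls.insert(0, "config_hash", config_hash(cfg))
        calls.to_csv(outdir / "population_calls.csv", index=False)
    else:
        stage_cluster(cfg, outdir)
        stage_annotate(cfg, outdir)
    return stage_evaluate(cfg, outdir)


# ----------------------------------------------------------------------
# CLI
# ----------------------------------------------------------------------


def _cli_config(config: str | None) -> dict:
    return load_config(config) if config else {}


@click.group()
@click.option("--verbose", is_flag=True, help="Enable debug logging.")
def main(verbose: bool) -> None:
    """Automated MHC-multimer gating pipeline."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _common(fn):
    fn = click.option("--outdir", type=click.Path(), required=True)(fn)
    fn = click.option("--config", type=click.Path(exists=True), default=None)(fn)
    fn = click.option("--seed", type=int, default=None)(fn)
    return fn


def _prep(config, seed):
    cfg = validate_config(_cli_config(config))
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


@main.command()
@_common
def simulate(config, outdir, seed):
    """Generate synthetic samples into OUTDIR."""
    stage_simulate(_prep(config, seed), Path(outdir))


@main.command()
@_common
def gate(config, outdir, seed):
    """DAG-prefilter the simulated samples in OUTDIR."""
    stage_gate(_prep(config, seed), Path(outdir))


@main.command()
@_common
def cluster(config, outdir, seed):
    """Cluster the gated samples in OUTDIR."""
    stage_cluster(_prep(config, seed), Path(outdir))


@main.command()
@_common
def annotate(config, outdir, seed):
    """Annotate clusters and call multimer+ populations."""
    stage_annotate(_prep(config, seed), Path(outdir))


@main.command()
@_common
def evaluate(config, outdir, seed):
    """Summarize calls (duplicate means, CVs, limit of detection)."""
    stage_evaluate(_prep(config, seed), Path(outdir))


@main.command("run-all")
@_common
@click.option("--mode", type=click.Choice(MODES), default=None)
def run_all(config, outdir, seed, mode):
    """Run the whole pipeline end to end."""
    cfg = _cli_config(config)
    if mode is not None:
        cfg["mode"] = mode
    summary = run_pipeline(cfg, outdir, seed=seed)
    click.echo(summary.to_string(index=False))


if __name__ == "__main__":
    main()
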