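"""End-to-end arms: binding analysis and growth screen.

``run_binding_arm`` chains windowing -> target calling -> condition and
cross-TF set comparison -> promoter motif scanning -> GO enrichment, and
writes per-stage TSVs plus one JSON summary.  ``run_growth_arm`` chains
calibration -> per-well spline fits -> strain aggregation -> BH-corrected
Welch tests with star annotations.  ``run_all`` simulates a complete
study with the synthetic generators and runs both arms; all randomness
flows from its single seed and the summary JSON is byte-deterministic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import read_annotation, read_chrom_sizes
from .calling import CallParameters, TargetCallResult, call_targets
from .compare import compare_conditions, cross_tf_overlap, annotate_known
from .enrichment import GOAnnotationMap, go_enrichment, results_to_frame
from .growth import (
    CalibrationCurve,
    adjust_comparisons,
    calibrate,
    compare_strains,
    comparisons_to_frame,
    curves_from_frame,
    fit_growth,
    read_growth_csv,
)
from .motif import MotifPattern, YRE, promoter_motif_fraction
from .signal import average_tracks, read_signal_track
from .simulate import (
    GrowthTruth,
    SimulationConfig,
    TEST_CALIBRATION,
    simulate_chipexo,
    simulate_go_map,
    simulate_growth,
    simulate_promoters,
)
from .windows import WindowSpec, extract_all_windows, metagene_profile

__all__ = ["BindingArmConfig", "GrowthArmConfig", "run_binding_arm", "run_growth_arm", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (FileNotFoundError, KeyError, ValueError) as exc:
        raise StageError(f"[{name}] {exc}") from exc


@dataclass
class BindingArmConfig:
    annotation: str
    chrom_sizes: str
    # (tf, condition) -> replicate bedGraph paths; replicates averaged base-wise
    tracks: Mapping[tuple[str, str], Sequence[str]]
    outdir: str
    control_condition: str = "control"
    stress_condition: str = "stress"
    params: CallParameters = field(default_factory=CallParameters)
    promoters_fasta: Optional[str] = None
    patterns: Mapping[str, MotifPattern] = field(default_factory=dict)
    go_map: Optional[str] = None
    known_targets: Mapping[str, str] = field(default_factory=dict)
    alpha: float = 0.1
    correction: str = "bonferroni"


def _read_promoters(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def run_binding_arm(config: BindingArmConfig) -> dict:
    """Run the full binding arm; returns the summary dict it also writes."""
    os.makedirs(config.outdir, exist_ok=True)
    genes = _stage("annotation", read_annotation, config.annotation)
    sizes = _stage("annotation", read_chrom_sizes, config.chrom_sizes)
    spec = config.params.window

    calls: dict[tuple[str, str], TargetCallResult] = {}
    summary: dict = {
        "parameters": {
            "threshold_factor": config.params.threshold_factor,
            "upstream_bp": spec.upstream_bp,
            "downstream_bp": spec.downstream_bp,
            "alpha": config.alpha,
            "correction": config.correction,
        },
        "n_genes": len(genes),
        "calls": {},
    }
    for (tf, condition), paths in sorted(config.tracks.items()):
        tracks = [
            _stage("signal", read_signal_track, p, sizes, tf, condition) for p in paths
        ]
        track = average_tracks(tracks)
        profiles = _stage("windows", extract_all_windows, track, genes, spec)
        result = _stage("calling", call_targets, profiles, config.params, tf, condition)
        calls[(tf, condition)] = result
        result.to_frame().to_csv(
            os.path.join(config.outdir, f"{tf}_{condition}_targets.tsv"), sep="\t", index=False
        )
        meta = metagene_profile(profiles, spec)
        pd.DataFrame({"offset": spec.offsets(), "mean_signal": meta}).to_csv(
            os.path.join(config.outdir, f"{tf}_{condition}_metagene.tsv"), sep="\t", index=False
        )
        summary["calls"][f"{tf}_{condition}"] = {
            "n_targets": len(result.targets),
            "background": result.background,
            "threshold": result.threshold,
            "mean_reads_per_target": result.mean_reads_per_target,
        }

    tfs = sorted({tf for tf, _ in calls})
    summary["conditions"] = {}
    per_tf_sets: dict[str, dict[str, frozenset[str]]] = {}
    for tf in tfs:
        ctrl = calls.get((tf, config.control_condition))
        stress = calls.get((tf, config.stress_condition))
        if ctrl is None or stress is None:
            continue
        comp = compare_conditions(ctrl.targets, stress.targets)
        per_tf_sets[tf] = {"control": comp.set_control, "stress": comp.set_stress}
        entry = dict(comp.counts())
        entry["fold_increase"] = comp.fold_increase
        summary["conditions"][tf] = entry
        for region, genes_in in (
            ("shared", comp.shared),
            ("control_only", comp.control_only),
            ("stress_only", comp.stress_only),
        ):
            with open(os.path.join(config.outdir, f"{tf}_{region}.txt"), "w") as fh:
                fh.write("\n".join(sorted(genes_in)) + ("\n" if genes_in else ""))

    if len(tfs) == 2 and all(tf in per_tf_sets for tf in tfs):
        a, b = tfs
        cross = cross_tf_overlap(
            per_tf_sets[a]["control"], per_tf_sets[a]["stress"],
            per_tf_sets[b]["control"], per_tf_sets[b]["stress"],
        )
        summary["cross_tf"] = cross.counts()

    summary["known_targets"] = {}
    for tf, path in sorted(config.known_targets.items()):
        if tf not in per_tf_sets:
            continue
        with open(path) as fh:
            known = {line.strip() for line in fh if line.strip()}
        count, fraction = annotate_known(per_tf_sets[tf]["stress"], known)
        summary["known_targets"][tf] = {"count_known": count, "fraction": fraction}

    if config.promoters_fasta and config.patterns:
        promoters = _stage("motif", _read_promoters, config.promoters_fasta)
        summary["motif"] = {}
        for tf, pattern in sorted(config.patterns.items()):
            if tf not in per_tf_sets:
                continue
            targets = per_tf_sets[tf]["stress"] - per_tf_sets[tf]["control"]
            n_with, fraction = _stage(
                "motif", promoter_motif_fraction, targets, promoters, pattern
            )
            summary["motif"][tf] = {
                "pattern": pattern.iupac,
                "n_targets": len(targets),
                "n_with_motif": n_with,
                "fraction": fraction,
            }

    if config.go_map:
        universe = [g.gene_id for g in genes]
        go_map = _stage("enrichment", GOAnnotationMap.from_tsv, config.go_map, universe)
        summary["enrichment"] = {}
        for tf in tfs:
            if tf not in per_tf_sets:
                continue
            targets = per_tf_sets[tf]["stress"] - per_tf_sets[tf]["control"]
            results = _stage(
                "enrichment", go_enrichment, targets, go_map, config.alpha, config.correction
            )
            results_to_frame(results).to_csv(
                os.path.join(config.outdir, f"{tf}_go_enrichment.tsv"), sep="\t", index=False
            )
            summary["enrichment"][tf] = {
                "n_terms_tested": len(results),
                "enriched_terms": sorted(r.term for r in results if r.enriched),
            }

    _write_summary(summary, os.path.join(config.outdir, "binding_summary.json"))
    return summary


@dataclass
class GrowthArmConfig:
    growth_csv: str
    outdir: str
    control_strain: str = "control"
    calibration_csv: Optional[str] = None
    smoothing: Optional[float] = None
    correction: str = "bh"


def run_growth_arm(config: GrowthArmConfig) -> dict:
    """Run the growth arm; returns the summary dict it also writes."""
    os.makedirs(config.outdir, exist_ok=True)
    df = _stage("input", read_growth_csv, config.growth_csv)
    if "od" not in df.columns:
        if config.calibration_csv is None:
            raise StageError("[calibration] green values provided but no calibration curve")
        curve = _stage("calibration", CalibrationCurve.from_csv, config.calibration_csv)
        df = df.copy()
        df["od"] = _stage("calibration", calibrate, df["green_value"].to_numpy(float), curve)
    curves = curves_from_frame(df)
    fits = [_stage("fit", fit_growth, c, config.smoothing) for c in curves]
    fit_df = pd.DataFrame(
        [
            (f.strain, f.replicate, f.mu_max, f.min_generation_time, f.lag_h, f.od0, f.fit_ok)
            for f in fits
        ],
        columns=["strain", "replicate", "mu_max", "min_generation_time", "lag_h", "od0", "fit_ok"],
    )
    fit_df.to_csv(os.path.join(config.outdir, "growth_fits.tsv"), sep="\t", index=False)

    by_strain: dict[str, list] = {}
    for f in fits:
        by_strain.setdefault(f.strain, []).append(f)
    if config.control_strain not in by_strain:
        raise StageError(f"[compare] control strain {config.control_strain!r} absent from data")
    control = by_strain[config.control_strain]

    comparisons, errors = [], []
    for strain in sorted(by_strain):
        if strain == config.control_strain:
            continue
        for metric in ("generation_time", "lag"):
            try:
                comparisons.append(
                    compare_strains(by_strain[strain], control, metric, strain=strain)
                )
            except ValueError as exc:
                errors.append({"strain": strain, "metric": metric, "error": str(exc)})
    comparisons = adjust_comparisons(comparisons, method=config.correction)
    comparisons_to_frame(comparisons).to_csv(
        os.path.join(config.outdir, "strain_comparisons.tsv"), sep="\t", index=False
    )
    summary = {
        "n_wells": len(fits),
        "n_wells_fit_ok": int(sum(f.fit_ok for f in fits)),
        "strains": {
            s: {
                "n_replicates": len(fs),
                "mean_generation_time": _mean_ok(fs, "min_generation_time"),
                "mean_lag_h": _mean_ok(fs, "lag_h"),
            }
            for s, fs in sorted(by_strain.items())
        },
        "comparisons": [
            {
                "strain": c.strain,
                "metric": c.metric,
                "percent_change": c.percent_change,
                "p_adj": c.p_adj,
                "stars": c.stars,
            }
            for c in comparisons
        ],
        "errors": errors,
    }
    _write_summary(summary, os.path.join(config.outdir, "growth_summary.json"))
    return summary


def _mean_ok(fits: Sequence, attr: str) -> Optional[float]:
    vals = [getattr(f, attr) for f in fits if f.fit_ok]
    return float(np.mean(vals)) if vals else None


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_summary(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def simulate_study(seed: int, outdir: str, n_genes: int = 200) -> dict:
    """Generate a complete synthetic study (two TFs, promoters, GO, growth).

    Returns the paths and truth tables needed to run both arms.
    """
    os.makedirs(outdir, exist_ok=True)
    # plant ~10% of genes per TF so peaks stay well above the all-gene
    # background that they themselves inflate
    n_planted = max(4, round(0.1 * n_genes))
    base = SimulationConfig(seed=seed, n_genes=n_genes, n_planted=n_planted)
    sim_a = simulate_chipexo(base, tf="TFa", outdir=outdir)
    # second TF: overlapping planted set, independent noise
    rng = np.random.default_rng(seed + 1)
    overlap = sorted(rng.choice(sorted(sim_a.planted), size=n_planted // 2, replace=False))
    others = sorted(set(base.gene_ids()) - sim_a.planted)
    extra = sorted(rng.choice(others, size=n_planted, replace=False))
    cfg_b = SimulationConfig(
        seed=seed + 1, n_genes=n_genes, planted_targets=frozenset(overlap) | frozenset(extra)
    )
    sim_b = simulate_chipexo(cfg_b, tf="TFb", outdir=outdir)

    gene_ids = base.gene_ids()
    motif_genes = sorted(sim_a.planted | sim_b.planted)
    planted_offsets = {g: -300 - 10 * (i % 40) for i, g in enumerate(motif_genes)}
    fasta = os.path.join(outdir, "promoters.fasta")
    simulate_promoters(gene_ids, YRE, planted_offsets, seed=seed + 2, fasta_path=fasta)

    go_tsv = os.path.join(outdir, "go_map.tsv")
    simulate_go_map(
        gene_ids, sorted(sim_a.planted), seed=seed + 3, tsv_path=go_tsv
    )

    growth_csv = os.path.join(outdir, "growth.csv")
    truths = {
        "control": GrowthTruth(mu=0.30, lag=5.0),
        "strain_fast": GrowthTruth(mu=0.33, lag=4.0),
        "strain_slow": GrowthTruth(mu=0.24, lag=6.5),
        "strain_diauxic": GrowthTruth(mu=0.30, lag=5.0, diauxic=True),
    }
    simulate_growth(truths, seed=seed + 4, csv_path=growth_csv)
    return {
        "outdir": outdir,
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "tracks": {
            ("TFa", "control"): [os.path.join(outdir, "TFa_control.bedgraph")],
            ("TFa", "stress"): [os.path.join(outdir, "TFa_stress.bedgraph")],
            ("TFb", "control"): [os.path.join(outdir, "TFb_control.bedgraph")],
            ("TFb", "stress"): [os.path.join(outdir, "TFb_stress.bedgraph")],
        },
        "promoters": fasta,
        "go_map": go_tsv,
        "growth_csv": growth_csv,
        "planted": {"TFa": sim_a.planted, "TFb": sim_b.planted},
        "growth_truth": truths,
    }


def run_all(seed: int, outdir: str, n_genes: int = 200) -> dict:
    """Simulate a study and run both arms; returns the combined summary."""
    inputs = simulate_study(seed, os.path.join(outdir, "inputs"), n_genes=n_genes)
    binding = run_binding_arm(
        BindingArmConfig(
            annotation=inputs["annotation"],
            chrom_sizes=inputs["chrom_sizes"],
            tracks=inputs["tracks"],
            outdir=os.path.join(outdir, "binding"),
            promoters_fasta=inputs["promoters"],
            patterns={"TFa": YRE, "TFb": YRE},
            go_map=inputs["go_map"],
        )
    )
    growth = run_growth_arm(
        GrowthArmConfig(
            growth_csv=inputs["growth_csv"],
            outdir=os.path.join(outdir, "growth"),
            control_strain="control",
        )
    )
    combined = {"seed": seed, "binding": binding, "growth": growth}
    _write_summary(combined, os.path.join(outdir, "summary.json"))
    return combined
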