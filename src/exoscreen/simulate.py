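"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* ChIP-exo tracks: Poisson background per base (default mean 5 counts,
  putting control per-gene window means in the 4-6 range) with planted
  promoter peaks for target genes — rectangular mass centred 250 bp
  upstream of the TSS, 100 bp wide, with total mass ``peak_fold`` times
  the window's expected background mass, so the 2.5x calling threshold
  has a direct dial.
* Promoters: uniform-random sequence made motif-free by resampling any
  window that matches the pattern on either strand, then one motif
  instance planted per chosen gene at a known offset.
* GO maps: terms sample genes uniformly from the universe; enriched
  terms over-sample the planted target set by a configurable factor.
* Growth curves: flat at the inoculation OD through the lag, then
  logistic growth toward capacity (optionally two-phase diauxic with an
  intermediate plateau), with multiplicative lognormal noise; optional
  emission as plate-reader green values through the inverse of the test
  calibration curve.

Everything is driven by one integer seed and is byte-deterministic.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, write_annotation_tsv
from .enrichment import GOAnnotationMap
from .growth import CalibrationCurve
from .motif import MotifPattern, YRE, scan_sequence
from .signal import SignalTrack, write_bedgraph
from .windows import WindowSpec

__all__ = [
    "SimulationConfig",
    "GrowthTruth",
    "TEST_CALIBRATION",
    "simulate_chipexo",
    "simulate_promoters",
    "simulate_go_map",
    "simulate_growth",
]

# Plausible monotone green-value <-> OD600 table for testing only; real
# screens must use the instrument supplier's standard curve.
TEST_CALIBRATION = CalibrationCurve(
    green=(1.0, 4.0, 8.0, 35.0, 70.0, 140.0, 330.0, 640.0, 950.0),
    od=(0.01, 0.05, 0.10, 0.50, 1.0, 2.0, 5.0, 10.0, 15.0),
)


@dataclass(frozen=True)
class GrowthTruth:
    """Ground-truth kinetics for one simulated strain."""

    mu: float = 0.3  # 1/h
    lag: float = 5.0  # h
    od0: float = 0.1
    capacity: float = 5.0  # final OD600 of yeast on ~2% glucose minimal medium
    diauxic: bool = False
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.capacity <= self.od0:
            raise ValueError("capacity must exceed the inoculation OD")


@dataclass(frozen=True)
class SimulationConfig:
    """Dials for all generators; defaults mirror the study conditions."""

    seed: int = 0
    n_genes: int = 200
    gene_spacing: int = 3000
    chrom: str = "chrS"
    background_rate: float = 5.0  # mean counts per base; control window mean ~ 4-6
    n_planted: int = 20
    planted_targets: Optional[frozenset[str]] = None
    peak_fold: float = 8.0
    peak_center_offset: int = -250  # bp relative to TSS; peaks sit 200-300 bp upstream
    peak_width: int = 100
    overdispersion: float = 0.0  # 0 = Poisson; > 0 = negative binomial variance inflation
    window: WindowSpec = field(default_factory=WindowSpec)

    @property
    def chrom_length(self) -> int:
        return self.n_genes * self.gene_spacing + 3000

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


def _draw_background(rng: np.random.Generator, rate: float, size: int, overdispersion: float) -> np.ndarray:
    if overdispersion <= 0:
        return rng.poisson(rate, size=size).astype(float)
    # Gamma-Poisson mixture: variance = rate * (1 + overdispersion)
    shape = rate / overdispersion
    lam = rng.gamma(shape, overdispersion, size=size)
    return rng.poisson(lam).astype(float)


def _make_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    genes = []
    for i, gid in enumerate(config.gene_ids()):
        tss = 1501 + i * config.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneAnnotation(gene_id=gid, chrom=config.chrom, strand=strand, tss=tss))
    return genes


@dataclass
class ChipExoSimulation:
    annotation: list[GeneAnnotation]
    chrom_sizes: dict[str, int]
    control: SignalTrack
    stress: SignalTrack
    planted: frozenset[str]
    tf: str


def simulate_chipexo(
    config: SimulationConfig,
    tf: str = "TF1",
    outdir: Optional[str] = None,
) -> ChipExoSimulation:
    """Simulate control and stress tracks with planted target peaks.

    The stress track is background plus a rectangular peak per planted
    gene (centred ``peak_center_offset`` from the TSS on the gene's
    strand); the control track is background only.  With ``outdir`` set,
    annotation TSV, chrom.sizes, both bedGraphs and a truth table are
    written there.
    """
    rng = np.random.default_rng(config.seed)
    genes = _make_annotation(config)
    gene_ids = [g.gene_id for g in genes]
    if config.planted_targets is not None:
        planted = frozenset(config.planted_targets)
        missing = planted - set(gene_ids)
        if missing:
            raise ValueError(f"planted genes absent from annotation: {sorted(missing)[:5]}")
    else:
        planted = frozenset(rng.choice(gene_ids, size=config.n_planted, replace=False))
    L = config.chrom_length
    control_counts = _draw_background(rng, config.background_rate, L, config.overdispersion)
    stress_counts = _draw_background(rng, config.background_rate, L, config.overdispersion)
    window_mass = config.background_rate * config.window.length
    peak_height = config.peak_fold * window_mass / config.peak_width
    half = config.peak_width // 2
    by_id = {g.gene_id: g for g in genes}
    for gid in sorted(planted):
        g = by_id[gid]
        tss0 = g.tss - 1
        center = tss0 + config.peak_center_offset if g.strand == "+" else tss0 - config.peak_center_offset
        lo = max(center - half, 0)
        hi = min(center + config.peak_width - half, L)
        stress_counts[lo:hi] += peak_height
    chrom_sizes = {config.chrom: L}
    sim = ChipExoSimulation(
        annotation=genes,
        chrom_sizes=chrom_sizes,
        control=SignalTrack(tf=tf, condition="control", counts={config.chrom: control_counts}),
        stress=SignalTrack(tf=tf, condition="stress", counts={config.chrom: stress_counts}),
        planted=planted,
        tf=tf,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_annotation_tsv(genes, os.path.join(outdir, "annotation.tsv"))
        with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
            fh.write(f"{config.chrom}\t{L}\n")
        write_bedgraph(sim.control, os.path.join(outdir, f"{tf}_control.bedgraph"))
        write_bedgraph(sim.stress, os.path.join(outdir, f"{tf}_stress.bedgraph"))
        pd.DataFrame(
            {"gene_id": gene_ids, "is_planted_target": [g in planted for g in gene_ids]}
        ).to_csv(os.path.join(outdir, f"{tf}_truth_targets.tsv"), sep="\t", index=False)
    return sim


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGT"))


def simulate_promoters(
    gene_ids: Sequence[str],
    pattern: MotifPattern = YRE,
    planted: Optional[Mapping[str, int]] = None,
    length: int = 1000,
    seed: int = 0,
    max_attempts: int = 500,
    fasta_path: Optional[str] = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Motif-free random promoters with one planted instance per chosen gene.

    ``planted`` maps gene_id -> TSS-relative offset (negative, upstream);
    the promoter spans -length..-1.  Background windows matching the
    pattern on either strand are resampled; a pattern permissive enough
    to defeat resampling (e.g. all-N) raises ``RuntimeError``.
    Returns ``(promoters, truth)`` where truth echoes the planted offsets.
    """
    planted = dict(planted or {})
    m = len(pattern)
    for gid, off in planted.items():
        if not (-length <= off <= -m):
            raise ValueError(f"{gid}: offset {off} outside promoter span for a {m}-mer")
    rng = np.random.default_rng(seed)
    promoters: dict[str, str] = {}
    for gid in gene_ids:
        codes = _random_seq(rng, length)
        for attempt in range(max_attempts):
            seq = "".join(_BASES[codes])
            hits = scan_sequence(seq, pattern, both_strands=True)
            if not hits:
                break
            for off0, _, _ in hits:
                codes[off0 : off0 + m] = _random_seq(rng, m)
        else:
            raise RuntimeError(
                f"could not generate a motif-free promoter for {gid}: pattern too permissive"
            )
        if gid in planted:
            idx = planted[gid] + length
            instance = "".join(
                str(rng.choice(sorted(cls))) for cls in pattern.classes()
            )
            seq = seq[:idx] + instance + seq[idx + m :]
            forward = [h for h in scan_sequence(seq, pattern, both_strands=False)]
            if [h[0] for h in forward] != [idx]:
                # planting created a spurious junction hit; rare — retry gene
                return simulate_promoters(
                    gene_ids, pattern, planted, length, seed + 1, max_attempts, fasta_path
                )
        promoters[gid] = seq
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for gid in gene_ids:
                fh.write(f">{gid}\n{promoters[gid]}\n")
    return promoters, dict(planted)


def simulate_go_map(
    universe: Sequence[str],
    targets: Sequence[str],
    n_terms: int = 20,
    term_size: int = 30,
    n_enriched: int = 3,
    enrichment_factor: float = 5.0,
    seed: int = 0,
    tsv_path: Optional[str] = None,
) -> tuple[GOAnnotationMap, frozenset[str]]:
    """GO map with ``n_enriched`` terms over-sampling the target set.

    Non-enriched terms draw ``term_size`` genes uniformly without
    replacement.  For enriched terms the fraction of members that are
    target genes is over-represented by ``enrichment_factor``: the
    target count is binomial with success probability
    ``factor * |targets| / |universe|`` and members are then chosen
    uniformly within the target/non-target strata.  Returns the map and
    the truth set of enriched terms.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    target_list = sorted(set(targets))
    other_list = sorted(set(universe) - set(target_list))
    terms: dict[str, frozenset[str]] = {}
    enriched_truth = set()
    for i in range(n_terms):
        term = f"TERM{i + 1:04d}"
        if i < n_enriched and target_list:
            p_target = min(1.0, enrichment_factor * len(target_list) / len(universe))
            k = int(rng.binomial(term_size, p_target))
            k = min(k, len(target_list), term_size)
            members = list(rng.choice(target_list, size=k, replace=False)) + list(
                rng.choice(other_list, size=term_size - k, replace=False)
            )
            enriched_truth.add(term)
        else:
            members = rng.choice(universe, size=term_size, replace=False)
        terms[term] = frozenset(str(g) for g in members)
    go_map = GOAnnotationMap(terms=terms, universe=frozenset(universe))
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            for term in sorted(terms):
                for gene in sorted(terms[term]):
                    fh.write(f"{term}\t{gene}\n")
    return go_map, frozenset(enriched_truth)


def _baranyi(t: np.ndarray, od0: float, mu: float, lag: float, cap: float) -> np.ndarray:
    """Baranyi-Roberts lag + logistic growth (smooth lag transition).

    The adjustment function A(t) delays growth by ``lag`` asymptotically;
    the log-OD trajectory approaches the line ``ln od0 + mu (t - lag)``
    during exponential phase, so the tangent lag construction recovers
    ``lag`` by design.  ``lag = 0`` reduces to plain logistic growth.
    The transition sharpness ``nu`` (dimensionless, > 1 = sharper than
    classic Baranyi) keeps the ramp short relative to the exponential
    phase so the planted rate is actually expressed in the curve.
    """
    t = np.asarray(t, dtype=float)
    nu = 10.0
    if lag > 0:
        r = nu * mu
        a = t + np.log(np.exp(-r * t) + math.exp(-r * lag) * (1.0 - np.exp(-r * t))) / r
    else:
        a = t
    e = np.exp(mu * a)
    return od0 * e / (1.0 + (od0 / cap) * (e - 1.0))


def growth_od(t: np.ndarray, truth: GrowthTruth) -> np.ndarray:
    """Noiseless OD trajectory: smooth lag, then (possibly diauxic) growth."""
    t = np.asarray(t, dtype=float)
    if not truth.diauxic:
        return _baranyi(t, truth.od0, truth.mu, truth.lag, truth.capacity)
    # first growth phase consumes the preferred substrate
    k1 = truth.od0 + 0.4 * (truth.capacity - truth.od0)
    od = _baranyi(t, truth.od0, truth.mu, truth.lag, k1)
    # exponential phase effectively over once 97% of the phase-1 ceiling
    # is reached; the second phase then follows after its own lag
    tau1 = truth.lag + math.log(0.97 / 0.03 * (k1 - truth.od0) / truth.od0) / truth.mu
    plateau = 4.0
    phase2 = t >= tau1
    if phase2.any():
        od1_end = float(_baranyi(np.array([tau1]), truth.od0, truth.mu, truth.lag, k1)[0])
        od2 = _baranyi(t[phase2] - tau1, od1_end, 0.6 * truth.mu, plateau, truth.capacity)
        od[phase2] = np.maximum(od[phase2], od2)
    return od


def simulate_growth(
    truths: Mapping[str, GrowthTruth],
    n_replicates: int = 3,
    t_max: float = 96.0,
    dt: float = 0.5,
    seed: int = 0,
    as_green: bool = False,
    calibration: CalibrationCurve = TEST_CALIBRATION,
    csv_path: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format screen data plus the truth table.

    Readings every ``dt`` hours for ``t_max`` hours (defaults mirror a
    96 h screen read every 30 min).  With ``as_green`` the OD is mapped
    back through the calibration curve into green values.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    rows = []
    for strain in sorted(truths):
        truth = truths[strain]
        clean = growth_od(t, truth)
        for rep in range(1, n_replicates + 1):
            noise = np.exp(rng.normal(0.0, truth.noise_sigma, size=len(t)))
            od = clean * noise
            if as_green:
                values = np.interp(od, calibration.od, calibration.green)
                col = "green_value"
            else:
                values, col = od, "od"
            for ti, vi in zip(t, values):
                rows.append((strain, rep, round(float(ti), 6), float(vi)))
    df = pd.DataFrame(rows, columns=["strain", "replicate", "time_h", col])
    truth_df = pd.DataFrame(
        [
            (s, tr.mu, math.log(2) / tr.mu, tr.lag, tr.od0, tr.capacity, tr.diauxic, tr.noise_sigma)
            for s, tr in sorted(truths.items())
        ],
        columns=["strain", "mu", "min_generation_time", "lag_h", "od0", "capacity", "diauxic", "noise_sigma"],
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
        truth_df.to_csv(os.path.splitext(csv_path)[0] + "_truth.csv", index=False)
    return df, truth_df
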