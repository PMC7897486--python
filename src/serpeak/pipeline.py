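"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the stages in dependency order on a synthetic
two-cell-type experiment: simulate -> callpeaks (per cell type) -> subpeaks
-> compare -> annotate -> chromstate -> correlate -> profile. Every stage
writes plain-text outputs to the run directory plus a manifest entry with
parameter values and output checksums; all randomness derives from the
single root seed, so re-running the same configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import chromstate as cs
from . import differential, io, sercall, simulate, stats, subpeaks
from .coverage import build_pileup, tag_density_profile
from .intervals import classify_genomic_location, promoter_window

__all__ = ["RunConfig", "run_pipeline", "DEMO_CHROMSTATE_EMISSION"]

ALL_STAGES = [
    "simulate",
    "callpeaks",
    "subpeaks",
    "compare",
    "annotate",
    "chromstate",
    "correlate",
    "profile",
]

# the 6-state chromatin model the demo simulates from; marks are
# (H3K4me1, H3K27ac, H3K27me3)
DEMO_CHROMSTATE_EMISSION = np.array(
    [
        [0.90, 0.85, 0.02],  # active enhancer
        [0.85, 0.10, 0.05],  # primed enhancer
        [0.60, 0.80, 0.10],  # active promoter-like
        [0.50, 0.10, 0.85],  # bivalent
        [0.05, 0.02, 0.90],  # polycomb repressed
        [0.03, 0.02, 0.03],  # quiescent
    ]
)


@dataclass
class RunConfig:
    """One pipeline run: root seed, simulation conditions, stage parameters."""

    outdir: str
    seed: int = 1
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    sercall: sercall.SerCallConfig = field(default_factory=sercall.SerCallConfig)
    valley_frac: float = subpeaks.DEFAULT_VALLEY_FRAC
    smooth_window: int = subpeaks.DEFAULT_SMOOTH_WINDOW
    min_subpeak_width: int = subpeaks.DEFAULT_MIN_WIDTH
    min_height: float = subpeaks.DEFAULT_MIN_HEIGHT
    shared_fraction: float = 0.6  # of truth regions bound in both cell types
    chromstate_bins: int = 5_000  # per cell type
    profile_half_width: int = 1_000

    @classmethod
    def demo(cls, outdir: str, seed: int = 1) -> "RunConfig":
        return cls(outdir=outdir, seed=seed, sim=simulate.SimulationConfig(seed=seed))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    ctx: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        runner = _RUNNERS[stage]
        files = runner(config, ctx, out)
        manifest["stages"][stage] = {
            "outputs": {f: _sha256(out / f) for f in sorted(files)},
            "seed": _stage_seed(config.seed, stage),
        }
    manifest["parameters"] = {
        "sim": asdict(config.sim),
        "sercall": asdict(config.sercall),
        "valley_frac": config.valley_frac,
        "smooth_window": config.smooth_window,
        "min_subpeak_width": config.min_subpeak_width,
        "min_height": config.min_height,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------------------------------
# stage runners; each gets (config, shared context, outdir) and returns the
# list of files it wrote (relative to outdir)


def _stage_simulate(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    seed = _stage_seed(cfg.seed, "simulate")
    genome = simulate.make_genome(cfg.sim)
    ctx["genome"] = genome

    # assign each chip_only truth region to a cell-type pattern
    rng = np.random.default_rng([seed, 1])
    chip_truth = [t for t in genome.truth if t.label == "chip_only"]
    other_truth = [t for t in genome.truth if t.label != "chip_only"]
    patterns = rng.choice(
        ["AB", "A", "B"],
        size=len(chip_truth),
        p=[cfg.shared_fraction, (1 - cfg.shared_fraction) / 2, (1 - cfg.shared_fraction) / 2],
    )
    truth_a = [t for t, p in zip(chip_truth, patterns) if "A" in p] + other_truth
    truth_b = [t for t, p in zip(chip_truth, patterns) if "B" in p] + other_truth
    ctx["patterns"] = dict(zip((t.region for t in chip_truth), patterns))
    ctx["truth_a"], ctx["truth_b"] = truth_a, truth_b

    reads = {
        "chip_A": simulate.simulate_reads(cfg.sim, truth_a, "chip", seed=seed),
        "chip_B": simulate.simulate_reads(cfg.sim, truth_b, "chip", seed=seed + 1),
        "input": simulate.simulate_reads(cfg.sim, genome.truth, "input", seed=seed),
    }
    ctx["reads"] = reads

    files = []
    for name, rs in reads.items():
        io.write_bed(rs, out / f"reads_{name}.bed")
        files.append(f"reads_{name}.bed")
    io.write_bed([io.BedRecord(iv) for iv in genome.blacklist], out / "blacklist.bed", columns=3)
    io.write_bedgraph(genome.mappability, out / "mappability.bedGraph")
    io.write_genes(genome.genes, out / "genes.tsv")
    genome.write_truth_json(out / "truth.json")
    return files + ["blacklist.bed", "mappability.bedGraph", "genes.tsv", "truth.json"]


def _stage_callpeaks(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    genome = ctx["genome"]
    files = []
    ctx["sers"] = {}
    for ct in ("A", "B"):
        result = sercall.call_sers(
            ctx["reads"][f"chip_{ct}"],
            ctx["reads"]["input"],
            genome.blacklist,
            genome.chrom_sizes,
            cfg.sercall,
        )
        ctx["sers"][ct] = result
        recs = [
            io.BedRecord(s.region, name=f"SER_{ct}_{i}", score=s.mean_normalized_coverage)
            for i, s in enumerate(result.sers)
        ]
        io.write_bed(recs, out / f"sers_{ct}.bed")
        model = result.models[0]
        with open(out / f"hmm_{ct}.json", "w") as fh:
            json.dump(
                {
                    "means": model.means.tolist(),
                    "sds": model.sds.tolist(),
                    "transition": model.transition.tolist(),
                    "startprob": model.startprob.tolist(),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        files += [f"sers_{ct}.bed", f"hmm_{ct}.json"]
    return files


def _stage_subpeaks(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    genome = ctx["genome"]
    ctx["datasets"] = {}
    files = []
    for ct in ("A", "B"):
        reads = ctx["reads"][f"chip_{ct}"]
        pileup = build_pileup(reads, genome.chrom_sizes)
        sps = []
        for ser in ctx["sers"][ct].sers:
            sps.extend(
                subpeaks.split_subpeaks(
                    ser,
                    pileup,
                    valley_frac=cfg.valley_frac,
                    min_width=cfg.min_subpeak_width,
                    smooth_window=cfg.smooth_window,
                )
            )
        sps = subpeaks.score_subpeaks(sps, pileup, pileup.total_mapped)
        sps = subpeaks.filter_subpeaks(sps, cfg.min_height)
        ctx["datasets"][ct] = differential.ScoredDataset(
            name=ct, subpeaks=sps, pileup=pileup, total_mapped=pileup.total_mapped
        )
        recs = [
            io.BedRecord(
                sp.region,
                name=f"subpeak_{ct}_{i}",
                value=sp.height_norm,
                summit_offset=sp.summit - sp.region.start,
            )
            for i, sp in enumerate(sps)
        ]
        io.write_narrowpeak(recs, out / f"subpeaks_{ct}.narrowPeak")
        files.append(f"subpeaks_{ct}.narrowPeak")
    return files


def _stage_compare(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    a, b = ctx["datasets"]["A"], ctx["datasets"]["B"]
    result = differential.compare_datasets(a, b)
    ctx["comparison"] = result
    rows = []
    for side, classified in (("A", result.classified_a), ("B", result.classified_b)):
        for c in classified:
            rows.append(
                {
                    "dataset": side,
                    "chrom": c.subpeak.region.chrom,
                    "start": c.subpeak.region.start,
                    "end": c.subpeak.region.end,
                    "summit": c.subpeak.summit,
                    "height": round(c.subpeak.height_norm, 4),
                    "height_in_other": round(c.height_in_other, 4),
                    "unique_score": round(c.unique_score, 4),
                    "nearest_summit_bp": (
                        -1
                        if np.isinf(c.nearest_other_summit_distance)
                        else int(c.nearest_other_summit_distance)
                    ),
                    "label": c.label,
                }
            )
    pd.DataFrame(rows).to_csv(out / "comparison.tsv", sep="\t", index=False)
    with open(out / "comparison_counts.json", "w") as fh:
        json.dump(result.counts, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return ["comparison.tsv", "comparison_counts.json"]


def _stage_annotate(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    seed = _stage_seed(cfg.seed, "annotate")
    genome = ctx["genome"]
    counts: Dict[str, int] = {}
    for sp in ctx["datasets"]["A"].subpeaks:
        label = classify_genomic_location(sp.region.chrom, sp.summit, genome.genes).value
        counts[label] = counts.get(label, 0) + 1
    with open(out / "genomic_distribution_A.json", "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # expression by binding category, using the two subpeak sets as factors
    peak_sets = {
        ct: [sp.region for sp in ds.subpeaks] for ct, ds in ctx["datasets"].items()
    }
    binding: Dict[str, str] = {}
    for g in genome.genes:
        prom = promoter_window(g)
        hits = [
            ct
            for ct, peaks in peak_sets.items()
            if any(
                iv.chrom == g.chrom and iv.overlap_length(prom) >= 0.3 * iv.length
                for iv in peaks
            )
        ]
        binding[g.gene_id] = "+".join(sorted(hits)) or "unbound"
    effect = {"A+B": 3.0, "A": 2.0, "B": 2.0, "unbound": 1.0}
    expr = simulate.simulate_expression(
        genome.genes, binding, effect, noise_sd=0.5, seed=seed
    )
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)

    genes_with_expr = [
        dataclasses.replace(g, expression=float(e))
        for g, e in zip(genome.genes, expr["expression"])
    ]
    groups = stats.expression_by_binding(genes_with_expr, peak_sets)
    summary_rows = []
    for label in sorted(groups):
        if len(groups[label]) == 0:
            continue
        box = stats.boxplot_summary(groups[label])
        summary_rows.append(
            {
                "group": label,
                "n": len(groups[label]),
                "q1": round(box.q1, 4),
                "median": round(box.median, 4),
                "q3": round(box.q3, 4),
                "whisker_low": round(box.whisker_low, 4),
                "whisker_high": round(box.whisker_high, 4),
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "expression_by_binding.tsv", sep="\t", index=False)
    return ["genomic_distribution_A.json", "expression.tsv", "expression_by_binding.tsv"]


def _stage_chromstate(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    seed = _stage_seed(cfg.seed, "chromstate")
    emission = DEMO_CHROMSTATE_EMISSION
    K = emission.shape[0]
    transition = np.full((K, K), 0.02 / (K - 1))
    np.fill_diagonal(transition, 0.98)
    startprob = np.full(K, 1.0 / K)
    sizes = {"chr1": cfg.chromstate_bins * 200}

    tracks = {}
    seg_truth = {}
    for i, ct in enumerate(("A", "B")):
        paths = simulate.simulate_state_paths(sizes, transition, startprob, seed + i)
        seg_truth[ct] = paths
        tracks[ct] = simulate.sample_mark_presence(paths, emission, seed + 10 + i)
    model = cs.fit_chromstate(tracks, n_states=K, seed=seed, n_restarts=2)
    segs = {ct: cs.segment(model, tracks[ct], cell_type=ct) for ct in tracks}

    np.savetxt(out / "chromstate_emission.tsv", model.emission, delimiter="\t", fmt="%.6f")
    np.savetxt(out / "chromstate_transition.tsv", model.transition, delimiter="\t", fmt="%.6f")
    files = ["chromstate_emission.tsv", "chromstate_transition.tsv"]
    for ct, seg in segs.items():
        recs = [
            io.BedRecord(iv, name=f"state{st}") for iv, st in seg.to_segments()
        ]
        io.write_bed(recs, out / f"segmentation_{ct}.bed")
        files.append(f"segmentation_{ct}.bed")

    # fates of the A-specific subpeak regions between the two cell types,
    # restricted to the simulated chromatin chromosome span
    peaks = [
        c.subpeak.region
        for c in ctx.get("comparison").classified_a
        if c.label == "unique" and c.subpeak.region.end <= sizes["chr1"]
    ] if ctx.get("comparison") else []
    fate = (
        cs.state_fate(peaks, segs["A"], segs["B"], n_states=K)
        if peaks
        else np.zeros((K, K), dtype=np.int64)
    )
    np.savetxt(out / "state_fate_A_specific.tsv", fate, delimiter="\t", fmt="%d")
    files.append("state_fate_A_specific.tsv")
    return files


def _stage_correlate(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    genome = ctx["genome"]
    bins = stats.make_genome_bins(genome.chrom_sizes, genome.blacklist, genome.mappability)
    corr = stats.correlation_matrix(
        {name: rs for name, rs in ctx["reads"].items()}, bins, genome.chrom_sizes
    )
    corr.round(6).to_csv(out / "correlation.tsv", sep="\t")
    order = stats.cluster_order(corr)
    (out / "cluster_order.txt").write_text("\n".join(order) + "\n")
    return ["correlation.tsv", "cluster_order.txt"]


def _stage_profile(cfg: RunConfig, ctx: dict, out: Path) -> List[str]:
    ds = ctx["datasets"]["A"]
    anchors = [(sp.region.chrom, sp.summit) for sp in ds.subpeaks]
    profile, n_used = tag_density_profile(
        ds.pileup, anchors, cfg.profile_half_width, ds.total_mapped
    )
    offsets = np.arange(-cfg.profile_half_width, cfg.profile_half_width + 1)
    pd.DataFrame({"offset": offsets, "mean_density_per10M": np.round(profile, 6)}).to_csv(
        out / "tag_density_A.tsv", sep="\t", index=False
    )
    return ["tag_density_A.tsv"]


_RUNNERS = {
    "simulate": _stage_simulate,
    "callpeaks": _stage_callpeaks,
    "subpeaks": _stage_subpeaks,
    "compare": _stage_compare,
    "annotate": _stage_annotate,
    "chromstate": _stage_chromstate,
    "correlate": _stage_correlate,
    "profile": _stage_profile,
}
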