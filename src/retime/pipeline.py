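"""End-to-end orchestration from a single flat config.

A pipeline run either simulates a cohort (``simulate: true``) or loads
RT bedGraphs and feature BEDs from the paths in the config, then runs
the stages in order: normalize -> smooth -> segment -> call ->
transmission (when daughter-generation profiles exist) -> characterize
-> enrich -> cluster -> atac. Stages whose inputs are absent are
recorded as skipped rather than failing, so partial configs still
produce the analyses they can support.

One global seed drives everything: each stage draws its own generator
from ``SeedSequence((seed, stage_index))`` with fixed stage indices, so
stages are individually reproducible and a rerun with the same config
produces byte-identical artifacts (the manifest records a sha256 per
file, which the determinism test compares).
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atac as atac_mod
from . import io
from .characterize import linkage_to_newick, mark_coverage_matrix, region_stats_table
from .clustering import build_rt_matrix, cluster_cohorts
from .differential import (
    ARTILSet,
    CallParams,
    assess_transmission,
    call_differential,
    normalize_replicates,
    profile_from_bedgraph,
    profile_to_bedgraph,
    segment_domains,
    smooth_profile,
)
from .enrichment import enrichment_z, shuffle_regions
from .intervals import RegionSet
from .synthetic import SyntheticSpec, make_feature_tracks, make_genome, make_rt_profiles

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("retime")

_STAGES = {
    "simulate": 0, "normalize": 1, "segment": 2, "call": 3, "transmission": 4,
    "characterize": 5, "enrich": 6, "cluster": 7, "atac": 8,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence((seed, _STAGES[stage])).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Flat key-value configuration; unknown keys are rejected."""

    outdir: str = "retime_out"
    seed: int = 17
    simulate: bool = False
    write_fasta: bool = True
    # simulation overrides (used when simulate is true)
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    probe_spacing: int = 10_000
    noise_sd: float = 0.25
    n_replicates: int = 2
    inherit_fraction: float = 0.57
    inherit_amplitude_factor: float = 0.6
    atac_multiplier: float = 1.2
    # file inputs (used when simulate is false)
    chrom_sizes: str | None = None
    mappable_bed: str | None = None
    fasta: str | None = None
    control_bedgraphs: list[str] = field(default_factory=list)
    treated_bedgraphs: list[str] = field(default_factory=list)
    daughter_control_bedgraphs: list[str] = field(default_factory=list)
    daughter_treated_bedgraphs: list[str] = field(default_factory=list)
    marks_beds: list[str] = field(default_factory=list)
    genes_bed: str | None = None
    origins_bed: str | None = None
    cfs_bed: str | None = None
    atac_control: list[str] = field(default_factory=list)
    atac_treated: list[str] = field(default_factory=list)
    # stage parameters
    span_bp: int = 500_000
    window_probes: int = 10
    p_thr: float = 0.05
    min_amp: float = 0.3
    min_region: int = 100_000
    max_gap: int = 1
    early_thr: float = 0.25
    late_thr: float = -0.25
    slope_thr: float = 1.0
    min_domain: int = 100_000
    n_shuffles: int = 1000
    min_recip: float = 0.5
    max_center_dist: int = 500

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run all applicable stages; return {relative path: sha256} manifest.

    The manifest is also written to ``outdir/manifest.tsv`` together with
    a ``params.yaml`` echo of every parameter, and a ``stages.tsv``
    recording which stages ran or were skipped and why.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(levelname)s %(message)s")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    emitted: list[Path] = []
    stages: list[tuple[str, str]] = []

    def emit(path: Path) -> None:
        emitted.append(path)

    # ------------------------------------------------------------------ load
    truth = None
    tracks: dict = {}
    genome = None
    fasta_seqs = None
    profiles: dict = {}
    if cfg.simulate:
        spec = SyntheticSpec(
            n_chroms=cfg.n_chroms,
            chrom_length=cfg.chrom_length,
            probe_spacing=cfg.probe_spacing,
            noise_sd=cfg.noise_sd,
            n_replicates=cfg.n_replicates,
            inherit_fraction=cfg.inherit_fraction,
            inherit_amplitude_factor=cfg.inherit_amplitude_factor,
            atac_multiplier=cfg.atac_multiplier,
            seed=cfg.seed,
        )
        log.info("simulate: %d chrom x %.1f Mb, seed %d", spec.n_chroms, spec.chrom_length / 1e6, spec.seed)
        profiles, truth = make_rt_profiles(spec)
        tracks = make_feature_tracks(spec, truth)
        genome, fasta_seqs = make_genome(spec)
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        emit(io.write_chrom_sizes(genome.chrom_lengths, cdir / "chrom.sizes"))
        emit(io.write_bed(genome.mappable, cdir / "mappable.bed"))
        if cfg.write_fasta:
            emit(io.write_fasta(fasta_seqs, cdir / "genome.fa"))
        for (cond, gen, rep), p in profiles.items():
            emit(io.write_bedgraph(profile_to_bedgraph(p), cdir / f"rt_{cond}_{gen}_{rep}.bedgraph"))
        emit(io.write_bed(truth.implant_set(), cdir / "truth_implants.bed"))
        emit(io.write_bed(truth.early, cdir / "truth_early.bed"))
        emit(io.write_bed(truth.late, cdir / "truth_late.bed"))
        for name in ("origins", "genes", "cfs"):
            emit(io.write_bed(tracks[name], cdir / f"{name}.bed"))
        for mname, mrs in tracks["marks"].items():
            emit(io.write_bed(mrs, cdir / f"{mname}.bed"))
        for (cond, rep), tr in tracks["atac_peaks"].items():
            df = tr.to_frame()
            peak_bed = cdir / f"atac_{cond}_{rep}.bed"
            with open(peak_bed, "w") as fh:
                for chrom, start, end, value in df.itertuples(index=False):
                    fh.write(f"{chrom}\t{int(start)}\t{int(end)}\tpeak\t{value:.6g}\t.\n")
            emit(peak_bed)
        stages.append(("simulate", "ran"))
    else:
        stages.append(("simulate", "skipped: simulate=false"))
        if cfg.chrom_sizes:
            genome = io.read_genome(cfg.chrom_sizes, cfg.mappable_bed)
        for key, cond, gen in (
            ("control_bedgraphs", "control", "t0"),
            ("treated_bedgraphs", "treated", "t0"),
            ("daughter_control_bedgraphs", "control", "n1"),
            ("daughter_treated_bedgraphs", "treated", "n1"),
        ):
            for i, path in enumerate(getattr(cfg, key)):
                rep = f"r{i + 1}"
                profiles[(cond, gen, rep)] = profile_from_bedgraph(
                    io.read_bedgraph(path), cond, gen, rep
                )
        if cfg.fasta:
            import pyfaidx

            fasta_seqs = pyfaidx.Fasta(cfg.fasta)

    params = CallParams(
        window_probes=cfg.window_probes, p_thr=cfg.p_thr, min_amp=cfg.min_amp,
        min_region=cfg.min_region, max_gap=cfg.max_gap, span_bp=cfg.span_bp,
    )

    # ------------------------------------------------------------- normalize
    t0_control = [profiles[k] for k in sorted(profiles) if k[0] == "control" and k[1] == "t0"]
    t0_treated = [profiles[k] for k in sorted(profiles) if k[0] == "treated" and k[1] == "t0"]
    artil: ARTILSet | None = None
    domains = None
    norm_map: dict = {}
    if len(t0_control) >= 2 and len(t0_treated) >= 2:
        normed = normalize_replicates(t0_control + t0_treated)
        norm_c, norm_t = normed[: len(t0_control)], normed[len(t0_control):]
        norm_map = {"control": norm_c, "treated": norm_t}
        stages.append(("normalize", "ran"))
        # -------------------------------------------------------------- segment
        from dataclasses import replace as _replace

        mean_vals = np.mean([p.values for p in norm_c], axis=0)
        mean_control = _replace(norm_c[0], values=mean_vals, replicate="mean")
        sm = smooth_profile(mean_control, cfg.span_bp)
        domains = segment_domains(sm, cfg.early_thr, cfg.late_thr, cfg.slope_thr, cfg.min_domain)
        emit(io.write_bed(RegionSet(domains.intervals, "domains"), out / "domains.bed"))
        stages.append(("segment", "ran"))
        # ----------------------------------------------------------------- call
        artil = call_differential(norm_c, norm_t, params)
        emit(io.write_bed(artil.to_region_set(), out / "artil.bed"))
        summary = pd.DataFrame(
            [
                {
                    "percent_genome_impacted": artil.percent_genome_impacted,
                    "n_regions": len(artil),
                    "n_adv": artil.n_adv,
                    "n_del": artil.n_del,
                    "prop_adv": artil.proportions["ADV"],
                    "prop_del": artil.proportions["DEL"],
                }
            ]
        )
        emit(_write_tsv(summary, out / "summary.tsv"))
        emit(_write_tsv(artil.to_frame(), out / "artil.tsv"))
        log.info(
            "call: %d regions (%d ADV / %d DEL), %.2f%% of genome",
            len(artil), artil.n_adv, artil.n_del, artil.percent_genome_impacted,
        )
        stages.append(("call", "ran"))
    else:
        stages.append(("normalize", "skipped: need >=2 replicates per condition"))
        stages.append(("segment", "skipped: no normalized profiles"))
        stages.append(("call", "skipped: no normalized profiles"))

    # ---------------------------------------------------------- transmission
    n1_control = [profiles[k] for k in sorted(profiles) if k[0] == "control" and k[1] == "n1"]
    n1_treated = [profiles[k] for k in sorted(profiles) if k[0] == "treated" and k[1] == "n1"]
    if artil is not None and len(n1_control) >= 2 and len(n1_treated) >= 2:
        normed = normalize_replicates(n1_control + n1_treated)
        daughter = call_differential(normed[: len(n1_control)], normed[len(n1_control):], params)
        report = assess_transmission(artil, daughter, cfg.min_recip)
        emit(_write_tsv(report.records, out / "transmission.tsv"))
        log.info("transmission: %d of %d regions", report.n_transmitted, report.n_total)
        stages.append(("transmission", "ran"))
    else:
        stages.append(("transmission", "skipped: no daughter cohort"))

    # ---------------------------------------------------------- characterize
    feature_tracks: dict[str, RegionSet] = {}
    if cfg.simulate:
        feature_tracks = {"origins": tracks["origins"], "genes": tracks["genes"]}
        marks = tracks["marks"]
        genes = tracks["genes"]
    else:
        marks = {Path(p).stem: io.read_bed(p) for p in cfg.marks_beds}
        genes = io.read_bed(cfg.genes_bed) if cfg.genes_bed else None
        if genes is not None:
            feature_tracks["genes"] = genes
        if cfg.origins_bed:
            feature_tracks["origins"] = io.read_bed(cfg.origins_bed)
    if artil is not None and len(artil):
        for direction in ("ADV", "DEL"):
            rs = artil.to_region_set(direction)
            if not len(rs):
                continue
            stats_df = region_stats_table(rs, fasta_seqs, feature_tracks)
            emit(_write_tsv(stats_df, out / f"region_stats_{direction.lower()}.tsv"))
        if len(marks) >= 2 and domains is not None:
            groups: dict[str, RegionSet] = {}
            for lab in ("Early", "Mid", "Late"):
                g = domains.to_region_set(lab)
                if len(g):
                    groups[lab] = g
            for direction in ("ADV", "DEL"):
                rs = artil.to_region_set(direction)
                if len(rs):
                    groups[direction] = rs
                    if genome is not None:
                        groups[f"{direction}-random"] = shuffle_regions(
                            rs, genome, stage_seed(cfg.seed, "characterize")
                        )
            if len(groups) >= 2:
                cm = mark_coverage_matrix(groups, marks)
                mat = cm.ordered().reset_index().rename(columns={"index": "region_class"})
                emit(_write_tsv(mat, out / "coverage_matrix.tsv"))
                if cm.row_linkage is not None:
                    (out / "coverage_dendrogram.nwk").write_text(
                        linkage_to_newick(cm.row_linkage, list(cm.matrix.index)) + "\n"
                    )
                    emit(out / "coverage_dendrogram.nwk")
        stages.append(("characterize", "ran"))
    else:
        stages.append(("characterize", "skipped: no called regions"))

    # ---------------------------------------------------------------- enrich
    cfs = tracks.get("cfs") if cfg.simulate else (io.read_bed(cfg.cfs_bed, "CFS") if cfg.cfs_bed else None)
    if artil is not None and cfs is not None and genome is not None:
        rows = []
        for direction in ("ADV", "DEL"):
            rs = artil.to_region_set(direction)
            if not len(rs):
                continue
            res = enrichment_z(
                rs, cfs, genome, n_shuffles=cfg.n_shuffles,
                seed=stage_seed(cfg.seed, "enrich"),
            )
            rows.append(
                {
                    "query": direction, "target": "CFS",
                    "observed_jaccard": res.observed_jaccard,
                    "null_mean": res.null_mean, "null_sd": res.null_sd,
                    "z_score": res.z_score, "empirical_p": res.empirical_p,
                    "n_shuffles": res.n_shuffles, "seed": res.seed,
                }
            )
        if rows:
            emit(_write_tsv(pd.DataFrame(rows), out / "enrichment.tsv"))
            stages.append(("enrich", "ran"))
    else:
        stages.append(("enrich", "skipped: needs called regions, CFS track and genome"))

    # --------------------------------------------------------------- cluster
    cohorts: dict[str, list] = {}
    for (cond, gen, rep), p in profiles.items():
        cohorts.setdefault(f"{cond}.{gen}", []).append(p)
    if len(cohorts) >= 3:
        mtx = build_rt_matrix(cohorts, cfg.span_bp)
        res = cluster_cohorts(mtx, n_bootstrap=100, seed=stage_seed(cfg.seed, "cluster"))
        (out / "clusters.nwk").write_text(res.newick + "\n")
        emit(out / "clusters.nwk")
        stages.append(("cluster", "ran"))
    else:
        stages.append(("cluster", "skipped: fewer than three cohorts"))

    # ------------------------------------------------------------------ atac
    atac_tracks = tracks.get("atac_peaks", {}) if cfg.simulate else None
    if not cfg.simulate and cfg.atac_control and cfg.atac_treated:
        atac_tracks = {}
        for cond, paths in (("control", cfg.atac_control), ("treated", cfg.atac_treated)):
            for i, p in enumerate(paths):
                rs = io.read_bed(p)
                atac_tracks[(cond, f"r{i + 1}")] = atac_mod.PeakTrack(
                    np.array([iv.chrom for iv in rs], dtype=object),
                    np.array([iv.start for iv in rs]),
                    np.array([iv.end for iv in rs]),
                    np.array([iv.score or 0.0 for iv in rs]),
                    condition=cond, replicate=f"r{i + 1}",
                )
    if atac_tracks and artil is not None and domains is not None:
        ctrl = [t for k, t in sorted(atac_tracks.items()) if k[0] == "control"]
        trt = [t for k, t in sorted(atac_tracks.items()) if k[0] == "treated"]
        normed_tracks = atac_mod.normalize_peak_values(ctrl + trt)
        mean_c = atac_mod.average_replicates(normed_tracks[: len(ctrl)])
        mean_t = atac_mod.average_replicates(normed_tracks[len(ctrl):])
        pairs = atac_mod.match_peaks(mean_c, mean_t, cfg.max_center_dist)
        classes: dict[str, RegionSet] = {}
        for direction in ("ADV", "DEL"):
            rs = artil.to_region_set(direction)
            if len(rs):
                classes[direction] = rs
        for lab in ("Early", "Mid", "Late"):
            g = domains.to_region_set(lab)
            if len(g):
                classes[lab] = g
        results = atac_mod.regional_peak_comparison(pairs, classes)
        df = pd.DataFrame(
            [
                {
                    "region_class": r.region_class, "n_pairs": r.n_pairs,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "median_shift": r.median_shift, "underpowered": r.underpowered,
                }
                for r in results.values()
            ]
        )
        emit(_write_tsv(df, out / "atac_comparison.tsv"))
        stages.append(("atac", "ran"))
    else:
        stages.append(("atac", "skipped: no peak tracks or no called regions"))

    # -------------------------------------------------------------- manifest
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    emit(out / "params.yaml")
    emit(_write_tsv(pd.DataFrame(stages, columns=["stage", "status"]), out / "stages.tsv"))
    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(set(emitted))}
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("path\tsha256\n")
        for rel, digest in sorted(manifest.items()):
            fh.write(f"{rel}\t{digest}\n")
    return manifest
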