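"""Pipeline orchestration: validated config, staged runs, manifest.

A run is driven by one YAML config.  Each stage either consumes input
files named in the config or, when none are given, simulates its own
inputs with the in-package generators (seeded, so reruns are
bit-identical).  Outputs are plain text (TSV/JSON/FASTA/Newick/VCF); a
manifest JSON records the config hash, package version, per-output
checksums, record counts and wall time per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__, io
from .alignment import Alignment
from .conflict import (DEFAULT_CLADE_MINIMA, Orthogroup, build_hypotheses,
                       delta_gls, exclude_outliers, filter_low_copy,
                       gene_topology_likelihoods, support_counts)
from .models import get_model
from .popgen import diversity_stats, hudson_fst, neighbor_joining, pairwise_distance
from .synteny import AnchorPair, chain_anchors, depth_ratio, syntenic_depth
from .synthetic import (Demography, simulate_coalescent, simulate_gene_set,
                        simulate_paranome, simulate_wgd_genome)
from .wgd import KsDistribution, ks_density_peaks, ks_to_age, ng86_ks

__all__ = ["RunConfig", "RunManifest", "ConfigError", "validate_config",
           "run_pipeline", "STAGES"]

STAGES = ("conflict", "wgd", "synteny", "popgen")


class ConfigError(ValueError):
    pass


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConflictConfig(_StrictModel):
    n_genes: int = Field(60, ge=1)
    length: int = Field(300, ge=1)
    mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    internal_length: float = Field(0.05, ge=0)
    terminal_length: float = Field(0.2, ge=0)
    model: Literal["jc69", "hky", "gtr", "wag"] = "jc69"
    gamma_shape: Optional[float] = Field(None, gt=0)
    tie_tol: float = Field(1e-3, gt=0)
    outlier_k: float = Field(1.5, gt=0)
    clade_minima: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_CLADE_MINIMA))
    n_species: dict[str, int] = Field(default_factory=lambda: {
        "eudicot": 4, "monocot": 4, "magnoliid": 3,
        "basal_angiosperm": 1, "gymnosperm": 1})
    # optional real inputs (all three must be given together)
    orthogroups_tsv: Optional[Path] = None
    alignment_dir: Optional[Path] = None
    clade_map_tsv: Optional[Path] = None


class WgdConfig(_StrictModel):
    n_background: int = Field(600, ge=0)
    n_wgd: int = Field(400, ge=0)
    wgd_mean: float = Field(0.7, gt=0)
    wgd_sd: float = Field(0.08, gt=0)
    decay_rate: float = Field(1.0, gt=0)
    bandwidth: float | Literal["silverman"] = "silverman"
    ks_range: tuple[float, float] = (0.01, 3.0)
    min_prominence: float = Field(0.1, gt=0, le=1)
    rate: float = Field(3.02e-9, gt=0)  # synonymous substitutions /site/yr
    emit_codon_pairs: bool = False
    ks_tsv: Optional[Path] = None  # optional real input: per-pair Ks table


class SyntenyConfig(_StrictModel):
    n_genes: int = Field(2000, ge=10)
    retention_rate: float = Field(0.6, ge=0, le=1)
    n_shuffles: int = Field(20, ge=0)
    n_copies: int = Field(2, ge=2)
    min_block: int = Field(5, ge=1)
    max_gap: int = Field(25, ge=1)
    # optional real inputs
    genome_a_tsv: Optional[Path] = None
    genome_b_tsv: Optional[Path] = None
    anchors_tsv: Optional[Path] = None


class PopgenConfig(_StrictModel):
    samples_per_deme: tuple[int, ...] = (20, 20, 20)
    deme_sizes: tuple[float, ...] = (10_000.0, 10_000.0, 10_000.0)
    split_times: tuple[float, ...] = (20_000.0, 40_000.0)
    migration: dict[str, float] = Field(default_factory=dict)  # "i-j" -> rate
    theta: float = Field(30.0, gt=0)
    locus_length: int = Field(100_000, ge=1)
    # optional real inputs
    vcf: Optional[Path] = None
    groups_tsv: Optional[Path] = None
    callable_length: Optional[int] = Field(None, ge=1)


class RunConfig(_StrictModel):
    seed: int = Field(..., ge=0, lt=2 ** 31)
    output_dir: Path
    stages: tuple[str, ...] = STAGES
    conflict: ConflictConfig = Field(default_factory=ConflictConfig)
    wgd: WgdConfig = Field(default_factory=WgdConfig)
    synteny: SyntenyConfig = Field(default_factory=SyntenyConfig)
    popgen: PopgenConfig = Field(default_factory=PopgenConfig)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)


class RunManifest(_StrictModel):
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = Field(default_factory=dict)
    completed: list[str] = Field(default_factory=list)
    failed: Optional[str] = None


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and range-check a YAML config (path, text or mapping).

    Unknown keys and out-of-range values raise :class:`ConfigError`
    listing every violation.
    """
    if isinstance(source, dict):
        payload = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError("config must be a mapping")
    try:
        cfg = RunConfig(**payload)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from exc
    unknown = [s for s in cfg.stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}; valid: {list(STAGES)}")
    for pc in (cfg.popgen,):
        d = len(pc.deme_sizes)
        for key in pc.migration:
            try:
                i, j = (int(x) for x in key.split("-"))
            except ValueError:
                raise ConfigError(f"migration key {key!r} must look like 'i-j'")
            if not (0 <= i < d and 0 <= j < d and i != j):
                raise ConfigError(f"migration between nonexistent demes: {key!r}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _stage_conflict(cfg: RunConfig, out: Path, log) -> dict:
    c = cfg.conflict
    model = get_model(c.model, gamma_shape=c.gamma_shape)
    if c.orthogroups_tsv is not None:
        orthogroups = io.read_orthogroups(c.orthogroups_tsv)
        clade_map = io.read_clade_map(c.clade_map_tsv)
        for og in orthogroups:
            fasta = Path(c.alignment_dir) / f"{og.id}.fasta"
            og.alignment = Alignment.from_fasta(fasta, alphabet="dna"
                                                if model.n_states == 4 else "protein")
        clade_species: dict[str, list[str]] = {}
        for sp, clade in clade_map.items():
            clade_species.setdefault(clade, []).append(sp)
        for v in clade_species.values():
            v.sort()
        orthogroups = filter_low_copy(orthogroups, clade_map, clade_minima=c.clade_minima)
        truth = None
    else:
        clade_species = {clade: [f"{clade[:3]}{i}" for i in range(n)]
                         for clade, n in c.n_species.items()}
        clade_map = {sp: clade for clade, spp in clade_species.items() for sp in spp}
        hypotheses = build_hypotheses(clade_species)
        gs = simulate_gene_set(hypotheses, c.mixture, c.n_genes, c.length,
                               c.internal_length, c.terminal_length, model, cfg.seed)
        orthogroups = [Orthogroup(f"og{i:04d}", {n: [n] for n in a.names}, a)
                       for i, a in enumerate(gs.alignments)]
        truth = gs.true_topology_labels
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for og in orthogroups:
            og.alignment.to_fasta(aln_dir / f"{og.id}.fasta")
    hypotheses = build_hypotheses(clade_species)
    (out / "hypotheses.nwk").write_text(
        "".join(h.tree.to_newick() + "\n" for h in hypotheses))
    log(f"conflict: scoring {len(orthogroups)} orthogroups against 3 hypotheses")
    results = []
    for og in orthogroups:
        lnls = gene_topology_likelihoods(og, hypotheses, model)
        results.append(delta_gls(lnls, tie_tol=c.tie_tol, orthogroup_id=og.id))
    survivors = exclude_outliers(results, k=c.outlier_k) if len(results) >= 5 else results
    sc = support_counts(survivors)
    io.write_gene_results(results, out / "gene_results.tsv")
    io.write_support_summary(sc, out / "support_summary.json")
    if truth is not None:
        _write_json({"true_topology_labels": truth, "mixture": list(c.mixture)},
                    out / "truth.json")
    log(f"conflict: counts {sc.counts}, chi2={sc.chi2:.4f}, p={sc.p:.4f}")
    return {"n_orthogroups": len(orthogroups), "n_after_outliers": len(survivors),
            "counts": list(sc.counts), "chi2": sc.chi2, "p": sc.p}


def _stage_wgd(cfg: RunConfig, out: Path, log) -> dict:
    c = cfg.wgd
    if c.ks_tsv is not None:
        import pandas as pd
        df = pd.read_csv(c.ks_tsv, sep="\t")
        dist = KsDistribution(df["ks"].to_numpy(),
                              df.get("weight", np.ones(len(df))).to_numpy())
        truth = None
    else:
        par = simulate_paranome(c.n_background, c.n_wgd, c.wgd_mean, c.wgd_sd,
                                c.decay_rate, seed=cfg.seed,
                                emit_codon_pairs=c.emit_codon_pairs)
        if par.codon_pairs is not None:
            estimates = [ng86_ks(p, pair_id=f"pair{i:05d}")
                         for i, p in enumerate(par.codon_pairs)]
            values = np.array([e.ks for e in estimates])
        else:
            values = par.ks_values
        dist = KsDistribution(values, np.ones_like(values))
        truth = {"wgd_mean": c.wgd_mean, "n_wgd": c.n_wgd,
                 "n_background": c.n_background}
    peaks = ks_density_peaks(dist, bandwidth=c.bandwidth, ks_range=c.ks_range,
                             min_prominence=c.min_prominence)
    ages = [ks_to_age(loc, c.rate) for loc, _ in peaks]
    payload = {
        "n_values": int(np.isfinite(dist.values).sum()),
        "bandwidth": dist.bandwidth,
        "peaks": [{"ks": loc, "density": h, "age_ma": age.ma}
                  for (loc, h), age in zip(peaks, ages)],
        "rate": c.rate,
    }
    _write_json(payload, out / "ks_peaks.json")
    if truth is not None:
        _write_json(truth, out / "truth.json")
    np.savetxt(out / "ks_values.tsv", dist.values, fmt="%.6f", header="ks",
               comments="")
    top = f"{peaks[0][0]:.3f} -> {ages[0].ma:.1f} Ma" if peaks else "none"
    log(f"wgd: {len(peaks)} peak(s); top {top}")
    return payload


def _stage_synteny(cfg: RunConfig, out: Path, log) -> dict:
    c = cfg.synteny
    if c.anchors_tsv is not None:
        genome_a = io.read_genome_ranks(c.genome_a_tsv)
        genome_b = io.read_genome_ranks(c.genome_b_tsv)
        anchors = io.read_anchors(c.anchors_tsv)
        truth = None
    else:
        sim = simulate_wgd_genome(c.n_genes, c.retention_rate, c.n_shuffles,
                                  seed=cfg.seed, n_copies=c.n_copies)
        genome_a, genome_b = sim.ancestral, sim.derived
        anchors = [AnchorPair(a, b) for a, b in sim.anchor_pairs]
        truth = {"retention_rate": c.retention_rate, "n_copies": c.n_copies}
    blocks = chain_anchors(anchors, genome_a, genome_b,
                           max_gap=c.max_gap, min_block=c.min_block)
    prof_a = syntenic_depth(blocks, genome_a, side="a")
    prof_b = syntenic_depth(blocks, genome_b, side="b")
    ratio = depth_ratio(prof_a, prof_b)
    io.write_blocks(blocks, out / "blocks.tsv")
    io.write_depths(prof_a.depths, out / "depth_a.tsv")
    io.write_depths(prof_b.depths, out / "depth_b.tsv")
    payload = {"n_anchors": len(anchors), "n_blocks": len(blocks),
               "modal_depth_a": prof_a.modal_depth,
               "modal_depth_b": prof_b.modal_depth,
               "depth_ratio": f"{ratio[0]}:{ratio[1]}",
               "histogram_a": prof_a.histogram, "histogram_b": prof_b.histogram}
    _write_json(payload, out / "depth_ratio.json")
    if truth is not None:
        _write_json(truth, out / "truth.json")
    log(f"synteny: {len(blocks)} blocks; depth ratio {ratio[0]}:{ratio[1]}")
    return payload


def _stage_popgen(cfg: RunConfig, out: Path, log) -> dict:
    c = cfg.popgen
    if c.vcf is not None:
        if c.callable_length is None:
            raise ConfigError("callable_length is required with a VCF input")
        matrix = io.read_vcf(c.vcf, L=c.callable_length, ploidy=2)
        groups = io.read_group_file(c.groups_tsv)
    else:
        migration = {tuple(int(x) for x in k.split("-")): v
                     for k, v in c.migration.items()}
        dem = Demography(c.deme_sizes, c.split_times, migration)
        sample = simulate_coalescent(c.samples_per_deme, dem, c.theta,
                                     c.locus_length, cfg.seed)
        matrix = sample.snp_matrix
        groups = {s: f"pop{d}" for s, d in sample.deme_assignment.items()}
        io.write_vcf(matrix, out / "snps.vcf")
        io.write_clade_map(groups, out / "groups.tsv")
    by_group: dict[str, list[str]] = {}
    for s, g in groups.items():
        by_group.setdefault(g, []).append(s)
    stats = {g: diversity_stats(matrix, sorted(members), label=g)
             for g, members in sorted(by_group.items())}
    fsts = {}
    names = sorted(by_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            fst = hudson_fst(matrix, sorted(by_group[a]), sorted(by_group[b]),
                             labels=(a, b))
            fsts[f"{a}-{b}"] = fst.fst
    tree = neighbor_joining(pairwise_distance(matrix), matrix.samples)
    (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    payload = {
        "groups": {g: {"pi": s.pi, "theta_w": s.theta_w, "S": s.S, "n": s.n}
                   for g, s in stats.items()},
        "fst": fsts,
        "n_sites": matrix.n_sites,
        "L": matrix.L,
    }
    _write_json(payload, out / "diversity.json")
    log(f"popgen: {matrix.n_sites} SNPs; "
        + "; ".join(f"{g}: pi={s.pi:.5f}" for g, s in stats.items()))
    return payload


_STAGE_FUNCS = {"conflict": _stage_conflict, "wgd": _stage_wgd,
                "synteny": _stage_synteny, "popgen": _stage_popgen}


def run_pipeline(config: RunConfig, log=None) -> RunManifest:
    """Execute the selected stages in order and write the run manifest.

    A stage failure halts the run; the manifest still records the stages
    that completed.  Deterministic stages rerun bit-identically for a
    fixed config (checksums in the manifest make this checkable).
    """
    if log is None:
        import sys

        def log(msg: str) -> None:
            print(msg, file=sys.stderr)

    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        version=__version__, seed=config.seed)
    for stage in config.stages:
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        log(f"[{stage}] starting")
        try:
            summary = _STAGE_FUNCS[stage](config, stage_dir, log)
        except Exception as exc:
            manifest.failed = f"{stage}: {exc}"
            _write_json(manifest.model_dump(mode="json"), out_root / "manifest.json")
            raise
        checksums = {p.name: _sha256(p) for p in sorted(stage_dir.iterdir())
                     if p.is_file()}
        manifest.stages[stage] = {
            "summary": summary, "checksums": checksums,
            "wall_time_s": round(time.time() - t0, 3),
        }
        manifest.completed.append(stage)
        log(f"[{stage}] done in {manifest.stages[stage]['wall_time_s']}s")
    _write_json(manifest.model_dump(mode="json"), out_root / "manifest.json")
    return manifest
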