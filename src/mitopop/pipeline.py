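"""End-to-end analysis pipeline: read -> prune -> collapse -> statistics.

Given a FASTA alignment, a sample-metadata table and a YAML/dict config,
runs the full mitochondrial phylogeography workflow and writes per-stage
artifacts plus a run manifest (seeds, checksums, model choices) so a rerun
with the same config and inputs reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .dating import expansion_time
from .diversity import INVERTEBRATE_MITO, diversity_stats
from .errors import ConfigError, SizeError
from .mismatch import expected_mismatch, fit_expansion, mismatch_histogram, parametric_bootstrap
from .network import median_joining, mp_prune
from .neutrality import neutrality_significance
from .seq_io import (
    collapse_haplotypes,
    prune_one_per_site,
    read_alignment,
    read_metadata,
    write_alignment,
)

log = logging.getLogger("mitopop")


@dataclass
class RunConfig:
    fasta: str
    metadata: str | None = None
    outdir: str = "mitopop_out"
    seed: int = 1
    lineage: str | None = None
    prune: bool = True
    genetic_code: int = INVERTEBRATE_MITO
    frame_offset: int | None = None
    epsilon: int = 0
    mp_postprocess: bool = True
    neutrality_reps: int = 10_000
    bootstrap_reps: int = 10_000
    weight_by_count: bool = True
    mu_site: float = 6.6e-8
    gen_per_year: tuple[float, float] = (2.0, 5.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise ConfigError(f"FASTA file not found: {self.fasta}")
        if self.metadata is not None and not Path(self.metadata).exists():
            raise ConfigError(f"metadata file not found: {self.metadata}")
        if self.prune and self.metadata is None:
            raise ConfigError("pruning to one individual per site requires metadata")
        for name in ("neutrality_reps", "bootstrap_reps"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100")
        lo, hi = self.gen_per_year
        if not 0 < lo <= hi:
            raise ConfigError("gen_per_year must satisfy 0 < low <= high")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to outdir)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package": "mitopop",
        "version": __version__,
        "seed": config.seed,
        "config": {**asdict(config), "gen_per_year": list(config.gen_per_year)},
        "inputs": {"fasta_sha256": _sha256(config.fasta)},
        "stages": {},
    }

    aln = read_alignment(config.fasta)
    meta = None
    if config.metadata:
        meta = read_metadata(config.metadata)
        manifest["inputs"]["metadata_sha256"] = _sha256(config.metadata)
    if config.lineage:
        if meta is None or "lineage" not in meta.columns:
            raise ConfigError("lineage filter requires metadata with a lineage column")
        keep = meta.loc[meta["lineage"] == config.lineage, "sample_id"]
        aln = aln.subset(keep)
        meta = meta[meta["lineage"] == config.lineage]
    log.info("alignment: %d sequences of %d nt", aln.n, aln.length)

    if config.prune:
        aln = prune_one_per_site(aln, meta, seed=config.seed)
        log.info("pruned to one individual per site: %d sequences", aln.n)
        write_alignment(aln, out / "pruned.fasta")
    manifest["stages"]["input"] = {"n": aln.n, "L": aln.length}

    # --- diversity -------------------------------------------------------
    ht = collapse_haplotypes(aln)
    stats = diversity_stats(aln, code=config.genetic_code, frame_offset=config.frame_offset)
    with open(out / "diversity.tsv", "w") as fh:
        fh.write("lineage\tN\tK\tH\tS\tpi_s\tpi_n\n")
        fh.write(stats.tsv_row(config.lineage or "all") + "\n")
    _dump_json(out / "diversity.json", asdict(stats))
    manifest["stages"]["diversity"] = asdict(stats)
    log.info("diversity: N=%d K=%d H=%.3f S=%d", stats.n, stats.k, stats.h, stats.s)

    # --- neutrality ------------------------------------------------------
    neut = neutrality_significance(aln, reps=config.neutrality_reps, seed=config.seed)
    with open(out / "neutrality.tsv", "w") as fh:
        fh.write("statistic\tvalue\tp\treps\tseed\n")
        fh.write(f"tajimas_D\t{neut.d:.6f}\t{neut.p_d:.6g}\t{neut.reps}\t{neut.seed}\n")
        fh.write(f"fu_Fs\t{neut.fs:.6f}\t{neut.p_fs:.6g}\t{neut.reps}\t{neut.seed}\n")
    _dump_json(out / "neutrality.json", asdict(neut))
    manifest["stages"]["neutrality"] = asdict(neut)
    log.info("neutrality: D=%.3f (p=%.4g) Fs=%.3f (p=%.4g)", neut.d, neut.p_d, neut.fs, neut.p_fs)

    # --- mismatch / expansion fit ---------------------------------------
    obs = mismatch_histogram(aln if config.weight_by_count else ht,
                             weight_by_count=config.weight_by_count)
    fit = fit_expansion(obs)
    fit = parametric_bootstrap(
        obs, fit, L=aln.length, reps=config.bootstrap_reps, seed=config.seed
    )
    exp = expected_mismatch(fit.tau, fit.theta0, obs.d_max)
    with open(out / "mismatch.tsv", "w") as fh:
        fh.write("i\tcount\tobs_freq\texp_freq\n")
        for i, (c, o, e) in enumerate(zip(obs.counts, obs.freqs, exp)):
            fh.write(f"{i}\t{c}\t{o:.6f}\t{e:.6f}\n")
    fit_dict = asdict(fit)
    fit_dict["theta1"] = None if math.isinf(fit.theta1) else fit.theta1
    _dump_json(out / "mismatch_fit.json", fit_dict)
    manifest["stages"]["mismatch"] = fit_dict
    log.info("mismatch fit: tau=%.3f (CI %.2f-%.2f) SSD p=%.3f raggedness=%.4f p=%.3f",
             fit.tau, *fit.tau_ci, fit.p_ssd, fit.raggedness, fit.p_raggedness)

    # --- network ---------------------------------------------------------
    net = median_joining(ht, epsilon=config.epsilon)
    mp_applied = False
    if config.mp_postprocess:
        try:
            net = mp_prune(net)
            mp_applied = True
        except SizeError as err:
            log.warning("MP post-processing skipped: %s", err)
    g = net.to_networkx()
    nx.write_graphml(g, out / "network.graphml")
    with open(out / "network_edges.tsv", "w") as fh:
        fh.write("node1\tnode2\tlength\tnode1_count\tnode2_count\tnode1_is_median\tnode2_is_median\n")
        attrs = dict(zip(net.node_ids, zip(net.node_counts, net.is_median)))
        for u, v, w in net.edges:
            fh.write(f"{u}\t{v}\t{w}\t{attrs[u][0]}\t{attrs[v][0]}\t"
                     f"{int(attrs[u][1])}\t{int(attrs[v][1])}\n")
    manifest["stages"]["network"] = {
        "nodes": len(net.node_ids),
        "observed_haplotypes": ht.k,
        "median_vectors": net.n_medians,
        "edges": len(net.edges),
        "total_length": net.total_length,
        "epsilon": config.epsilon,
        "mp_applied": mp_applied,
    }
    log.info("network: %d haplotypes, %d median vectors, %d edges",
             ht.k, net.n_medians, len(net.edges))

    # --- dating ----------------------------------------------------------
    et = expansion_time(fit.tau, config.mu_site, aln.length, config.gen_per_year)
    dating = {
        **asdict(et),
        "generations_rounded": et.generations_rounded,
        "years_rounded": list(et.years_rounded),
        "tau_ci_generations": [
            expansion_time(t, config.mu_site, aln.length, config.gen_per_year).generations_rounded
            for t in fit.tau_ci if t > 0
        ],
    }
    _dump_json(out / "dating.json", dating)
    manifest["stages"]["dating"] = dating
    log.info("dating: %s generations (%s-%s years ago)",
             et.generations_rounded, *et.years_rounded)

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    _dump_json(out / "manifest.json", manifest)
    return manifest


def _dump_json(path: Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
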