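"""End-to-end orchestration of the analysis stages.

A run is described by a flat INI-style config file (``key = value`` lines
under one section per stage); stages present in the file are executed in
dependency order (simulate first, then the independent analyses).  Every
stage writes one output file; a JSON manifest records package version,
config digest, seeds, SHA-256 digests of all outputs and per-stage
summaries.  Failures are recorded per stage and do not stop later,
independent stages.  Re-running with an identical config reproduces
byte-identical numeric outputs.

Example config::

    [run]
    outdir = out
    seed = 7

    [simulate]
    n_taxa = 100
    n_orfs = 2000
    n_samples = 2

    [stats]
    [census]
    [richness]
    environment = drum1

    [aacomp]
    n1 = 40
    n2 = 30

    [kaks]
    omegas = 0.1,1,5
    n_seeds = 5
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import metadata as _im
from pathlib import Path

import numpy as np
import pandas as pd

from . import aacomp, census, community, richness, selection, synthetic, tables_io
from .errors import ConfigError, DeuteromicsError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "stats", "census", "aacomp", "kaks", "richness")


@dataclass
class RunConfig:
    """Parsed run description: output directory, seed and per-stage options."""

    outdir: Path
    seed: int = 0
    stages: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ConfigError(f"cannot read config file {path}")
        outdir = Path(parser.get("run", "outdir", fallback="deuteromics_out"))
        seed = parser.getint("run", "seed", fallback=0)
        stages = {name: dict(parser[name]) for name in parser.sections()
                  if name != "run"}
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stage section(s): {sorted(unknown)}")
        for name, opts in stages.items():
            if opts.get("enabled", "true").lower() in ("false", "0", "no"):
                stages[name] = None
        return cls(outdir=outdir, seed=seed,
                   stages={k: v for k, v in stages.items() if v is not None})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_table(opts: dict, default_path: Path | None) -> tables_io.OrfTable:
    path = opts.get("table") or default_path
    if path is None:
        raise ConfigError("no ORF table available: give 'table =' or enable "
                          "the simulate stage")
    return tables_io.read_orf_table(path)


def _stage_simulate(opts, ctx):
    fields = {f.name: f.type for f in dataclasses.fields(synthetic.CommunityConfig)}
    kwargs = {}
    for key, raw in opts.items():
        if key in ("enabled",):
            continue
        if key not in fields:
            raise ConfigError(f"unknown simulate option {key!r}")
        if key == "abundance_log10_range":
            kwargs[key] = tuple(float(x) for x in raw.split(","))
        elif key in ("noiseless", "normalize"):
            kwargs[key] = raw.lower() in ("1", "true", "yes")
        elif key == "transposase_tpm_share":
            kwargs[key] = None if raw.lower() == "none" else float(raw)
        elif key in ("n_taxa", "n_orfs", "n_samples", "min_bp", "max_bp", "seed"):
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    kwargs.setdefault("seed", ctx["seed"])
    table = synthetic.generate_orf_table(synthetic.CommunityConfig(**kwargs))
    out = ctx["outdir"] / "orf_table.tsv"
    tables_io.write_orf_table(table, out)
    ctx["table_path"] = out
    return [out], {"n_orfs": len(table), "n_samples": len(table.sample_ids),
                   "zero_richness_taxa": len(table.metadata["zero_richness_taxa"])}


def _stage_stats(opts, ctx):
    table = _load_table(opts, ctx.get("table_path"))
    include_unknowns = opts.get("include_unknowns", "false").lower() in ("1", "true")
    wl = community.weighted_gene_length(table)
    rows = [
        {"statistic": "weighted_mean_length_bp", "scope": "pooled",
         "value": wl.mean_bp},
        {"statistic": "weighted_sd_length_bp", "scope": "pooled",
         "value": wl.sd_bp},
        {"statistic": "gc_mean", "scope": "pooled",
         "value": community.gc_content(table)},
    ]
    sets = {}
    for s in table.sample_ids:
        rows.append({"statistic": "richness_known", "scope": s,
                     "value": community.species_richness(table, s, False)})
        rows.append({"statistic": "richness_with_unknowns", "scope": s,
                     "value": community.species_richness(table, s, True)})
        sets[s] = community.species_set(table, s, include_unknowns)
    for i, a in enumerate(table.sample_ids):
        for b in table.sample_ids[i + 1:]:
            rows.append({"statistic": "jaccard", "scope": f"{a}|{b}",
                         "value": community.jaccard(sets[a], sets[b])})
    out = ctx["outdir"] / "stats.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.10g")
    return [out], {"weighted_mean_length_bp": wl.mean_bp}


def _stage_census(opts, ctx):
    table = _load_table(opts, ctx.get("table_path"))
    matcher = census.TRANSPOSASE_MATCHER
    if "keywords" in opts or "orthogroups" in opts:
        matcher = census.CategoryMatcher(
            keywords=frozenset(k.strip() for k in
                               opts.get("keywords", "transposase").split(",")),
            orthogroups=frozenset(o.strip() for o in
                                  opts.get("orthogroups", "").split(",") if o.strip()),
            description="user matcher")
    result = census.transposase_census(table, matcher)
    out = ctx["outdir"] / "census.tsv"
    result.to_dataframe().to_csv(out, sep="\t", index=False, float_format="%.10g")
    summary = {"mean_count_pct": result.mean_count_pct,
               "mean_tpm": result.mean_tpm,
               "orphan_pct": census.orphan_fraction(table)}
    if "genes" in opts:
        genes = [g.strip() for g in opts["genes"].split(",") if g.strip()]
        gout = ctx["outdir"] / "gene_tpm.tsv"
        census.gene_tpm_table(table, genes).to_csv(gout, sep="\t",
                                                   float_format="%.10g")
        return [out, gout], summary
    return [out], summary


def _stage_aacomp(opts, ctx):
    if "group_a" in opts and "group_b" in opts:
        mat_a = aacomp.composition_matrix(
            tables_io.read_fasta(opts["group_a"]), "group_a")
        mat_b = aacomp.composition_matrix(
            tables_io.read_fasta(opts["group_b"]), "group_b")
    else:
        mat_a, mat_b = synthetic.generate_aa_groups(
            n1=int(opts.get("n1", 129)), n2=int(opts.get("n2", 70)),
            seed=int(opts.get("seed", ctx["seed"])))
    result = aacomp.enrichment_test(
        mat_a, mat_b,
        alpha=float(opts.get("alpha", 0.05)),
        correction=opts.get("correction", "none"))
    out = ctx["outdir"] / "aacomp.tsv"
    result.per_residue.to_csv(out, sep="\t", float_format="%.10g")
    n_enr, n_dep, n_same = result.counts
    return [out], {"self_correlation_a": aacomp.group_self_correlation(mat_a),
                   "self_correlation_b": aacomp.group_self_correlation(mat_b),
                   "n_enriched": n_enr, "n_depleted": n_dep, "n_same": n_same}


def _read_pair_manifest(path: str) -> list[selection.CodonSequencePair]:
    manifest = pd.read_csv(path, sep="\t")
    pairs = []
    for row in manifest.itertuples(index=False):
        seqs_a = dict(tables_io.read_fasta(row.file_a))
        seqs_b = dict(tables_io.read_fasta(row.file_b))
        pairs.append(selection.CodonSequencePair(
            seq_a=seqs_a[row.id_a], seq_b=seqs_b[row.id_b],
            id_a=row.id_a, id_b=row.id_b))
    return pairs


def _stage_kaks(opts, ctx):
    band = tuple(float(x) for x in
                 opts.get("neutral_band", "0.9,1.1").split(","))
    if "pairs" in opts:
        pairs = _read_pair_manifest(opts["pairs"])
    else:
        omegas = [float(x) for x in opts.get("omegas", "0.1,1,5").split(",")]
        n_seeds = int(opts.get("n_seeds", 5))
        base_seed = int(opts.get("seed", ctx["seed"]))
        pairs = [synthetic.generate_codon_pair(synthetic.OmegaConfig(
                    omega=w, n_codons=int(opts.get("n_codons", 300)),
                    n_events=int(opts.get("n_events", 60)),
                    seed=base_seed + 1000 * i + j))
                 for i, w in enumerate(omegas) for j in range(n_seeds)]
    screen = selection.kaks_screen(pairs, neutral_band=band)
    out = ctx["outdir"] / "kaks.tsv"
    screen.table.to_csv(out, sep="\t", index=False, float_format="%.10g")
    return [out], {"regime_counts": screen.regime_counts,
                   "n_errors": len(screen.errors)}


def _stage_richness(opts, ctx):
    table = _load_table(opts, ctx.get("table_path"))
    scope = None
    if "gene_scope" in opts:
        scope = {a.strip() for a in opts["gene_scope"].split(",") if a.strip()}
    model = richness.PowerLawRichnessModel.from_orf_table(
        table, environment=opts.get("environment", "synthetic"),
        gene_scope=scope, min_dobs=int(opts.get("min_dobs", 1)))
    fit = model.fit()
    dist = fit.delta_distribution()
    fit_out = ctx["outdir"] / "richness_fit.json"
    fit_out.write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
    kde_out = ctx["outdir"] / "richness_kde.tsv"
    dist.to_dataframe().to_csv(kde_out, sep="\t", index=False,
                               float_format="%.10g")
    return [fit_out, kde_out], {"gamma": fit.gamma, "c": fit.c,
                                "r_squared": fit.r_squared,
                                "delta_spread": dist.spread}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "stats": _stage_stats,
    "census": _stage_census,
    "aacomp": _stage_aacomp,
    "kaks": _stage_kaks,
    "richness": _stage_richness,
}


def run_all(config: RunConfig) -> dict:
    """Execute every stage named in the config; return the run manifest.

    The manifest is also written to ``<outdir>/run_manifest.json``.  A
    stage failure is recorded (status ``failed`` plus the error message)
    without aborting later stages, except that stages needing the
    simulated table fail individually if it is unavailable.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    log_path = config.outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("deuteromics")
    root.addHandler(handler)

    try:
        version = _im.version("deuteromics")
    except _im.PackageNotFoundError:  # pragma: no cover
        version = "unknown"

    ctx = {"outdir": config.outdir, "seed": config.seed}
    manifest: dict = {"package": "deuteromics", "version": version,
                      "seed": config.seed, "stages": {}}
    try:
        for name in STAGE_ORDER:
            if name not in config.stages:
                continue
            logger.info("running stage %s", name)
            entry: dict = {"status": "ok", "outputs": {}, "summary": {},
                           "error": None}
            try:
                outputs, summary = _STAGE_FUNCS[name](config.stages[name], ctx)
                entry["outputs"] = {str(p): _sha256(Path(p)) for p in outputs}
                entry["summary"] = summary
            except (DeuteromicsError, OSError, KeyError, ValueError) as exc:
                logger.error("stage %s failed: %s", name, exc)
                entry["status"] = "failed"
                entry["error"] = str(exc)
            manifest["stages"][name] = entry
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest["ok"] = all(e["status"] == "ok" for e in manifest["stages"].values())
    (config.outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
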