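"""End-to-end pipeline orchestration with reproducible run manifests.

Stages (dependency order): ``simulate`` -> ``compose`` -> ``variance`` ->
``signal`` -> ``pgls`` -> ``correlations``.  Every stage reads and writes
plain-text TSV/Newick between steps; a JSON manifest records the tool
version, a hash of the configuration, input checksums, the seeds used,
per-stage runtimes and the produced files, so a rerun with the same
configuration is identical except for timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, function_matrix as fm, phylo_comparative as pcm
from . import seq_composition as sc, synthetic_data as sd
from . import taxonomy_partition as tp

logger = logging.getLogger(__name__)

STAGES = ("simulate", "compose", "variance", "signal", "pgls", "correlations")

DEFAULT_CONFIG = {
    "seed": 20260929,
    "stages": list(STAGES),
    "simulate": {
        "n_tips": 120,
        "birth_rate": 1.0,
        "trait": {"sigma2": 60.0, "root": 50.0, "transform": None,
                  "param": None},
        "ko": {"n_kos": 120, "beta_magnitude": 2.0,
               "frac_positive": 1 / 3, "frac_negative": 1 / 3},
        "genomes": {"n": 8, "n_cds": 60, "cds_length": 300,
                    "intergenic_length": 60},
        "taxonomy_fractions": {"phylum": 0.85, "class": 0.6, "order": 0.4,
                               "family": 0.25, "genus": 0.1,
                               "species": 0.02},
    },
    "signal": {"stats": ["K", "lambda", "kappa", "delta"], "n_perm": 199},
    "pgls": {"n_predictors": 8, "structure": "BM"},
    "correlations": {"alpha": 0.01},
}

_ALLOWED_TOP = set(DEFAULT_CONFIG) | {"out"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    bad = sorted(set(cfg) - _ALLOWED_TOP)
    if bad:
        raise ConfigError(f"unknown configuration keys: {bad}")
    def deep_merge(base: dict, override: dict) -> dict:
        out = dict(base)
        for key, val in override.items():
            if isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = deep_merge(out[key], val)
            else:
                out[key] = val
        return out

    merged = deep_merge(json.loads(json.dumps(DEFAULT_CONFIG)), cfg)
    unknown_stages = sorted(set(merged["stages"]) - set(STAGES))
    if unknown_stages:
        raise ConfigError(f"unknown stages: {unknown_stages}")
    merged["stages"] = [s for s in STAGES if s in merged["stages"]]
    if "pgls" in merged["stages"] and "simulate" not in merged["stages"]:
        raise ConfigError("stage 'pgls' needs the simulated tree; include "
                          "'simulate' or run the stages manually")
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("tree", "trait", "ko", "genomes", "taxonomy", "signal"),
        sd.spawn_seeds(int(config["seed"]), 6)))
    manifest = {"tool": "gcpanorama", "version": __version__,
                "config_hash": hashlib.sha256(
                    json.dumps(config, sort_keys=True).encode()).hexdigest(),
                "master_seed": int(config["seed"]), "seeds": seeds,
                "stages": {}, "outputs": [], "input_checksums": {}}
    state: dict = {}
    for stage in config["stages"]:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            produced = _STAGE_FUNCS[stage](config, out, seeds, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(exc)}
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"status": "ok",
                                     "runtime_s": round(dt, 3)}
        manifest["outputs"].extend(str(p.relative_to(out)) for p in produced)
        logger.info("stage %s: done in %.2fs", stage, dt)
    for rel in manifest["outputs"]:
        manifest["input_checksums"][rel] = _sha256(out / rel)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    stamped = dict(manifest)
    stamped["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(stamped, fh, indent=2, sort_keys=True)


# -- stages -----------------------------------------------------------------

def _stage_simulate(cfg, out: Path, seeds, state) -> list[Path]:
    sim = cfg["simulate"]
    tree = sd.sim_yule_tree(sim["n_tips"], sim["birth_rate"], seeds["tree"])
    tcfg = sim["trait"]
    trait = sd.sim_bm_trait(tree, tcfg["sigma2"], tcfg["root"],
                            tcfg.get("transform"), tcfg.get("param"),
                            seeds["trait"])
    kcfg = sim["ko"]
    komat, truth = sd.sim_ko_matrix(trait, kcfg["n_kos"],
                                    kcfg["beta_magnitude"],
                                    kcfg["frac_positive"],
                                    kcfg["frac_negative"],
                                    seed=seeds["ko"])
    depth = tree.max_depth()
    heights = {r: f * depth
               for r, f in sim["taxonomy_fractions"].items()}
    taxonomy = sd.sim_taxonomy(tree, heights)
    produced = []

    def save(path: Path):
        produced.append(path)
        return path

    pcm.write_newick(tree, save(out / "tree.nwk"),
                     include_internal_labels=False)
    pd.DataFrame({"tip": list(trait), "value": list(trait.values())}).to_csv(
        save(out / "trait.tsv"), sep="\t", index=False)
    komat.to_frame().to_csv(save(out / "ko_matrix.tsv"), sep="\t",
                            index_label="genome_id")
    truth.table.to_csv(save(out / "ko_truth.tsv"), sep="\t", index=False)
    tax_rows = [{"genome_id": g, **dict(zip(taxonomy.ranks, labs))}
                for g, labs in taxonomy.labels.items()]
    pd.DataFrame(tax_rows).to_csv(save(out / "taxonomy.tsv"), sep="\t",
                                  index=False)
    gcfg = sim["genomes"]
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    tips = list(trait)[:gcfg["n"]]
    gseeds = sd.spawn_seeds(seeds["genomes"], len(tips))
    # tip trait values are GC percentages; clip into the generator's range
    truth_rows = []
    for tip, gseed in zip(tips, gseeds):
        target = float(np.clip(trait[tip] / 100.0, 0.2, 0.8))
        genome = sd.sim_genome(target, gcfg["n_cds"], gcfg["cds_length"],
                               gcfg["intergenic_length"], genome_id=tip,
                               seed=gseed)
        sd.write_genome_files(genome, save(gdir / f"{tip}.fasta"),
                              save(gdir / f"{tip}.gff3"))
        truth_rows.append({"genome_id": tip, "target_gc": target,
                           "seed": gseed})
    pd.DataFrame(truth_rows).to_csv(save(out / "genome_truth.tsv"),
                                    sep="\t", index=False)
    state.update(tree=tree, trait=trait, ko=komat, truth=truth,
                 taxonomy=taxonomy, genome_dir=gdir)
    return produced


def _stage_compose(cfg, out: Path, seeds, state) -> list[Path]:
    gdir = state.get("genome_dir", out / "genomes")
    fastas = sorted(Path(gdir).glob("*.fasta"))
    if not fastas:
        raise FileNotFoundError(f"no FASTA files under {gdir}; run the "
                                "'simulate' stage first or point to real data")
    genomes = [sc.read_genome(f, f.with_suffix(".gff3"), genome_id=f.stem)
               for f in fastas]
    profiles = sc.build_profiles(genomes)
    sc.write_composition_table(profiles, out / "composition.tsv")
    state["profiles"] = profiles
    return [out / "composition.tsv"]


def _stage_variance(cfg, out: Path, seeds, state) -> list[Path]:
    trait, taxonomy = _need(state, "trait", "taxonomy", stage="variance")
    profile = tp.variance_profile(trait, taxonomy)
    profile.table.to_csv(out / "variance_profile.tsv", sep="\t", index=False)
    return [out / "variance_profile.tsv"]


def _stage_signal(cfg, out: Path, seeds, state) -> list[Path]:
    tree, trait = _need(state, "tree", "trait", stage="signal")
    scfg = cfg["signal"]
    rows = []
    for stat in scfg["stats"]:
        if stat == "K":
            res = pcm.blomberg_k(trait, tree, n_perm=scfg["n_perm"],
                                 seed=seeds["signal"])
        elif stat == "lambda":
            res = pcm.fit_lambda(trait, tree)
        elif stat == "kappa":
            res = pcm.fit_kappa(trait, tree)
        elif stat == "delta":
            res = pcm.fit_delta(trait, tree)
        else:
            raise ConfigError(f"unknown signal statistic {stat!r}")
        rows.append({"statistic": res.statistic, "estimate": res.estimate,
                     "p": res.p_value, "logL": res.log_likelihood,
                     "n": res.n_tips, "seed": res.seed})
    pd.DataFrame(rows).to_csv(out / "signal.tsv", sep="\t", index=False)
    return [out / "signal.tsv"]


def _stage_pgls(cfg, out: Path, seeds, state) -> list[Path]:
    tree, trait, komat, truth = _need(state, "tree", "trait", "ko", "truth",
                                      stage="pgls")
    k = cfg["pgls"]["n_predictors"]
    # strongest simulated couplings as predictors (KO presence profiles)
    tt = truth.table.reindex(
        truth.table.beta.abs().sort_values(ascending=False).index)
    kos = list(tt.ko_id.head(k))
    X = komat.to_frame()[kos].astype(float)
    fit = pcm.pgls(trait, X, tree, structure=cfg["pgls"]["structure"])
    res = pd.DataFrame({"term": fit.terms, "beta": fit.coef, "se": fit.se,
                        "t": fit.t_values, "p": fit.p_values})
    path = out / "pgls.tsv"
    with open(path, "w") as fh:
        res.to_csv(fh, sep="\t", index=False)
        fh.write(f"# R2\t{fit.r_squared:.6f}\n")
        fh.write(f"# multiple_r\t{fit.multiple_r:.6f}\n")
        fh.write(f"# structure\t{fit.structure}\n")
    return [path]


def _stage_correlations(cfg, out: Path, seeds, state) -> list[Path]:
    trait, komat = _need(state, "trait", "ko", stage="correlations")
    gc = np.array([trait[g] for g in komat.genome_ids])
    corr = fm.correlate_features(komat.to_frame().astype(float), gc)
    corr.to_csv(out / "ko_correlations.tsv", sep="\t", index=False)
    curve = fm.min_distance_curve(gc / 100.0, komat)
    curve.table.to_csv(out / "min_distance_curve.tsv", sep="\t", index=False)
    return [out / "ko_correlations.tsv", out / "min_distance_curve.tsv"]


def _need(state: dict, *keys, stage: str):
    missing = [k for k in keys if k not in state]
    if missing:
        raise RuntimeError(
            f"stage {stage!r} is missing upstream results {missing}; run the "
            "'simulate' stage first")
    return tuple(state[k] for k in keys)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "compose": _stage_compose,
    "variance": _stage_variance,
    "signal": _stage_signal,
    "pgls": _stage_pgls,
    "correlations": _stage_correlations,
}
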