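"""End-to-end orchestration: simulate -> phenotype -> variant sets -> M_eff
-> association scans -> GRS -> CNA-region GWAS, driven by one YAML config,
with a machine-readable run manifest (config hash, per-stage output
checksums, timings, warnings)."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .association import run_scan
from .cna_gwas import (
    flag_known, gain_loss_test, lead_snps, plot_manhattan,
    restrict_to_regions, significant_variants,
)
from .grs import GrsSpec, compute_grs, mist_test, pathway_outcomes
from .multiple_testing import meff_total, significance_threshold
from .somatic import burden_summary, call_hypermutation, filter_genes
from .synthetic import SimulationConfig, simulate_cohort, write_cohort
from .variant_sets import build_cna_set, build_functional_set, build_gwas_set
from .association import make_design

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in fields(SimulationConfig)}

#: per-section allowed keys; unknown keys are rejected before any computation
ALLOWED_KEYS = {
    "outdir": None,
    "seed": None,
    "simulate": _SIM_KEYS - {"seed"},
    "phenotype": {"method", "fixed_threshold", "min_gene_freq"},
    "sets": {"gwas_p_cut", "functional_max_dist", "promoter_bp"},
    "scan": {"alpha"},
    "grs": {"enabled"},
    "cna_gwas": {"window_bp", "known_radius", "alpha"},
}

DEFAULT_CONFIG = {
    "phenotype": {"method": "fixed", "fixed_threshold": 23, "min_gene_freq": 0.05},
    "sets": {"gwas_p_cut": 1e-5, "functional_max_dist": 200_000, "promoter_bp": 1000},
    "scan": {"alpha": 0.05},
    "grs": {"enabled": True},
    "cna_gwas": {"window_bp": 1_000_000, "known_radius": 1_000_000, "alpha": 0.05},
}


def load_config(path: str | Path) -> dict:
    """Read and validate the pipeline config; unknown keys are an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(ALLOWED_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in ALLOWED_KEYS.items():
        if allowed is None or section not in raw:
            continue
        bad = set(raw[section] or {}) - allowed
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, vals in raw.items():
        if section in ("outdir", "seed"):
            cfg[section] = vals
        else:
            cfg.setdefault(section, {}).update(vals or {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def run_all(config_path: str | Path, outdir: str | Path | None = None,
            seed: int | None = None) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``<outdir>/manifest.json``). Any stage failure aborts with a
    stage-named error; outputs of completed stages are retained."""
    cfg = load_config(config_path)
    outdir = Path(outdir or cfg.get("outdir", "gsassoc_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 17))

    collector = _WarningCollector()
    logging.getLogger("gsassoc").addHandler(collector)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict = {"config_hash": config_hash, "seed": seed, "stages": {}}
    t_all = time.time()

    def _record(stage: str, t0: float, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in paths.items()
                        if Path(p).is_file() and str(p).endswith((".tsv", ".json"))},
        }

    try:
        # ---- stage: simulate -------------------------------------------
        t0 = time.time()
        sim_kwargs = dict(cfg.get("simulate", {}))
        sim_cfg = SimulationConfig(seed=seed, **sim_kwargs)
        cohort = simulate_cohort(sim_cfg)
        inputs_dir = outdir / "inputs"
        paths = write_cohort(cohort, inputs_dir)
        _record("simulate", t0, paths)

        # ---- stage: phenotype ------------------------------------------
        t0 = time.time()
        ph = cfg["phenotype"]
        call = call_hypermutation(
            cohort.somatic.counts["nonsyn_point"], method=ph["method"],
            fixed_threshold=ph["fixed_threshold"])
        genes_nonhyper = filter_genes(cohort.somatic, call.stratum("non_hyper"),
                                      ph["min_gene_freq"])
        genes_combined = filter_genes(cohort.somatic, call.stratum("combined"),
                                      ph["min_gene_freq"])
        pheno_dir = outdir / "phenotype"
        pheno_dir.mkdir(exist_ok=True)
        hyper_path = pheno_dir / "hypermutation.tsv"
        gio._write_tsv(call.status.rename("hypermutated").reset_index()
                       .rename(columns={"index": "sample"}), hyper_path)
        genes_path = pheno_dir / "analysis_genes.tsv"
        gio._write_tsv(pd.DataFrame(
            [(g, "non_hyper") for g in genes_nonhyper]
            + [(g, "combined") for g in genes_combined],
            columns=["gene", "stratum"]), genes_path)
        summary_path = pheno_dir / "burden_summary.tsv"
        gio._write_tsv(burden_summary(cohort.somatic, call), summary_path)
        _record("phenotype", t0, {"hypermutation": hyper_path,
                                  "genes": genes_path, "summary": summary_path})

        # ---- stage: variant sets ---------------------------------------
        t0 = time.time()
        st = cfg["sets"]
        cohort_ids = set(cohort.genotypes.variants["id"])
        cohort_stats = cohort.summary_stats[
            cohort.summary_stats["id"].isin(cohort_ids)]
        sets = {}
        if len(cohort_stats):
            sets["gwas_suggestive"] = build_gwas_set(
                cohort_stats, genes_combined, st["gwas_p_cut"])
        sets["functional"] = build_functional_set(
            cohort.genotypes.variants, cohort.annotations, genes_combined,
            max_dist=st["functional_max_dist"], promoter_bp=st["promoter_bp"])
        sets["cna_region"] = build_cna_set(
            cohort.genotypes.variants, cohort.annotations.cna_regions,
            {g: c for g, c in cohort.annotations.gene_chrom().items()
             if g in genes_combined})
        sets_dir = outdir / "sets"
        sets_dir.mkdir(exist_ok=True)
        set_paths = {}
        for name, vs in sets.items():
            p = sets_dir / f"{name}.tsv"
            gio._write_tsv(vs.pairs, p)
            set_paths[name] = p
        _record("build_sets", t0, set_paths)

        # ---- stage: M_eff + scans --------------------------------------
        t0 = time.time()
        alpha = cfg["scan"]["alpha"]
        scan_dir = outdir / "scan"
        scan_dir.mkdir(exist_ok=True)
        scan_paths = {}
        meff_rows = []
        for name, vs in sets.items():
            if vs.n_pairs == 0:
                logger.warning("scan: variant set %s is empty, skipped", name)
                continue
            meff = meff_total(cohort.genotypes, vs.variant_ids())
            meff_rows.append({"set": name, "n_variants": meff.n_variants,
                              "meff": meff.total})
            for stratum, genes in (("non_hyper", genes_nonhyper),
                                   ("combined", genes_combined)):
                pairs = vs.pairs[vs.pairs["gene"].isin(genes)]
                if len(pairs) == 0:
                    continue
                sub = type(vs)(name=vs.name, pairs=pairs)
                thr = significance_threshold(alpha, len(genes), max(1.0, meff.total))
                table, signif = run_scan(
                    cohort.genotypes, cohort.somatic, cohort.covariates,
                    sub, stratum, thr, hyper_status=cohort.truth.hyper_status)
                table.insert(0, "set", name)
                p = scan_dir / f"{name}_{stratum}.tsv"
                gio.write_assoc(table, p)
                scan_paths[f"{name}_{stratum}"] = p
        meff_path = scan_dir / "meff.tsv"
        gio._write_tsv(pd.DataFrame(meff_rows), meff_path)
        scan_paths["meff"] = meff_path
        _record("scan", t0, scan_paths)

        # ---- stage: GRS ------------------------------------------------
        if cfg["grs"]["enabled"]:
            t0 = time.time()
            spec = GrsSpec.from_tables(cohort.grs_weights, cohort.pathways)
            spec.validate_against(cohort.somatic)
            grs = compute_grs(cohort.genotypes, spec)
            G = np.column_stack([cohort.genotypes.dosage(v)
                                 for v in spec.variant_ids])
            design = make_design(cohort.covariates, cohort.genotypes.samples)
            indicators, burden = pathway_outcomes(cohort.somatic, spec.pathways)
            rows = [mist_test(burden.to_numpy(), "count", grs.to_numpy(), G,
                              design, outcome_name="burden").__dict__]
            for nm, vec in indicators.items():
                if 0 < vec.sum() < len(vec):
                    rows.append(mist_test(vec.to_numpy(), "binary",
                                          grs.to_numpy(), G, design,
                                          outcome_name=nm).__dict__)
            grs_path = outdir / "grs_mist.tsv"
            gio._write_tsv(pd.DataFrame(rows), grs_path)
            _record("grs", t0, {"grs_mist": grs_path})

        # ---- stage: CNA-region GWAS ------------------------------------
        t0 = time.time()
        cg = cfg["cna_gwas"]
        regions = cohort.annotations.cna_regions
        in_region = restrict_to_regions(cohort.summary_stats, regions)
        # LD-based M_eff where genotypes exist; summary-only variants
        # contribute one independent test each
        with_geno = [v for v in in_region["id"] if v in cohort_ids]
        meff_ld = meff_total(cohort.genotypes, with_geno).total if with_geno else 0.0
        meff_gwas = meff_ld + (len(in_region) - len(with_geno))
        thr = significance_threshold(cg["alpha"], 1, max(1.0, meff_gwas))
        signif = significant_variants(in_region, thr)
        leads = lead_snps(signif, window_bp=cg["window_bp"])
        leads = flag_known(leads, cohort.truth.known_loci, radius=cg["known_radius"])
        cna_dir = outdir / "cna_gwas"
        cna_dir.mkdir(exist_ok=True)
        leads_path = cna_dir / "locus_report.tsv"
        gio._write_tsv(leads, leads_path)
        fisher_path = cna_dir / "gain_loss.json"
        try:
            fisher_p, table = gain_loss_test(regions, leads)
            fisher_path.write_text(json.dumps(
                {"fisher_p": fisher_p, "table": table.to_dict()}, indent=1))
        except ValueError as exc:
            logger.warning("gain/loss test skipped: %s", exc)
        plot_manhattan(in_region, thr.threshold, cna_dir / "manhattan.png")
        stats_json = cna_dir / "summary.json"
        stats_json.write_text(json.dumps({
            "n_in_region": int(len(in_region)), "meff": float(meff_gwas),
            "threshold": thr.threshold, "n_significant": int(len(signif)),
            "n_loci": int(len(leads)),
            "n_known": int(leads["known"].sum()) if len(leads) else 0,
        }, indent=1))
        _record("cna_gwas", t0, {"locus_report": leads_path,
                                 "gain_loss": fisher_path,
                                 "summary": stats_json})
    finally:
        logging.getLogger("gsassoc").removeHandler(collector)

    manifest["warnings"] = collector.messages
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def render_report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run (burden table + loci)."""
    outdir = Path(outdir)
    parts = []
    burden = outdir / "phenotype" / "burden_summary.tsv"
    if burden.exists():
        parts.append("Mutation burden by stratum:\n"
                     + gio._read_tsv(burden).to_string(index=False))
    summary = outdir / "cna_gwas" / "summary.json"
    if summary.exists():
        parts.append("CNA-region GWAS: "
                     + json.dumps(json.loads(summary.read_text())))
    loci = outdir / "cna_gwas" / "locus_report.tsv"
    if loci.exists():
        df = gio._read_tsv(loci)
        cols = [c for c in ("id", "chrom", "pos", "eaf", "OR", "p",
                            "region_label", "region_direction", "known")
                if c in df.columns]
        parts.append("Lead SNPs in CNA regions:\n"
                     + df[cols].to_string(index=False))
    gl = outdir / "cna_gwas" / "gain_loss.json"
    if gl.exists():
        parts.append("Gain/loss enrichment: " + gl.read_text())
    return "\n\n".join(parts) if parts else "no outputs found"
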