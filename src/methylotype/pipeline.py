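"""End-to-end pipeline: simulate/load -> preprocess -> differential
methylation -> bootstrap clustering -> enrichment -> marker panel -> calls.

The stage order mirrors the analysis it packages: differentially
methylated CpGs between tumors and normals define the clustering feature
set; bootstrap-supported clusters define the methylator (CII) and
low-methylator (CI) groups; cluster-specific signatures are characterized
by genomic context and PRC2-target enrichment; perfectly separating CpGs
form the marker panel whose mean + 2 SD cutoffs yield per-sample
Epi-subtype calls.

Every run writes its stage outputs plus a provenance manifest (config,
seed, package versions, SHA-256 checksums) into the run directory, and all
randomness derives from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (read_annotation, read_beta_matrix, read_sample_sheet,
                 write_annotation, write_beta_matrix, write_sample_sheet)
from .simulate import SimConfig, simulate_dataset
from .preprocess import beta_to_m, quantile_normalize
from .diffmeth import (build_dm_table, compute_delta_beta, fit_moderated_t,
                       select_dm_cpgs, signature_overlap)
from .clustering import (DEFAULT_SCALES, multiscale_bootstrap_au,
                         select_significant_clusters)
from .enrichment import annotate_categories, category_chi_squared, prc2_enrichment
from .panel import (classify_samples, clinical_association, fit_cutoffs,
                    select_perfect_markers)

log = logging.getLogger("methylotype")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Single-file configuration of a full run (YAML round-trippable)."""

    # inputs: either a simulation block or paths to the three tables
    sim: SimConfig | None = None
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    # thresholds
    q_threshold: float = 0.05
    delta_threshold: float = 0.2
    au_threshold: float = 95.0
    min_cluster_size: int = 5
    panel_k: int = 25
    classifier_markers: int = 3
    rule: str = "majority"
    # bootstrap
    scales: tuple = DEFAULT_SCALES
    n_boot: int = 1000
    seed: int = 0
    # flags
    drop_snps: bool = True  # applied at signature selection
    quantile: bool = False  # matrix-level quantile normalization of betas
    cluster_on: str = "beta"  # or "m"

    def validate(self) -> None:
        if self.sim is None and self.beta_path is None:
            raise PipelineError("config needs either a sim block or beta_path")
        if self.sim is None and (self.sample_sheet_path is None
                                 or self.annotation_path is None):
            raise PipelineError(
                "file inputs need sample_sheet_path and annotation_path")
        if not 0 < self.q_threshold < 1:
            raise PipelineError("q_threshold outside (0, 1)")
        if not 0 <= self.delta_threshold < 1:
            raise PipelineError("delta_threshold outside [0, 1)")
        if not 0 <= self.au_threshold <= 100:
            raise PipelineError("au_threshold outside [0, 100]")
        if self.rule not in ("majority", "all", "any"):
            raise PipelineError("rule must be majority/all/any")
        if self.cluster_on not in ("beta", "m"):
            raise PipelineError("cluster_on must be 'beta' or 'm'")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scales"] = [float(r) for r in self.scales]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            d["sim"] = SimConfig(**d["sim"])
        if "scales" in d and d["scales"] is not None:
            d["scales"] = tuple(d["scales"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the single config seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, writing outputs and a manifest to ``outdir``.

    Returns the run summary (also written as ``summary.json``). A stage
    failure raises :class:`PipelineError` after writing a failure marker;
    outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    summary: dict = {"seed": config.seed, "version": __version__}
    try:
        return _run(config, outdir, summary)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    finally:
        log.info("pipeline finished in %.1f s", time.time() - t0)
        log.removeHandler(fh)
        fh.close()


def _stage(name):
    log.info("stage: %s", name)


def _run(config: PipelineConfig, outdir: Path, summary: dict) -> dict:
    bootstrap_seed, = _substream_seeds(config.seed, 1)

    # ----- inputs ---------------------------------------------------------
    _stage("inputs")
    truth = None
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.sim.seed
                                      if config.sim.seed else config.seed)
        beta, sheet, annotation, truth = simulate_dataset(sim_cfg)
        write_beta_matrix(beta, outdir / "beta.tsv")
        write_sample_sheet(sheet, outdir / "samples.csv")
        write_annotation(annotation, outdir / "annotation.csv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    else:
        beta = read_beta_matrix(config.beta_path)
        sheet = read_sample_sheet(config.sample_sheet_path)
        annotation = read_annotation(config.annotation_path)
    sheet = sheet.set_index("sample_id", drop=False).loc[list(beta.columns)]
    summary["n_probes"], summary["n_samples"] = beta.shape

    # ----- preprocess -----------------------------------------------------
    _stage("preprocess")
    if config.quantile:
        beta = quantile_normalize(beta)
    m = beta_to_m(beta)

    tissue = sheet["tissue"].to_numpy()
    tumors = list(sheet.loc[sheet["tissue"] == "tumor", "sample_id"])
    if len(tumors) < 3 or (tissue == "normal").sum() < 2:
        raise PipelineError("need >= 3 tumors and >= 2 normals")

    # ----- tumor vs normal differential methylation -----------------------
    _stage("differential methylation: tumor vs normal")
    fit = fit_moderated_t(m, tissue, reference="normal", test="tumor")
    delta = compute_delta_beta(beta, tissue, reference="normal", test="tumor")
    dm = build_dm_table(fit, delta)
    dm.to_csv(outdir / "dm_tumor_vs_normal.tsv", sep="\t")
    sig_tn = select_dm_cpgs(dm, config.q_threshold, config.delta_threshold,
                            annotation, exclude_snps=config.drop_snps,
                            label="tumor-vs-normal")
    sig_tn.to_frame().to_csv(outdir / "signature_tumor_vs_normal.tsv",
                             sep="\t", index=False)
    summary["n_dm_tumor_vs_normal"] = len(sig_tn)
    summary["prior_df_tumor_vs_normal"] = fit.d0
    if len(sig_tn) < 2:
        raise PipelineError("tumor-vs-normal signature too small to cluster on")

    # ----- bootstrap clustering of tumors ---------------------------------
    _stage("bootstrap clustering")
    features = (beta if config.cluster_on == "beta" else m)
    feat = features.loc[sig_tn.probes, tumors]
    dendro = multiscale_bootstrap_au(feat, scales=config.scales,
                                     B=config.n_boot, seed=bootstrap_seed)
    partition = select_significant_clusters(
        dendro, au_threshold=config.au_threshold,
        min_size=config.min_cluster_size, feature_matrix=feat)
    (outdir / "clusters.json").write_text(json.dumps(
        {"dendrogram": dendro.to_dict(),
         "partition": partition.to_dict()}, indent=1))
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    summary["n_significant_clusters"] = len(partition.clusters)
    summary["cluster_sizes"] = {c["label"]: c["size"]
                                for c in partition.clusters}
    summary["cluster_au"] = {c["label"]: c["au"] for c in partition.clusters}

    has_two = {"CI", "CII"} <= set(partition.labels)
    if not has_two:
        log.warning("no CI/CII partition found; downstream stages skipped")
        return _finish(config, outdir, summary)
    ci = partition.members("CI")
    cii = partition.members("CII")
    if truth is not None:
        epi = truth["sample_epigenotype"]
        summary["cii_methylator_fraction"] = float(
            np.mean([epi[s] == "methylator" for s in cii]))

    # ----- cluster-specific signatures ------------------------------------
    _stage("cluster-specific signatures")
    normals = list(sheet.loc[sheet["tissue"] == "normal", "sample_id"])
    sigs = {}
    comparisons = {"CI_vs_normal": (normals, ci),
                   "CII_vs_normal": (normals, cii),
                   "CII_vs_CI": (ci, cii)}
    for name, (ref, test) in comparisons.items():
        cols = ref + test
        labels = ["ref"] * len(ref) + ["test"] * len(test)
        f = fit_moderated_t(m[cols], labels, reference="ref", test="test")
        d = compute_delta_beta(beta[cols], labels, reference="ref", test="test")
        tbl = build_dm_table(f, d)
        sigs[name] = select_dm_cpgs(
            tbl, config.q_threshold, config.delta_threshold, annotation,
            exclude_snps=config.drop_snps, label=name)
        sigs[name].to_frame().to_csv(outdir / f"signature_{name}.tsv",
                                     sep="\t", index=False)
        summary[f"n_dm_{name}"] = len(sigs[name])
        summary[f"n_hyper_{name}"] = len(sigs[name].hyper)
        summary[f"n_hypo_{name}"] = len(sigs[name].hypo)
    if len(sigs["CI_vs_normal"]) and len(sigs["CII_vs_normal"]):
        summary["overlap_CI_in_CII_percent"] = signature_overlap(
            sigs["CI_vs_normal"], sigs["CII_vs_normal"])

    # ----- enrichment -----------------------------------------------------
    _stage("enrichment")
    tested = list(dm.index[~dm["p"].isna()])
    enrich: dict = {}
    if len(sigs["CI_vs_normal"]) and len(sigs["CII_vs_normal"]):
        for scheme in ("region", "cpg_class"):
            ca = annotate_categories(sigs["CI_vs_normal"].probes, annotation,
                                     scheme, background_probes=tested)
            cb = annotate_categories(sigs["CII_vs_normal"].probes, annotation,
                                     scheme, background_probes=tested)
            merged = (ca.counts + cb.counts) > 0
            stat, df, p = category_chi_squared(ca.counts[merged],
                                               cb.counts[merged])
            enrich[f"{scheme}_chi2"] = {"statistic": stat, "df": df, "p": p,
                                        "CI": ca.counts.to_dict(),
                                        "CII": cb.counts.to_dict()}
    for name in ("CI_vs_normal", "CII_vs_normal"):
        if len(sigs[name].hyper):
            k, exp, p = prc2_enrichment(sigs[name].hyper, annotation, tested)
            enrich[f"prc2_{name}"] = {"overlap": k, "expected": exp, "p": p}
            summary[f"prc2_p_{name}"] = p
    (outdir / "enrich.json").write_text(json.dumps(enrich, indent=1))

    # ----- marker panel and Epi-calls -------------------------------------
    _stage("marker panel")
    panel = select_perfect_markers(sigs["CII_vs_CI"].probes, beta, ci, cii,
                                   k=config.panel_k)
    summary["n_perfect_markers"] = len(panel)
    luma = list(sheet.loc[(sheet["tissue"] == "tumor")
                          & (sheet["subtype"] == "LumA"), "sample_id"])
    if len(panel) and len(luma) >= 2:
        from .panel import MarkerPanel
        sub = MarkerPanel(markers=panel.markers[:config.classifier_markers])
        sub = fit_cutoffs(sub, beta, luma)
        (outdir / "panel.json").write_text(json.dumps(sub.to_dict(), indent=1))
        calls = classify_samples(sub, beta[tumors], rule=config.rule)
        pd.DataFrame([{"sample_id": c.sample_id, "call": c.call}
                      for c in calls]).to_csv(outdir / "calls.csv", index=False)
        call_map = {c.sample_id: c.call for c in calls}
        subtype = sheet["subtype"]
        lumb = [s for s in tumors if subtype[s] == "LumB"]
        if lumb:
            summary["pct_lumB_called_epi_lumB_HER2"] = 100.0 * float(
                np.mean([call_map[s] == "Epi_lumB_HER2" for s in lumb]))
        if luma:
            summary["pct_lumA_called_epi_lumA"] = 100.0 * float(
                np.mean([call_map[s] == "Epi_lumA" for s in luma]))
        if truth is not None:
            epi = truth["sample_epigenotype"]
            y_true = np.array([epi[s] == "methylator" for s in tumors])
            y_pred = np.array([call_map[s] == "Epi_lumB_HER2" for s in tumors])
            sens = float(y_pred[y_true].mean()) if y_true.any() else np.nan
            spec = float((~y_pred[~y_true]).mean()) if (~y_true).any() else np.nan
            summary["epi_call_balanced_accuracy"] = (sens + spec) / 2.0
        groups = {"Epi_lumA": [s for s in tumors
                               if call_map[s] == "Epi_lumA"],
                  "Epi_lumB_HER2": [s for s in tumors
                                    if call_map[s] == "Epi_lumB_HER2"]}
        if all(groups.values()):
            assoc = clinical_association(groups["Epi_lumA"],
                                         groups["Epi_lumB_HER2"], sheet)
            (outdir / "clinical.json").write_text(json.dumps(assoc, indent=1))
            summary["clinical_p"] = {k: v["p"] for k, v in assoc.items()}

    return _finish(config, outdir, summary)


def _finish(config: PipelineConfig, outdir: Path, summary: dict) -> dict:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "config": yaml.safe_load((outdir / "config.yaml").read_text()),
        "seed": config.seed,
        "versions": {"methylotype": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "checksums": {p.name: _sha256(p)
                      for p in sorted(outdir.iterdir())
                      if p.is_file() and p.name != "manifest.json"
                      and p.name != "run.log"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
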