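"""Seeded generator of 27K-style methylation datasets.

The generator emulates the statistical structure the downstream analysis
assumes: bimodal per-probe baseline methylation, beta-distributed
measurement noise, a normal-tissue group, and two latent tumor
epigenotypes — a low-methylator group and a *methylator* group that gains
additional methylation at a CpG-island/promoter/PRC2-enriched probe set of
cancer-hypermethylated loci (so the low-methylator group's aberrant CpGs
are a subset of the methylator group's, as observed in luminal tumors). IHC metadata
are drawn so that St Gallen 2013 surrogate subtyping reproduces the
intended subtype of every tumor, and the latent epigenotype follows the
clinical picture of the methylator phenotype: every luminal B-HER2 tumor
is a methylator, a configurable share of luminal B tumors are, and no
luminal A tumor is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (assign_st_gallen_subtype, validate_annotation,
                 validate_beta_matrix)


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults are a desk-scale cohort mirroring the discovery study's
    proportions: 8 adjacent normals and 28 luminal tumors (8 luminal A,
    16 luminal B of which half are latent methylators, 4 luminal B-HER2)
    over 5,000 probes.
    """

    n_probes: int = 5000
    n_normals: int = 8
    n_lumA: int = 8
    n_lumB: int = 16
    n_lumB_HER2: int = 4
    frac_lumB_methylator: float = 0.5
    n_tumor_dm_probes: int = 300
    n_methylator_probes: int = 300
    delta_beta_effect: float = 0.3
    beta_noise_concentration: float = 50.0
    frac_island: float = 0.40
    frac_shore: float = 0.25
    prc2_background_rate: float = 0.12
    prc2_enrichment_factor: float = 4.0
    frac_snp_probes: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_lumB_methylator": self.frac_lumB_methylator,
            "frac_island": self.frac_island,
            "frac_shore": self.frac_shore,
            "prc2_background_rate": self.prc2_background_rate,
            "frac_snp_probes": self.frac_snp_probes,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_island + self.frac_shore > 1.0:
            raise ValueError("frac_island + frac_shore exceeds 1")
        counts = (self.n_probes, self.n_normals, self.n_lumA, self.n_lumB,
                  self.n_lumB_HER2)
        if any(c <= 0 for c in counts[:2]) or any(c < 0 for c in counts[2:]):
            raise ValueError("probe/sample counts must be positive")
        if self.n_tumor_dm_probes + self.n_methylator_probes > self.n_probes:
            raise ValueError(
                "n_tumor_dm_probes + n_methylator_probes exceeds n_probes")
        if self.prc2_enrichment_factor <= 0:
            raise ValueError("prc2_enrichment_factor must be > 0")
        if self.beta_noise_concentration <= 0:
            raise ValueError("beta_noise_concentration must be > 0")


# baseline bimodal mixture: most 27K probes sit in unmethylated promoters
_LOW_MEAN, _LOW_SD = 0.10, 0.05
_HIGH_MEAN, _HIGH_SD = 0.85, 0.05
_FRAC_LOW = 0.65
_MEAN_CLIP = (0.02, 0.98)


def _beta_draw(rng: np.random.Generator, mean: np.ndarray,
               concentration: float) -> np.ndarray:
    m = np.clip(mean, *_MEAN_CLIP)
    return rng.beta(m * concentration, (1.0 - m) * concentration)


def _ihc_for_subtype(rng: np.random.Generator, subtype: str) -> dict:
    """Draw IHC markers consistent with the requested St Gallen subtype.

    Ki-67 distributions mirror the discovery cohort (luminal A 10+-4 %,
    luminal B 43+-23 %, luminal B-HER2 50+-22 %), truncated to the region
    the subtype's rule admits.
    """
    if subtype == "LumA":
        ki67 = float(np.clip(rng.normal(10, 4), 0.5, 19.5))
        pgr = float(np.clip(rng.normal(60, 20), 20, 100))
        her2 = False
    elif subtype == "LumB":
        # ki67 >= 20 guarantees the LumB rule regardless of PgR
        ki67 = float(np.clip(rng.normal(43, 23), 20, 95))
        pgr = float(np.clip(rng.normal(35, 25), 0, 100))
        her2 = False
    elif subtype == "LumB_HER2":
        ki67 = float(np.clip(rng.normal(50, 22), 1, 95))
        pgr = float(np.clip(rng.normal(40, 25), 0, 100))
        her2 = True
    else:  # pragma: no cover
        raise ValueError(subtype)
    assert assign_st_gallen_subtype(True, pgr, ki67, her2) == subtype
    return {"er": True, "pgr_percent": round(pgr, 1),
            "ki67_percent": round(ki67, 1), "her2": her2}


def simulate_dataset(config: SimConfig):
    """Generate one dataset.

    Returns
    -------
    beta : DataFrame
        probes x samples beta matrix.
    sheet : DataFrame
        sample sheet (tissue, IHC, subtype, clinical covariates).
    annotation : DataFrame
        per-probe genomic-context annotation.
    truth : dict
        latent ground truth — ``sample_epigenotype`` (normal / low /
        methylator per sample), ``probe_class`` (null / tumor_dm /
        methylator per probe), and the config used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_probes = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])

    # --- annotation -------------------------------------------------------
    region = rng.choice(["Promoter", "TSS1500", "Body", "UTR3"],
                        size=n_probes, p=[0.50, 0.25, 0.20, 0.05])
    frac_poor = 1.0 - config.frac_island - config.frac_shore
    cpg_class = rng.choice(["island", "shore", "poor"], size=n_probes,
                           p=[config.frac_island, config.frac_shore, frac_poor])
    known_snp = rng.random(n_probes) < config.frac_snp_probes
    gene_symbol = np.array([f"GENE{i // 2:05d}" for i in range(n_probes)])

    # --- baseline means ---------------------------------------------------
    low = rng.random(n_probes) < _FRAC_LOW
    baseline = np.where(low,
                        rng.normal(_LOW_MEAN, _LOW_SD, n_probes),
                        rng.normal(_HIGH_MEAN, _HIGH_SD, n_probes))
    baseline = np.clip(baseline, *_MEAN_CLIP)

    # --- signal probe assignment -----------------------------------------
    # methylator probes come preferentially from low-baseline island/promoter
    # probes (room for a +delta_beta gain; the biology of the phenotype)
    probe_class = np.full(n_probes, "null", dtype=object)
    low_idx = np.flatnonzero(baseline < 0.5)
    if len(low_idx) < config.n_methylator_probes + config.n_tumor_dm_probes:
        raise ValueError(
            "infeasible config: low-methylation probe pool smaller than the "
            "requested signal probe sets")
    pref = 1.0 + 3.0 * ((cpg_class[low_idx] == "island")
                        & (region[low_idx] == "Promoter"))
    meth_idx = rng.choice(low_idx, size=config.n_methylator_probes,
                          replace=False, p=pref / pref.sum())
    probe_class[meth_idx] = "methylator"
    remaining = np.setdiff1d(low_idx, meth_idx)
    dm_idx = rng.choice(remaining, size=config.n_tumor_dm_probes, replace=False)
    probe_class[dm_idx] = "tumor_dm"

    # PRC2 flags: background rate everywhere, odds multiplied on methylator
    # probes by the configured enrichment factor
    p0 = config.prc2_background_rate
    odds1 = config.prc2_enrichment_factor * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    prc2_p = np.where(probe_class == "methylator", p1, p0)
    prc2_target = rng.random(n_probes) < prc2_p

    annotation = validate_annotation(pd.DataFrame({
        "gene_symbol": gene_symbol,
        "region_category": region,
        "cpg_class": cpg_class,
        "prc2_target": prc2_target,
        "known_snp": known_snp,
    }, index=pd.Index(probe_ids, name="probe_id")))

    # --- samples ----------------------------------------------------------
    records = []
    epigenotype = []
    n_meth_lumB = int(round(config.frac_lumB_methylator * config.n_lumB))
    lumB_meth_flags = np.zeros(config.n_lumB, dtype=bool)
    lumB_meth_flags[rng.choice(config.n_lumB, n_meth_lumB, replace=False)] = True

    def clinical(rng, methylator: bool) -> dict:
        # methylator tumors skew larger, higher grade, more relapse
        size = float(np.clip(rng.normal(2.7 if methylator else 2.2, 0.4), 2.0, 3.0))
        grade = int(rng.choice([2, 3], p=[0.3, 0.7] if methylator else [0.7, 0.3]))
        node = bool(rng.random() < (0.6 if methylator else 0.45))
        relapse = bool(rng.random() < (0.15 if methylator else 0.02))
        return {"size_cm": round(size, 1), "grade": grade,
                "node": node, "relapse": relapse}

    for i in range(config.n_normals):
        records.append({"sample_id": f"N{i + 1:02d}", "tissue": "normal",
                        "er": False, "pgr_percent": 0.0, "ki67_percent": 0.0,
                        "her2": False, "subtype": "NA", "size_cm": np.nan,
                        "grade": pd.NA, "node": pd.NA, "relapse": pd.NA})
        epigenotype.append("normal")
    tumor_plan = ([("LumA", False)] * config.n_lumA
                  + [("LumB", bool(f)) for f in lumB_meth_flags]
                  + [("LumB_HER2", True)] * config.n_lumB_HER2)
    for i, (subtype, is_meth) in enumerate(tumor_plan):
        rec = {"sample_id": f"T{i + 1:02d}", "tissue": "tumor",
               "subtype": subtype}
        rec.update(_ihc_for_subtype(rng, subtype))
        rec.update(clinical(rng, is_meth))
        records.append(rec)
        epigenotype.append("methylator" if is_meth else "low")
    sheet = pd.DataFrame(records)[
        ["sample_id", "tissue", "er", "pgr_percent", "ki67_percent", "her2",
         "subtype", "size_cm", "grade", "node", "relapse"]]

    # --- beta values ------------------------------------------------------
    is_tumor = (sheet["tissue"] == "tumor").to_numpy()
    is_meth = np.array([e == "methylator" for e in epigenotype])
    n_samples = len(sheet)
    means = np.tile(baseline[:, None], (1, n_samples))
    means[probe_class == "tumor_dm"] += np.where(
        is_tumor, config.delta_beta_effect, 0.0)
    # methylator probes are cancer-hypermethylated loci that gain an EXTRA
    # +delta in methylator-epigenotype samples, so the low-methylator
    # cluster's aberrant CpGs are nested within the methylator cluster's
    means[probe_class == "methylator"] += (
        np.where(is_tumor, config.delta_beta_effect, 0.0)
        + np.where(is_meth, config.delta_beta_effect, 0.0))
    values = _beta_draw(rng, means, config.beta_noise_concentration)
    beta = validate_beta_matrix(pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"),
        columns=sheet["sample_id"].tolist()))

    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "sample_epigenotype": dict(zip(sheet["sample_id"], epigenotype)),
        "probe_class": dict(zip(probe_ids.tolist(), probe_class.tolist())),
    }
    return beta, sheet, annotation, truth
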