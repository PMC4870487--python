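"""Genomic-context characterization of methylation signatures.

Signatures are cross-tabulated against the probe annotation by gene-region
category (TSS1500 / Promoter / Body / 3'UTR) or CpG class (island / shore /
poor), two signatures' distributions are compared by Pearson's chi-squared
test, and over-representation of Polycomb (PRC2) target genes among
promoter methylation events is scored with a one-sided hypergeometric
tail against the tested background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

_SCHEMES = {"region": "region_category", "cpg_class": "cpg_class"}
_CATEGORIES = {"region": ("TSS1500", "Promoter", "Body", "UTR3"),
               "cpg_class": ("island", "shore", "poor")}


@dataclass
class CategoryCounts:
    """Per-category probe counts and fractions for a signature vs background."""

    scheme: str
    counts: pd.Series
    fractions: pd.Series
    background_counts: pd.Series
    background_fractions: pd.Series


def _tabulate(probe_ids, annotation, column, categories) -> pd.Series:
    probe_ids = list(probe_ids)
    missing = [p for p in probe_ids if p not in annotation.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} probe(s) lack annotation: {missing[:10]}")
    counts = (annotation.loc[probe_ids, column]
              .value_counts().reindex(categories, fill_value=0))
    counts.name = "count"
    return counts


def annotate_categories(signature_probes, annotation: pd.DataFrame,
                        scheme: str = "region",
                        background_probes=None) -> CategoryCounts:
    """Cross-tabulate a signature's probes by genomic context.

    ``background_probes`` defaults to every annotated probe; passing the
    tested probe set keeps signature and background on the same footing.
    Empty signatures are an error (fractions undefined).
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(_SCHEMES)}")
    probes = list(signature_probes)
    if not probes:
        raise ValidationError("empty signature: fractions undefined")
    col, cats = _SCHEMES[scheme], _CATEGORIES[scheme]
    counts = _tabulate(probes, annotation, col, cats)
    bg = (list(background_probes) if background_probes is not None
          else list(annotation.index))
    bg_counts = _tabulate(bg, annotation, col, cats)
    return CategoryCounts(
        scheme=scheme, counts=counts,
        fractions=counts / counts.sum(),
        background_counts=bg_counts,
        background_fractions=bg_counts / bg_counts.sum())


def category_chi_squared(counts_a, counts_b):
    """Pearson chi-squared on a 2 x k contingency table of category counts.

    No continuity correction (k is usually > 2 here); ``df = k - 1``.
    Raises if any expected cell is zero (merge sparse categories first).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("counts must be two equal-length vectors")
    table = np.vstack([a, b])
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValidationError(
            "zero expected cell; merge categories before testing")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def prc2_enrichment(signature_probes, annotation: pd.DataFrame,
                    background_probes, promoter_only: bool = True,
                    include_tss1500: bool = False):
    """One-sided hypergeometric enrichment of PRC2 targets in a signature.

    The universe is the tested background (by default restricted to
    promoter-region probes, as promoter methylation events are what PRC2
    occupancy in embryonic stem cells predisposes to hypermethylation).

    Returns ``(overlap, expected, p)`` where ``p = P[X >= overlap]`` for
    ``X`` hypergeometric with the background's PRC2-target count.
    """
    regions = {"Promoter"} | ({"TSS1500"} if include_tss1500 else set())

    def restrict(probes):
        probes = list(probes)
        miss = [p for p in probes if p not in annotation.index]
        if miss:
            raise ValidationError(f"unannotated probe(s): {miss[:10]}")
        if not promoter_only:
            return probes
        sub = annotation.loc[probes]
        return list(sub.index[sub["region_category"].isin(regions)])

    bg = restrict(background_probes)
    sig = restrict(signature_probes)
    outside = set(sig) - set(bg)
    if outside or not bg:
        raise ValidationError(
            "signature must be drawn from the background universe; "
            f"{len(outside)} probe(s) outside it" if bg
            else "empty background after promoter restriction")
    N, n = len(bg), len(sig)
    K = int(annotation.loc[bg, "prc2_target"].sum())
    k = int(annotation.loc[sig, "prc2_target"].sum()) if sig else 0
    expected = n * K / N
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    return k, float(expected), p
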