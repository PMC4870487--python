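"""Perfect-marker selection, the mean + 2 SD cutoff model and Epi-calls.

A *perfect marker* is a CpG whose beta values separate the two methylation
clusters completely (ROC AUC exactly 1, verified as disjoint value ranges
rather than a floating-point comparison). Each marker's decision cutoff is
the mean plus twice the sample standard deviation of the luminal-A
(reference) samples; a sample exceeding the cutoffs of enough markers is
called Epi-lumB-HER2 (the methylator epigenotype), otherwise Epi-lumA.

Clinical associations between two sample groups use the Mann-Whitney U
test for continuous covariates (exact null distribution for small
combined n, normal approximation with tie correction otherwise) and
chi-squared contingency tests for categorical ones, substituting Fisher's
exact test whenever an expected cell drops below 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

EXACT_MW_MAX_N = 12  # combined sample size up to which the exact null is used


def compute_auc(values, binary_labels) -> float:
    """Area under the ROC curve via the rank-sum statistic.

    ``AUC = U / (n1 * n2)``: the probability that a positive-class value
    exceeds a negative-class value, ties counting one half.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MarkerRecord:
    """One panel marker with its separation evidence and fitted cutoff."""

    probe_id: str
    auc: float
    orientation: str  # 'hyper' = higher beta in the methylator cluster
    margin: float  # min(high group) - max(low group), beta units
    mu_a: float | None = None
    sigma_a: float | None = None
    cutoff: float | None = None


@dataclass
class MarkerPanel:
    markers: list[MarkerRecord] = field(default_factory=list)

    @property
    def probe_ids(self) -> list[str]:
        return [m.probe_id for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.markers])

    def to_dict(self) -> dict:
        return {"markers": [asdict(m) for m in self.markers]}

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(markers=[MarkerRecord(**m) for m in d["markers"]])


def select_perfect_markers(signature_probes, beta_matrix: pd.DataFrame,
                           ci_samples, cii_samples, k: int = 25) -> MarkerPanel:
    """Keep the signature probes that separate CI from CII perfectly.

    Perfection is exact set separation of the observed beta values
    (equivalently AUC = 1). When more than ``k`` probes qualify they are
    ranked by separation margin (gap between the groups' value ranges)
    descending, ties broken by probe_id; fewer than ``k`` may be returned.
    """
    ci = list(ci_samples)
    cii = list(cii_samples)
    if not ci or not cii:
        raise ValidationError("both clusters must be non-empty")
    records = []
    labels = np.array([False] * len(ci) + [True] * len(cii))
    for probe in signature_probes:
        row = beta_matrix.loc[probe]
        a = row[ci].to_numpy(dtype=float)
        b = row[cii].to_numpy(dtype=float)
        if a.max() < b.min():  # hyper in CII
            margin = float(b.min() - a.max())
            orientation = "hyper"
        elif b.max() < a.min():  # hypo in CII
            margin = float(a.min() - b.max())
            orientation = "hypo"
        else:
            continue
        auc = compute_auc(np.concatenate([a, b]), labels)
        if orientation == "hypo":
            auc = 1.0 - auc
        records.append(MarkerRecord(probe_id=str(probe), auc=auc,
                                    orientation=orientation, margin=margin))
    records.sort(key=lambda m: (-m.margin, m.probe_id))
    return MarkerPanel(markers=records[:k])


def fit_cutoffs(panel: MarkerPanel, beta_matrix: pd.DataFrame,
                luma_sample_ids) -> MarkerPanel:
    """Fit each marker's mean + 2 SD cutoff over the luminal-A samples.

    The standard deviation uses the n-1 denominator; at least two
    luminal-A samples are required.
    """
    luma = list(luma_sample_ids)
    if len(luma) < 2:
        raise ValidationError("need >= 2 luminal-A samples to fit cutoffs")
    missing = [p for p in panel.probe_ids if p not in beta_matrix.index]
    if missing:
        raise ValidationError(f"panel probe(s) absent from matrix: {missing}")
    fitted = []
    for m in panel.markers:
        vals = beta_matrix.loc[m.probe_id, luma].to_numpy(dtype=float)
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        fitted.append(MarkerRecord(
            probe_id=m.probe_id, auc=m.auc, orientation=m.orientation,
            margin=m.margin, mu_a=mu, sigma_a=sigma,
            cutoff=mu + 2.0 * sigma if m.orientation == "hyper"
            else mu - 2.0 * sigma))
    return MarkerPanel(markers=fitted)


@dataclass
class EpiCall:
    sample_id: str
    flags: dict  # probe_id -> bool (exceeds the marker's cutoff)
    call: str  # Epi_lumA | Epi_lumB_HER2


def classify_samples(panel: MarkerPanel, beta_matrix: pd.DataFrame,
                     rule: str = "majority") -> list[EpiCall]:
    """Call each sample's epigenetic subtype from the fitted panel.

    Per marker the sample is flagged when its beta exceeds the cutoff
    (falls below it for hypo-oriented markers). Flags combine by
    ``rule``: ``majority`` (strict, default), ``all`` or ``any``; a
    sample satisfying the rule is called ``Epi_lumB_HER2``.
    """
    if rule not in ("majority", "all", "any"):
        raise ValueError("rule must be 'majority', 'all' or 'any'")
    if not panel.markers or panel.markers[0].cutoff is None:
        raise ValidationError("panel has no fitted cutoffs")
    missing = [p for p in panel.probe_ids if p not in beta_matrix.index]
    if missing:
        raise ValidationError(f"panel probe(s) absent from matrix: {missing}")
    calls = []
    for sample in beta_matrix.columns:
        flags = {}
        for m in panel.markers:
            b = float(beta_matrix.loc[m.probe_id, sample])
            flags[m.probe_id] = (b > m.cutoff if m.orientation == "hyper"
                                 else b < m.cutoff)
        n_flag = sum(flags.values())
        if rule == "majority":
            positive = n_flag * 2 > len(flags)
        elif rule == "all":
            positive = n_flag == len(flags)
        else:
            positive = n_flag > 0
        calls.append(EpiCall(sample_id=str(sample), flags=flags,
                             call="Epi_lumB_HER2" if positive else "Epi_lumA"))
    return calls


# ---------------------------------------------------------------------------
# clinical associations


def mann_whitney(a, b) -> dict:
    """Two-sided Mann-Whitney U; exact null for combined n <= 12."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact = (a.size + b.size) <= EXACT_MW_MAX_N and not ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return {"test": "mann_whitney_exact" if exact else "mann_whitney_normal",
            "statistic": float(res.statistic), "p": float(res.pvalue)}


def categorical_test(table) -> dict:
    """Chi-squared on a contingency table; Fisher's exact when sparse.

    Fisher's exact test (two-sided) replaces the chi-squared automatically
    whenever any expected cell count is below 5 (only defined for 2x2).
    """
    t = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(t)
    if (expected < 5).any():
        if t.shape != (2, 2):
            raise ValidationError(
                "expected cell < 5 in a non-2x2 table; merge categories")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return {"test": "fisher_exact", "statistic": float(odds),
                "p": float(p)}
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return {"test": "chi_squared", "statistic": float(stat), "p": float(p),
            "df": int(df)}


def clinical_association(group_a_ids, group_b_ids,
                         sample_sheet: pd.DataFrame) -> dict:
    """Compare clinicopathologic covariates between two sample groups.

    Continuous covariates (Ki-67 %, tumor size) use the Mann-Whitney U
    test; categorical ones (grade, node involvement, PgR status at the
    20 % positivity threshold) use chi-squared / Fisher contingency tests.
    """
    sheet = sample_sheet.set_index("sample_id")
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if not a_ids or not b_ids:
        raise ValidationError("both groups must be non-empty")
    a, b = sheet.loc[a_ids], sheet.loc[b_ids]
    report = {}
    for var in ("ki67_percent", "size_cm"):
        x = a[var].dropna().to_numpy(dtype=float)
        y = b[var].dropna().to_numpy(dtype=float)
        if x.size and y.size:
            report[var] = mann_whitney(x, y)
    cat_defs = {
        "grade": lambda df: df["grade"].map({2: "II", 3: "III"}),
        "node": lambda df: df["node"].map({True: "pos", False: "neg"}),
        "pgr_status": lambda df: np.where(
            df["pgr_percent"] >= 20, "pos", "neg"),
    }
    for var, f in cat_defs.items():
        va = pd.Series(f(a)).dropna()
        vb = pd.Series(f(b)).dropna()
        levels = sorted(set(va) | set(vb))
        if len(levels) < 2 or va.empty or vb.empty:
            continue
        table = np.array([[int((va == lv).sum()) for lv in levels],
                          [int((vb == lv).sum()) for lv in levels]])
        report[var] = categorical_test(table)
        report[var]["levels"] = levels
    return report
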