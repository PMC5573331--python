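"""Biomass grouping, differential abundance, trait correlations, qPCR.

Plants are split into Small / Medium / Large groups by total root mass
(TRM): Medium is the inclusive band mean +/- f * sd (sample sd, f = 0.5 by
default); Small and Large lie strictly below / above it.  miRNAs passing a
group-mean abundance floor (10 RPTM in either extreme group) are tested for
Small-vs-Large differential abundance with a negative-binomial likelihood
ratio test using a moment-estimated common dispersion and library-size
offsets, followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("plantsrna")

TRAITS = ["TRM", "RM", "HT", "MLL", "MLW", "TLA", "LN"]


@dataclass
class GroupAssignment:
    labels: dict[str, str]
    lo: float
    hi: float

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]


def assign_groups(trm: Mapping[str, float] | pd.Series,
                  f: float = 0.5,
                  reference: Sequence[float] | None = None) -> GroupAssignment:
    """Small/Medium/Large labels from TRM with thresholds mean +/- f*sd.

    ``reference`` optionally supplies the values the thresholds are computed
    from (e.g. a larger phenotyped cohort); by default the labelled samples
    themselves.  The sd is the sample (n-1) standard deviation; boundary
    values are Medium (the band is inclusive).
    """
    series = pd.Series(dict(trm), dtype=float)
    if len(series) < 3 and reference is None:
        raise ValueError("need at least 3 samples to form groups")
    ref = np.asarray(reference, dtype=float) if reference is not None \
        else series.to_numpy()
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0.0:
        log.warning("assign_groups: zero variance; all samples Medium")
        return GroupAssignment({s: "Medium" for s in series.index},
                               mean, mean)
    lo, hi = mean - f * sd, mean + f * sd
    labels = {}
    for sid, v in series.items():
        labels[sid] = "Small" if v < lo else ("Large" if v > hi else "Medium")
    return GroupAssignment(labels, lo, hi)


def filter_by_abundance(matrix: pd.DataFrame, groups: GroupAssignment,
                        floor: float = 10.0) -> pd.DataFrame:
    """Keep rows with mean RPTM >= floor in either the Small or Large group."""
    small = [s for s in groups.samples("Small") if s in matrix.columns]
    large = [s for s in groups.samples("Large") if s in matrix.columns]
    keep = (matrix[small].mean(axis=1) >= floor) | \
           (matrix[large].mean(axis=1) >= floor)
    return matrix.loc[keep]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- exact negative-binomial test machinery -------------------------------

def _common_dispersion(y_eq: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Pooled moment estimate of the NB dispersion on size-equalized
    counts: E[s^2] = m + phi * m^2 within each group, so
    phi = sum(s^2 - m) / sum(m^2) pooled over genes and groups."""
    num = 0.0
    den = 0.0
    for idx in group_idx:
        yy = y_eq[:, idx]
        m = yy.mean(axis=1)
        v = yy.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m ** 2))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _exact_nb_pvalue(a: int, b: int, n_s: int, n_l: int, phi: float) -> float:
    """Exact conditional two-sided NB test of group sums ``a`` vs ``b``.

    Conditional on the total ``t = a + b``, the distribution of ``a`` is
    free of the common expression rate (negative hypergeometric with the
    aggregate size parameters n/phi); the two-sided p-value sums every
    outcome no more probable than the observed one.
    """
    t = a + b
    if t == 0:
        return 1.0
    r_s = n_s / max(phi, 1e-8)
    r_l = n_l / max(phi, 1e-8)
    k = np.arange(t + 1)
    logw = (gammaln(k + r_s) - gammaln(k + 1)
            + gammaln(t - k + r_l) - gammaln(t - k + 1))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return float(min(w[w <= w[a] * (1 + 1e-12)].sum(), 1.0))


def test_differential(counts: pd.DataFrame,
                      library_sizes: Mapping[str, int] | pd.Series,
                      groups: GroupAssignment) -> pd.DataFrame:
    """Small-vs-Large exact negative-binomial test per miRNA.

    Counts are scaled to a common library size, a common dispersion is
    moment-estimated across genes, and each gene is tested with the exact
    conditional NB test on the per-group aggregate counts (the classic
    overdispersed analogue of Fisher's exact test used for count libraries).
    Returns a DataFrame indexed like ``counts`` with group mean RPTM,
    log2 fold change (Large over Small), raw and BH-adjusted p-values,
    sorted by adjusted p.
    """
    small = [s for s in groups.samples("Small") if s in counts.columns]
    large = [s for s in groups.samples("Large") if s in counts.columns]
    if len(small) < 2 or len(large) < 2:
        raise ValueError("each compared group needs at least 2 libraries")
    cols = small + large
    y = counts[cols].to_numpy(dtype=float)
    L = np.array([library_sizes[s] for s in cols], dtype=float)
    lbar = L.mean()
    y_eq = y / L * lbar
    n_s, n_l = len(small), len(large)
    idx_s = np.arange(n_s)
    idx_l = np.arange(n_s, n_s + n_l)

    phi = _common_dispersion(y_eq, [idx_s, idx_l])
    log.info("test_differential: common dispersion %.4g over %d miRNAs",
             phi, y.shape[0])

    agg_s = np.round(y_eq[:, idx_s].sum(axis=1)).astype(np.int64)
    agg_l = np.round(y_eq[:, idx_l].sum(axis=1)).astype(np.int64)
    mean_s = y_eq[:, idx_s].mean(axis=1) / lbar * 1e7
    mean_l = y_eq[:, idx_l].mean(axis=1) / lbar * 1e7

    eps = 0.5 / lbar * 1e7
    out = pd.DataFrame({
        "mean_rptm_small": mean_s,
        "mean_rptm_large": mean_l,
        "log2_fc": np.log2((mean_l + eps) / (mean_s + eps)),
        "p_value": [_exact_nb_pvalue(int(a), int(b), n_s, n_l, phi)
                    for a, b in zip(agg_s, agg_l)],
    }, index=counts.index)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("p_adj", kind="mergesort")


def trait_correlations(table: pd.DataFrame,
                       traits: Sequence[str] = TRAITS
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix with per-pair p-values.

    Constant columns give NaN for their pairs.
    """
    traits = [t for t in traits if t in table.columns]
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))),
                     index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if j <= i:
                continue
            pair = table[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


@dataclass
class QpcrRecord:
    sample_id: str
    target_ct: float
    reference_ct: float
    delta_ct: float
    ddct: float
    fold_change: float


def ddct_fold_change(records: pd.DataFrame,
                     calibrator: str) -> list[QpcrRecord]:
    """2^-ddCt relative quantification.

    ``records`` needs columns ``sample_id``, ``target_ct``,
    ``reference_ct``.  dCt = Ct_target - Ct_reference; ddCt subtracts the
    calibrator's dCt, so the calibrator's fold change is exactly 1.
    """
    df = records.set_index("sample_id")
    if calibrator not in df.index:
        raise ValueError(f"calibrator sample {calibrator!r} missing")
    dct = df["target_ct"] - df["reference_ct"]
    cal = float(dct.loc[calibrator])
    out = []
    for sid, row in df.iterrows():
        d = float(dct.loc[sid])
        out.append(QpcrRecord(
            sample_id=str(sid), target_ct=float(row["target_ct"]),
            reference_ct=float(row["reference_ct"]), delta_ct=d,
            ddct=d - cal, fold_change=2.0 ** (-(d - cal)),
        ))
    return out


def expression_trm_correlation(levels: pd.Series, trm: pd.Series,
                               groups: GroupAssignment | None = None):
    """Pearson correlation between per-sample expression and TRM.

    Returns ``(r, p)`` — and, when a grouping is supplied, a per-group
    mean +/- sd summary of the expression levels.
    """
    if set(levels.index) != set(trm.index):
        raise ValueError("expression and TRM sample ids do not match")
    if len(levels) < 3:
        raise ValueError("need at least 3 matched samples")
    x = trm.loc[levels.index].to_numpy(dtype=float)
    y = levels.to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    if groups is None:
        return float(r), float(p)
    summary = {}
    for gname in ("Small", "Medium", "Large"):
        ids = [s for s in groups.samples(gname) if s in levels.index]
        if ids:
            vals = levels.loc[ids]
            summary[gname] = (float(vals.mean()),
                              float(vals.std(ddof=1)) if len(ids) > 1 else 0.0)
    return float(r), float(p), summary
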