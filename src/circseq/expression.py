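"""Abundance quantification and differential screening of circRNA counts.

Quantification follows RPM = 1e6 * C / N on back-spliced read counts.
Differential testing is a conditional negative-binomial exact test on
normalized pooled counts (binomial conditional test in the Poisson limit),
with library-size or TMM normalization computed in-module.  Screening uses
the strict rule |log2FC| > 1 and p < 0.05 on raw p-values; a
Benjamini-Hochberg column is emitted as a side channel but not used for the
screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class CountMatrix:
    """Integer back-spliced read counts, features x samples, with a
    sample -> group map."""

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        df = self.values
        if df.columns.duplicated().any():
            raise ValueError("sample_ids must be unique")
        if df.index.duplicated().any():
            raise ValueError("feature_ids must be unique")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in df.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path, group_of: Mapping[str, str]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dict(group_of))


def rpm(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Back-spliced reads per million mapped back-spliced reads,
    RPM = 1e6 * C / N per sample; every column sums to 1e6."""
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return df / totals * 1e6


def normalize_factors(matrix: CountMatrix | pd.DataFrame, method: str = "tmm") -> pd.Series:
    """Per-sample depth scaling factors, normalized to geometric mean 1.

    ``librarysize``: column total over the geometric mean of totals.
    ``tmm``: robust relative depth as the weighted trimmed mean of per-feature
    M-values (log2 ratio of raw counts against the reference sample, the one
    with the median total; 30% M-trim and 5% A-trim per tail).  Unlike the
    plain library size, the trimmed estimate ignores a minority of
    composition outliers, so an equal-expression pair with a few spiked
    features still gets factors near 1.
    """
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    totals = df.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if method == "librarysize":
        return totals / stats.gmean(totals)
    if method != "tmm":
        raise ValueError(f"unknown normalization method {method!r}")
    ref = totals.sort_values(kind="stable").index[(len(totals) - 1) // 2]
    factors = {}
    for s in df.columns:
        factors[s] = _tmm_pair(df[s].to_numpy(float), df[ref].to_numpy(float))
    f = pd.Series(factors)
    return f / stats.gmean(f)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = 1.0 / o + 1.0 / r  # asymptotic variance of M on the raw scale
    lo_m, hi_m = np.quantile(m, [0.30, 0.70])
    lo_a, hi_a = np.quantile(a, [0.05, 0.95])
    sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not sel.any():
        return 1.0
    return float(2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))


def effective_library_sizes(matrix: CountMatrix, method: str = "tmm") -> pd.Series:
    """Per-sample effective depths on the scale of the column totals."""
    totals = matrix.values.sum(axis=0).astype(float)
    if method == "librarysize":
        return totals
    return normalize_factors(matrix, "tmm") * stats.gmean(totals)


@dataclass(frozen=True)
class DeResult:
    feature_id: str
    mean_rpm_a: float
    mean_rpm_b: float
    log2fc: float  # b versus a
    p_value: float
    direction: str  # up | down | ns


def _classify(log2fc: float, p: float, lfc_cut: float = 1.0, p_cut: float = 0.05) -> str:
    if p < p_cut and log2fc > lfc_cut:
        return "up"
    if p < p_cut and log2fc < -lfc_cut:
        return "down"
    return "ns"


def common_dispersion(pseudo: np.ndarray, group_idx: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion across features, floored at 0.

    Within each group the excess of the variance over the mean is related to
    the squared mean; estimates are pooled over groups and features weighted
    by residual degrees of freedom.
    """
    num = 0.0
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            continue
        sub = pseudo[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        w = len(idx) - 1
        num += w * np.sum((var[ok] - mu[ok]) / mu[ok] ** 2)
        den += w * ok.sum()
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_pvalue(y_b: int, total: int, r_a: float, r_b: float) -> float:
    """Two-sided exact p for the split of ``total`` pooled counts between two
    NB groups with sizes r_a, r_b, conditioning on the total.

    The conditional law is negative hypergeometric; the p-value sums the
    probabilities of all splits no more likely than the observed one
    (the minimum-likelihood two-sided convention).
    """
    y = np.arange(total + 1)
    if math.isfinite(r_a) and r_a > 0 and math.isfinite(r_b) and r_b > 0:
        logpmf = (
            special.gammaln(y + r_b) - special.gammaln(y + 1)
            + special.gammaln(total - y + r_a) - special.gammaln(total - y + 1)
        )
    else:  # dispersion 0: Poisson limit -> binomial split
        raise ValueError("group NB sizes must be positive and finite")
    logpmf -= special.logsumexp(logpmf)
    return _minlike_twosided(logpmf, y_b)


def _binomial_pvalue(y_b: int, total: int, prob_b: float) -> float:
    y = np.arange(total + 1)
    return _minlike_twosided(stats.binom.logpmf(y, total, prob_b), y_b)


def _minlike_twosided(logpmf: np.ndarray, observed: int) -> float:
    # sum of probabilities of outcomes no more likely than the observed one,
    # with the customary (1 + 1e-7) relative guard against float ties
    obs = logpmf[observed]
    include = logpmf <= obs + 1e-7
    if include.all():
        return 1.0
    p = float(np.exp(special.logsumexp(logpmf[include])))
    return min(1.0, max(p, float(np.finfo(float).tiny)))


def exact_test(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    dispersion: float | str = "auto",
    norm: str = "tmm",
    pseudo_count: float = 0.5,
) -> list[DeResult]:
    """Per-feature conditional exact test of group_b versus group_a.

    Counts are scaled to a common library size (the geometric mean of the
    effective sizes) and rounded; the split of each feature's pooled count
    between the groups is then tested against its conditional null
    (negative hypergeometric for NB dispersion > 0, binomial at 0).
    ``dispersion="auto"`` estimates a method-of-moments common dispersion.
    Features with zero counts in both groups return p = 1 and log2fc = 0.
    """
    sa = matrix.samples_in(group_a)
    sb = matrix.samples_in(group_b)
    if not sa or not sb:
        raise ValueError(f"empty group: {group_a if not sa else group_b}")
    if set(sa) & set(sb):
        raise ValueError("groups must be disjoint")
    eff = effective_library_sizes(matrix, norm)
    common = stats.gmean(eff[sa + sb])
    sub = matrix.values[sa + sb].to_numpy(float)
    scale = (common / eff[sa + sb]).to_numpy()
    pseudo = sub * scale[None, :]
    pseudo_int = np.rint(pseudo).astype(np.int64)
    n_a, n_b = len(sa), len(sb)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)

    if dispersion == "auto":
        phi = common_dispersion(pseudo, [idx_a, idx_b])
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be >= 0")

    rpm_df = rpm(matrix)
    mean_rpm_a = rpm_df[sa].mean(axis=1)
    mean_rpm_b = rpm_df[sb].mean(axis=1)

    results = []
    for fi, fid in enumerate(matrix.features):
        y_a = int(pseudo_int[fi, idx_a].sum())
        y_b = int(pseudo_int[fi, idx_b].sum())
        total = y_a + y_b
        mean_a = pseudo[fi, idx_a].mean()
        mean_b = pseudo[fi, idx_b].mean()
        lfc = math.log2((mean_b + pseudo_count) / (mean_a + pseudo_count))
        if total == 0:
            p = 1.0
            lfc = 0.0
        elif phi == 0:
            p = _binomial_pvalue(y_b, total, n_b / (n_a + n_b))
        else:
            p = _conditional_pvalue(y_b, total, n_a / phi, n_b / phi)
        results.append(
            DeResult(
                feature_id=fid,
                mean_rpm_a=float(mean_rpm_a.iloc[fi]),
                mean_rpm_b=float(mean_rpm_b.iloc[fi]),
                log2fc=float(lfc),
                p_value=p,
                direction=_classify(lfc, p),
            )
        )
    return results


def screen_de(
    results: Sequence[DeResult], lfc_cut: float = 1.0, p_cut: float = 0.05
) -> tuple[list[DeResult], list[DeResult]]:
    """Strict screening rule: up if log2FC > cut and p < p_cut, down if
    log2FC < -cut and p < p_cut.  Returns (up, down)."""
    up = [r for r in results if r.p_value < p_cut and r.log2fc > lfc_cut]
    down = [r for r in results if r.p_value < p_cut and r.log2fc < -lfc_cut]
    return up, down


def top_changed(results: Sequence[DeResult], k: int = 5) -> pd.DataFrame:
    """Top-k up- and down-regulated features ranked by |log2FC| among the
    screened set (the 'most robust changes' table)."""
    up, down = screen_de(results)
    rows = []
    for direction, group in (("up", up), ("down", down)):
        ranked = sorted(group, key=lambda r: (-abs(r.log2fc), r.feature_id))[:k]
        for rank, r in enumerate(ranked, 1):
            rows.append((direction, rank, r.feature_id, r.log2fc, r.p_value))
    return pd.DataFrame(rows, columns=["direction", "rank", "feature_id", "log2fc", "p_value"])


def de_table(results: Sequence[DeResult]) -> pd.DataFrame:
    """Tabular DE output with a BH-adjusted side column (not used by the
    screen)."""
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_rpm_a": [r.mean_rpm_a for r in results],
            "mean_rpm_b": [r.mean_rpm_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    df["fdr"] = stats.false_discovery_control(df["p_value"], method="bh")
    df["direction"] = [r.direction for r in results]
    return df


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative 2^-ddCt relative expression against a reference gene and a
    control condition."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_case = ct_target_case - ct_ref_case
    delta_ctrl = ct_target_ctrl - ct_ref_ctrl
    return 2.0 ** -(delta_case - delta_ctrl)
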