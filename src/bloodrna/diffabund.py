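"""Differential distribution of features between library groups.

A deliberately transparent negative-binomial testing scheme patterned on
the classic count-based differential-expression workflow:

* library scaling by upper-quartile normalization (factor = 75th percentile
  of a library's nonzero counts, rescaled to geometric mean 1);
* per-feature NB dispersion (Var = mu + alpha*mu^2) by method of moments,
  pooled across all libraries ("blind", used when any group is a single
  library) or within each group with the maximum taken ("per_condition");
  the per-feature estimate is shrunk toward a fitted mean-dispersion
  trend (alpha(mu) = a0 + a1/mu), which also serves as fallback where the
  moment estimate is unusable;
* a two-sided Wald test on log group means (the trend-stabilized
  dispersion is treated as known, so the statistic is referred to a
  normal) for replicated groups, and an exact-style conditional
  beta-binomial test for single-library-vs-single-library contrasts;
* Benjamini-Hochberg q-values over eligible features within each contrast.

No numeric equivalence with any external differential tool is claimed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import EligibilityFilter, apply_min_count

ALPHA_FLOOR = 1e-8
# Empirical-Bayes-style compromise between the noisy per-feature moment
# estimate and the smooth mean-dispersion trend; fixed by a calibration
# simulation against the nominal 5% level.
SHRINKAGE_WEIGHT = 0.7

FRACTIONS = ("I", "II", "III", "IV", "V")
COHORTS = ("H", "LSCC", "LAC")


@dataclass(frozen=True)
class ContrastDesign:
    """Two disjoint library groups and the dispersion mode for the test."""

    mode: str  # fraction_vs_fraction | cohort_vs_cohort
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    dispersion_mode: str = "auto"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if self.dispersion_mode not in ("auto", "blind", "per_condition"):
            raise ValueError(f"unknown dispersion mode {self.dispersion_mode!r}")

    @property
    def resolved_dispersion(self) -> str:
        if self.dispersion_mode != "auto":
            return self.dispersion_mode
        return (
            "blind"
            if min(len(self.group_a), len(self.group_b)) == 1
            else "per_condition"
        )


def upper_quartile_factors(matrix: pd.DataFrame) -> pd.Series:
    """Per-library size factors from the 75th percentile of nonzero counts.

    Factors are rescaled so their geometric mean is 1; dividing a library's
    counts by its factor puts all libraries on a common scale.
    """
    uq = {}
    for lib in matrix.columns:
        col = matrix[lib]
        nz = col[col > 0]
        if nz.empty:
            raise ValueError(f"library {lib!r} has no nonzero counts")
        uq[lib] = float(np.percentile(nz, 75))
    uqs = pd.Series(uq)
    return uqs / stats.gmean(uqs)


def normalize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix / upper_quartile_factors(matrix)


def _moment_alpha(values: np.ndarray) -> float:
    """Method-of-moments dispersion from one group of normalized counts."""
    if len(values) < 2:
        return np.nan
    mu = values.mean()
    if mu <= 0:
        return np.nan
    var = values.var(ddof=1)
    return (var - mu) / mu**2


def estimate_dispersion(
    norm_counts: pd.DataFrame, design: ContrastDesign
) -> pd.Series:
    """Per-feature NB dispersion alpha for one contrast.

    Blind mode pools every library of the contrast as a single group;
    per-condition fits within each group and takes the maximum.  Usable
    moment estimates are shrunk toward a mean-dispersion trend
    alpha(mu) = a0 + a1/mu fitted across features; features whose moment
    estimate is undefined or non-positive take the trend value outright;
    everything is floored at a small positive value.
    """
    libs = list(design.group_a) + list(design.group_b)
    sub = norm_counts[libs]
    mode = design.resolved_dispersion
    raw = np.full(len(sub), np.nan)
    for i, (_, row) in enumerate(sub.iterrows()):
        if mode == "blind":
            raw[i] = _moment_alpha(row.to_numpy(dtype=float))
        else:
            a = _moment_alpha(row[list(design.group_a)].to_numpy(dtype=float))
            b = _moment_alpha(row[list(design.group_b)].to_numpy(dtype=float))
            if np.isnan(a) and np.isnan(b):
                raw[i] = np.nan
            else:
                raw[i] = np.nanmax([a, b])
    mu = sub.mean(axis=1).to_numpy(dtype=float)
    alpha = _with_trend_fallback(raw, mu)
    return pd.Series(alpha, index=sub.index, name="alpha")


def _with_trend_fallback(raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    valid = np.isfinite(raw) & (raw > 0) & (mu > 0)
    out = raw.copy()
    if valid.sum() >= 2:
        X = np.column_stack([np.ones(valid.sum()), 1.0 / mu[valid]])
        coef, *_ = np.linalg.lstsq(X, raw[valid], rcond=None)
        with np.errstate(divide="ignore"):
            trend = np.where(
                mu > 0, coef[0] + coef[1] / np.where(mu > 0, mu, 1.0), ALPHA_FLOOR
            )
        trend = np.maximum(trend, ALPHA_FLOOR)
        out = np.where(
            valid, SHRINKAGE_WEIGHT * raw + (1 - SHRINKAGE_WEIGHT) * trend, trend
        )
    else:
        out[~valid] = ALPHA_FLOOR
    return np.maximum(out, ALPHA_FLOOR)


def _wald_test(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[float, float, float, float, float]:
    """Two-sided Wald test of equal NB means on the log scale.

    The delta-method variance of a log group mean is (1/mu + alpha)/n;
    with the trend-stabilized dispersion treated as known the statistic
    is referred to a standard normal.
    """
    pc = 0.5  # continuity offset so zero-mean groups stay testable
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    la, lb = np.log(ma + pc), np.log(mb + pc)
    va = ((ma + pc) + alpha * (ma + pc) ** 2) / na
    vb = ((mb + pc) + alpha * (mb + pc) ** 2) / nb
    se = np.sqrt(va / (ma + pc) ** 2 + vb / (mb + pc) ** 2)
    stat = (lb - la) / se
    p = 2.0 * stats.norm.sf(abs(stat))
    log2fc = (lb - la) / np.log(2.0)
    return ma, mb, log2fc, stat, min(p, 1.0)


def _conditional_test(
    a: float, b: float, alpha: float
) -> tuple[float, float, float, float, float]:
    """Exact-style conditional test for 1-vs-1 contrasts.

    For two NB(mu, alpha) counts with a common mean, the first count given
    the total is beta-binomial(N, r, r) with r = 1/alpha (binomial(N, 1/2)
    in the Poisson limit); the two-sided p sums all outcomes no more
    probable than the observed one.
    """
    ka, kb = int(round(a)), int(round(b))
    n = ka + kb
    pc = 0.5
    log2fc = float(np.log2((b + pc) / (a + pc)))
    if n == 0:
        return a, b, 0.0, 0.0, 1.0
    r = 1.0 / max(alpha, ALPHA_FLOOR)
    r = min(r, 1e6)  # beta-binomial -> binomial limit, numerically stable
    x = np.arange(n + 1)
    pmf = stats.betabinom.pmf(x, n, r, r)
    p_obs = pmf[ka]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    stat = float(ka - n / 2.0)
    return a, b, log2fc, stat, min(p, 1.0)


def nb_test(
    norm_counts: pd.DataFrame,
    alpha: pd.Series,
    design: ContrastDesign,
    eligible: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-feature differential test for one contrast.

    Returns a frame with columns feature_id, mean_A, mean_B, log2fc, stat,
    p, q, eligible.  q-values (Benjamini-Hochberg) are computed over
    eligible features only; ineligible features keep NaN p and q.
    """
    eligible_set = set(eligible) if eligible is not None else set(norm_counts.index)
    ga = norm_counts[list(design.group_a)].to_numpy(dtype=float)
    gb = norm_counts[list(design.group_b)].to_numpy(dtype=float)
    one_vs_one = ga.shape[1] == 1 and gb.shape[1] == 1
    rows = []
    for i, fid in enumerate(norm_counts.index):
        is_eligible = fid in eligible_set
        if not is_eligible:
            a_mean = ga[i].mean()
            b_mean = gb[i].mean()
            rows.append((fid, a_mean, b_mean, np.nan, np.nan, np.nan, False))
            continue
        al = float(alpha.loc[fid])
        if one_vs_one:
            ma, mb, lfc, st, p = _conditional_test(ga[i, 0], gb[i, 0], al)
        else:
            ma, mb, lfc, st, p = _wald_test(ga[i], gb[i], al)
        rows.append((fid, ma, mb, lfc, st, p, True))
    out = pd.DataFrame(
        rows, columns=["feature_id", "mean_A", "mean_B", "log2fc", "stat", "p", "eligible"]
    )
    out["q"] = np.nan
    mask = out["eligible"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out[["feature_id", "mean_A", "mean_B", "log2fc", "stat", "p", "q", "eligible"]]


def run_contrast(
    matrix: pd.DataFrame,
    design: ContrastDesign,
    filt: EligibilityFilter = EligibilityFilter(),
) -> pd.DataFrame:
    """Normalize, estimate dispersion, and test one contrast end-to-end.

    Eligibility uses raw fragment counts summed over the contrast's
    libraries (the per-test semantics of the minimum-alignment-count
    cut-off).
    """
    libs = list(design.group_a) + list(design.group_b)
    eligible = apply_min_count(matrix, filt, libraries=libs)
    norm = normalize_counts(matrix[libs])
    alpha = estimate_dispersion(norm, design)
    return nb_test(norm, alpha, design, eligible=eligible)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "fraction", "cohort"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    bad_f = set(sheet["fraction"]) - set(FRACTIONS)
    bad_c = set(sheet["cohort"]) - set(COHORTS)
    if bad_f or bad_c:
        raise ValueError(f"unknown fraction/cohort labels: {bad_f | bad_c}")
    return sheet


def enumerate_contrasts(sheet: pd.DataFrame) -> dict[str, ContrastDesign]:
    """The two published comparison schemes.

    Fraction-vs-fraction: all 10 fraction pairs, the three cohorts acting
    as replicates of each fraction (per-condition dispersion).
    Cohort-vs-cohort: within each fraction, healthy vs LSCC and healthy vs
    LAC (single libraries, blind dispersion).
    """
    by_fraction: dict[str, list[str]] = {}
    by_pair: dict[tuple[str, str], list[str]] = {}
    for _, row in sheet.iterrows():
        by_fraction.setdefault(row["fraction"], []).append(row["library_id"])
        by_pair.setdefault((row["fraction"], row["cohort"]), []).append(
            row["library_id"]
        )
    missing = [f for f in FRACTIONS if f not in by_fraction]
    if missing:
        raise ValueError(f"sample sheet missing fractions: {missing}")
    contrasts: dict[str, ContrastDesign] = {}
    for fa, fb in itertools.combinations(FRACTIONS, 2):
        contrasts[f"fraction_{fa}_vs_{fb}"] = ContrastDesign(
            mode="fraction_vs_fraction",
            group_a=tuple(sorted(by_fraction[fa])),
            group_b=tuple(sorted(by_fraction[fb])),
        )
    for f in FRACTIONS:
        for cohort in ("LSCC", "LAC"):
            ga = by_pair.get((f, "H"))
            gb = by_pair.get((f, cohort))
            if not ga or not gb:
                raise ValueError(f"fraction {f}: missing H or {cohort} library")
            contrasts[f"fraction_{f}_H_vs_{cohort}"] = ContrastDesign(
                mode="cohort_vs_cohort",
                group_a=tuple(sorted(ga)),
                group_b=tuple(sorted(gb)),
            )
    return contrasts


def run_contrasts(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    filt: EligibilityFilter = EligibilityFilter(),
) -> dict[str, pd.DataFrame]:
    """All fraction-vs-fraction and per-fraction cohort contrasts."""
    unknown = set(sheet["library_id"]) - set(matrix.columns)
    if unknown:
        raise ValueError(f"sample sheet libraries absent from count matrix: {unknown}")
    return {
        name: run_contrast(matrix, design, filt)
        for name, design in enumerate_contrasts(sheet).items()
    }
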