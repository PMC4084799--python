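"""Per-probeset differential-inclusion testing.

Implements the testing stack for a small paired design:

* plain paired t-tests (one-sample t on within-pair case - control
  differences, df = n_pairs - 1), used for pi0 estimation because their
  null p-values are independent across probesets;
* empirical-Bayes moderated t-tests, which borrow strength across probesets
  by shrinking each probeset's variance toward a common prior
  ``s2 ~ s0^2 * F(d, d0)``, with hyperparameters (d0, s0^2) estimated by
  method of moments on log variances;
* Storey's pi0 estimator: raw pi0(lambda) = #{p > lambda} / (m (1-lambda))
  on a lambda grid, smoothed by a cubic smoothing spline with 3 effective
  degrees of freedom and read off at the largest lambda;
* q-values (step-up with the pi0 factor; pi0 = 1 reduces exactly to
  Benjamini-Hochberg);
* directional enrichment: among probesets below a p-value threshold, an
  exact binomial test of the proportion with t > 0 (higher inclusion in
  cases) against 0.5, plus the same proportion in p-value bins of width
  0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats

from .inclusion import ExpressionBundle, InclusionMatrix

__all__ = [
    "ModerationParams",
    "Pi0Estimate",
    "paired_differences",
    "paired_t_tests",
    "fit_moderation",
    "moderated_t_tests",
    "estimate_pi0",
    "compute_qvalues",
    "direction_enrichment",
    "bin_direction",
    "expression_level_contrast",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


# ---------------------------------------------------------------------------
# paired t-tests

def pairing_from_design(design: pd.DataFrame) -> list[tuple[str, str]]:
    """(case sample, control sample) per pair, in pair order."""
    out = []
    for pair, grp in design.groupby("pair", sort=True):
        case = grp.loc[grp["status"] == "case", "sample"].item()
        control = grp.loc[grp["status"] == "control", "sample"].item()
        out.append((case, control))
    return out


def paired_differences(
    values: pd.DataFrame,
    pairing: list[tuple[str, str]],
) -> pd.DataFrame:
    """Within-pair case - control differences, one column per pair."""
    cols = {}
    for i, (case, control) in enumerate(pairing):
        cols[f"d{i + 1}"] = values[case] - values[control]
    return pd.DataFrame(cols, index=values.index)


def _t_from_differences(diffs: np.ndarray) -> tuple[np.ndarray, ...]:
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return mean, sd, t, p, zero_var


def paired_t_tests(
    incl: InclusionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    *,
    pairing: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided one-sample t-test on within-pair differences per probeset.

    Returns a table with the per-pair differences, ``mean_diff``, ``s2``
    (sample variance of the differences), ``t``, ``p_plain``, ``df``,
    ``direction`` (sign of t) and ``zero_variance``.  Probesets whose
    difference vector has zero variance get an undefined statistic
    (t = NaN); they are flagged so downstream pi0 estimation can drop them.
    """
    values = incl.values if isinstance(incl, InclusionMatrix) else incl
    if pairing is None:
        pairing = pairing_from_design(design)
    n = len(pairing)
    if n < 2:
        raise ValueError("need at least 2 pairs for a paired t-test")
    diffs = paired_differences(values, pairing)
    mean, sd, t, p, zero_var = _t_from_differences(
        diffs.to_numpy(dtype=float))
    out = diffs.copy()
    out["n_pairs"] = n
    out["mean_diff"] = mean
    out["s2"] = sd**2
    out["df"] = n - 1
    out["t"] = t
    out["p_plain"] = p
    out["direction"] = np.sign(t)
    out["zero_variance"] = zero_var
    return out


def welch_t_tests(
    incl: InclusionMatrix | pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Unpaired Welch t-test per probeset (sensitivity-analysis mode)."""
    values = incl.values if isinstance(incl, InclusionMatrix) else incl
    cases = design.loc[design["status"] == "case", "sample"]
    controls = design.loc[design["status"] == "control", "sample"]
    t, p = stats.ttest_ind(
        values[list(cases)], values[list(controls)], axis=1, equal_var=False
    )
    return pd.DataFrame(
        {"t": t, "p_plain": p, "direction": np.sign(t)}, index=values.index
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

@dataclass
class ModerationParams:
    """Hyperparameters of the scaled-F prior on probeset variances."""

    d0: float          # prior degrees of freedom; may be inf
    s02: float         # prior variance
    d: float           # residual df per probeset (equal across probesets)

    def __post_init__(self) -> None:
        if not (self.d0 > 0 or np.isinf(self.d0)) and self.d0 != 0.0:
            raise ValueError("d0 must be positive, zero (no-shrinkage "
                             "limit) or infinite")
        if not self.s02 > 0 and not np.isinf(self.d0):
            raise ValueError("s02 must be positive")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def fit_moderation(s2: np.ndarray | pd.Series, d: float) -> ModerationParams:
    """Method-of-moments fit of the variance prior on log variances.

    Under ``s2 ~ s0^2 * (chi2_d / d) / (chi2_d0 / d0)`` the mean and
    variance of ``log s2`` are known in closed form via digamma/trigamma;
    matching the first two moments yields (d0, s0^2).  When the observed
    spread of log variances does not exceed the sampling spread expected
    from chi2_d alone, d0 is infinite (all variances shrunk to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    positive = s2 > 0
    if positive.sum() == 0:
        raise ValueError("all variances are zero; cannot fit moderation")
    if len(s2) < 100:
        warnings.warn("fewer than 100 variances; moderation fit is "
                      "unstable", stacklevel=2)
    z = np.log(s2[positive])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    m = len(e)
    evar = float(((e - emean) ** 2).sum() / (m - 1))
    evar -= float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return ModerationParams(d0=d0, s02=s02, d=float(d))


def moderated_t_tests(
    table: pd.DataFrame,
    params: ModerationParams,
) -> pd.DataFrame:
    """Add moderated columns to a plain paired-test table.

    Posterior variance ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)``;
    ``t_mod = mean_diff / (s~ / sqrt(n_pairs))``; two-sided p from the t
    distribution with ``d0 + d`` df (standard normal when d0 is infinite;
    d0 = 0 recovers the plain test exactly).
    """
    if params is None:
        raise ValueError("moderation params missing")
    out = table.copy()
    s2 = out["s2"].to_numpy(dtype=float)
    n = out["n_pairs"].to_numpy(dtype=float)
    d = params.d
    if np.isinf(params.d0):
        s2_post = np.full_like(s2, params.s02)
        df_total = np.inf
    else:
        s2_post = (params.d0 * params.s02 + d * s2) / (params.d0 + d)
        df_total = params.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = out["mean_diff"].to_numpy(dtype=float) / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t_mod"] = t_mod
    out["p_mod"] = p_mod
    out["direction"] = np.sign(np.where(np.isnan(t_mod), out["t"], t_mod))
    return out


def run_tests(
    incl: InclusionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    *,
    pairing: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, ModerationParams]:
    """Plain + moderated tests in one call (the standard stack)."""
    table = paired_t_tests(incl, design, pairing=pairing)
    usable = ~table["zero_variance"]
    params = fit_moderation(
        table.loc[usable, "s2"], d=float(table["df"].iloc[0]))
    table = moderated_t_tests(table, params)
    return table, params


# ---------------------------------------------------------------------------
# pi0 and q-values

@dataclass
class Pi0Estimate:
    """Storey pi0 estimate with its raw lambda trajectory."""

    pi0: float
    lambda_grid: tuple[float, ...]
    raw_pi0: tuple[float, ...]
    n_tests: int
    method: str = "smoother"


_SPLINE_LAMBDA_CACHE: dict[tuple[float, ...], float] = {}


def _smoothing_parameter_for_df(x: np.ndarray, target_df: float = 3.0
                                ) -> float:
    """Find the penalty giving a smoother matrix with the target trace.

    ``make_smoothing_spline`` is linear in y, so the effective degrees of
    freedom equal the trace of the smoother matrix, computed column by
    column from unit responses.  The penalty is found by bisection on its
    logarithm (df decreases monotonically with the penalty).
    """
    key = tuple(np.round(x, 10))
    if key in _SPLINE_LAMBDA_CACHE:
        return _SPLINE_LAMBDA_CACHE[key]

    def df_of(log_lam: float) -> float:
        lam = np.exp(log_lam)
        tr = 0.0
        for i in range(len(x)):
            y = np.zeros_like(x)
            y[i] = 1.0
            spl = interpolate.make_smoothing_spline(x, y, lam=lam)
            tr += float(spl(x[i]))
        return tr

    lo, hi = -25.0, 25.0  # log penalty bracket
    # df_of is decreasing; want df_of(mid) == target
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if df_of(mid) > target_df:
            lo = mid
        else:
            hi = mid
    lam = float(np.exp(0.5 * (lo + hi)))
    _SPLINE_LAMBDA_CACHE[key] = lam
    return lam


def estimate_pi0(
    pvalues: np.ndarray | pd.Series,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    *,
    smoother_df: float = 3.0,
) -> Pi0Estimate:
    """Estimate the proportion of true null hypotheses (Storey smoother).

    ``raw_pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on
    the grid; a natural cubic smoothing spline with ``smoother_df``
    effective degrees of freedom is fitted to the trajectory and evaluated
    at the largest lambda; the result is clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < 100:
        warnings.warn("pi0 estimation with fewer than 100 p-values is "
                      "unreliable", stacklevel=2)
    grid = np.asarray(lambda_grid, dtype=float)
    if len(grid) < 4:
        raise ValueError("need at least 4 lambda grid points to smooth")
    if np.any((grid <= 0) | (grid >= 1)) or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be increasing within (0, 1)")
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    lam_penalty = _smoothing_parameter_for_df(grid, smoother_df)
    spline = interpolate.make_smoothing_spline(grid, raw, lam=lam_penalty)
    pi0 = float(np.clip(spline(grid[-1]), 0.0, 1.0))
    return Pi0Estimate(
        pi0=pi0,
        lambda_grid=tuple(grid),
        raw_pi0=tuple(raw),
        n_tests=m,
    )


def compute_qvalues(
    pvalues: np.ndarray | pd.Series,
    pi0: float,
) -> np.ndarray:
    """Step-up q-values ``q(j) = min_{k>=j} pi0 m p(k) / k``, clipped at 1.

    With pi0 = 1 this is exactly the Benjamini-Hochberg adjusted p-value.
    Input order is preserved; NaN p-values yield NaN q-values.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pi0 * m * pv[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.clip(qs, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# directional enrichment

def direction_enrichment(
    table: pd.DataFrame,
    threshold: float = 0.2,
    *,
    p_column: str = "p_mod",
    t_column: str = "t_mod",
) -> dict:
    """Test the excess of positive t-statistics below a p-value threshold.

    Counts probesets with ``p <= threshold`` split by the sign of t
    (t = 0 and undefined statistics excluded) and applies a two-sided
    exact binomial test against a null proportion of 0.5.  A positive
    excess means more probesets with higher inclusion in cases.
    """
    sub = table[(table[p_column] <= threshold)
                & np.isfinite(table[t_column])]
    n_pos = int((sub[t_column] > 0).sum())
    n_neg = int((sub[t_column] < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        return {
            "threshold": threshold, "n_pos": 0, "n_neg": 0,
            "proportion_pos": np.nan, "p_binomial": np.nan,
            "defined": False,
        }
    result = stats.binomtest(n_pos, n, p=0.5, alternative="two-sided")
    return {
        "threshold": threshold,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "proportion_pos": n_pos / n,
        "p_binomial": float(result.pvalue),
        "defined": True,
    }


def bin_direction(
    table: pd.DataFrame,
    *,
    width: float = 0.05,
    p_column: str = "p_mod",
    t_column: str = "t_mod",
) -> pd.DataFrame:
    """Per-bin counts of positive/negative t over p-value bins of ``width``.

    Bins partition [0, 1]; each row reports the bin interval, the counts of
    t > 0 and t < 0 and the proportion positive (NaN for empty bins).
    """
    n_bins = int(round(1.0 / width))
    if not np.isclose(n_bins * width, 1.0):
        raise ValueError("bin width must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sub = table[np.isfinite(table[p_column]) & np.isfinite(table[t_column])]
    p = sub[p_column].to_numpy()
    t = sub[t_column].to_numpy()
    idx = np.clip(np.floor(p / width).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n_pos = int((t[mask] > 0).sum())
        n_neg = int((t[mask] < 0).sum())
        n_zero = int((t[mask] == 0).sum())
        total = n_pos + n_neg
        rows.append({
            "bin_left": edges[b],
            "bin_right": edges[b + 1],
            "n_pos": n_pos,
            "n_neg": n_neg,
            "n_zero": n_zero,
            "proportion_pos": n_pos / total if total else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression level of affected probesets

def expression_level_contrast(
    bundle: ExpressionBundle,
    table: pd.DataFrame,
    *,
    alpha: float = 0.01,
    p_column: str = "p_mod",
    t_column: str = "t_mod",
) -> pd.DataFrame:
    """Compare raw expression of affected probesets with their gene's rest.

    For each direction group (Up: p <= alpha and t > 0; Down: p <= alpha
    and t < 0), and for every metaprobeset containing at least one group
    member and at least one unaffected probeset, computes the ratio of the
    group members' mean linear-scale intensity (2**log2, averaged across
    all samples) to the unaffected probesets' mean.  Reports the mean and
    median per-metaprobeset ratio and a Wilcoxon signed-rank test of the
    log2 ratios against zero.  Metaprobesets with no unaffected probeset
    are skipped and counted.
    """
    tested = table.index
    p = table[p_column]
    t = table[t_column]
    affected_up = (p <= alpha) & (t > 0)
    affected_dn = (p <= alpha) & (t < 0)
    unaffected = ~(affected_up | affected_dn)
    meta_of = bundle.annotation.loc[tested, "metaprobeset"]
    linear = (2.0 ** bundle.probesets.loc[tested]).mean(axis=1)

    rows = []
    groups = (("Up", affected_up), ("Down", affected_dn),
              ("Unaffected", unaffected))
    for group_name, mask in groups:
        ratios = []
        n_skipped = 0
        for meta, idx in tested.groupby(meta_of).items():
            members = [i for i in idx if mask.loc[i]]
            if not members:
                continue
            others = [i for i in idx if unaffected.loc[i]]
            if not others:
                n_skipped += 1
                continue
            ratios.append(
                linear.loc[members].mean() / linear.loc[others].mean()
            )
        ratios = np.asarray(ratios)
        if len(ratios) >= 1:
            logr = np.log2(ratios)
            nonzero = logr[logr != 0]
            if len(nonzero) >= 10:
                stat, pval = stats.wilcoxon(nonzero)
            else:
                stat, pval = np.nan, np.nan
            rows.append({
                "group": group_name,
                "n_metaprobesets": len(ratios),
                "n_skipped_no_unaffected": n_skipped,
                "mean_ratio": float(ratios.mean()),
                "median_ratio": float(np.median(ratios)),
                "p_signed_rank": float(pval) if np.isfinite(pval) else np.nan,
            })
        else:
            rows.append({
                "group": group_name,
                "n_metaprobesets": 0,
                "n_skipped_no_unaffected": n_skipped,
                "mean_ratio": np.nan,
                "median_ratio": np.nan,
                "p_signed_rank": np.nan,
            })
    return pd.DataFrame(rows)
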