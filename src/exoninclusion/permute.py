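"""Exhaustive relabelings of the paired design and permutation pi0 tests.

The key diagnostic for a genuine transcriptome-wide signal in a tiny paired
study is that the observed case/control labeling yields a *lower* pi0 (more
apparent non-null probesets) than any relabeling of the samples:

* restricted enumeration — swap/not-swap the labels within each sibling
  pair (2**n_pairs ordered labelings, all of them properly paired, so the
  paired t-test stays comparable);
* unrestricted enumeration — all C(2n, n) ordered case/control splits of
  the 2n samples regardless of sibship (70 ordered, 35 unordered splits for
  4 pairs); pairs are re-formed within intact sibling pairs first, the
  remaining cases and controls matched in ascending sample order.

Each configuration gets a pi0 estimate from plain paired t-tests with the
same settings as the observed analysis; the empirical p-value is the
tie-inclusive fraction of ordered labelings whose pi0 is at or below the
observed one (the observed labeling and its global mirror always count, so
the smallest attainable p is 2 / #ordered).  The number of properly paired
sibling pairs per configuration supports the pi0-vs-pairing correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import (
    DEFAULT_LAMBDA_GRID,
    estimate_pi0,
    paired_t_tests,
)
from .inclusion import InclusionMatrix

__all__ = [
    "LabelConfiguration",
    "PermutationSummary",
    "enumerate_within_pair",
    "enumerate_group_splits",
    "pi0_per_configuration",
    "empirical_p",
    "pi0_pairing_correlation",
    "run_permutation_analysis",
]


@dataclass
class LabelConfiguration:
    """One case/control assignment of the 2 n_pairs samples.

    ``case_samples`` is the ordered tuple of samples labelled case;
    ``pairing`` lists (case, control) sample pairs used for the paired
    test; ``properly_paired`` counts sibling pairs holding exactly one
    case and one control.  A configuration and its global label swap (its
    *mirror*) are indistinguishable to a two-sided paired test.
    """

    case_samples: tuple[str, ...]
    pairing: tuple[tuple[str, str], ...]
    constrained: bool
    properly_paired: int
    is_observed: bool
    pi0: float | None = None


def _design_pairs(design: pd.DataFrame) -> list[tuple[str, str]]:
    """Sibling (case, control) sample pairs of the observed design."""
    pairs = []
    for pair, grp in design.groupby("pair", sort=True):
        case = grp.loc[grp["status"] == "case", "sample"].item()
        control = grp.loc[grp["status"] == "control", "sample"].item()
        pairs.append((case, control))
    return pairs


def enumerate_within_pair(design: pd.DataFrame) -> list[LabelConfiguration]:
    """All 2**n_pairs labelings obtained by swapping labels within pairs.

    Every configuration keeps all sibling pairs properly paired; the
    pairing used for the paired test remains the sibling pairs (with the
    case/control roles possibly swapped).  The observed labeling is the
    all-no-swap element.
    """
    sib = _design_pairs(design)
    n = len(sib)
    configs = []
    for swaps in product((False, True), repeat=n):
        pairing = tuple(
            (c, t) if swap else (t, c)
            for (t, c), swap in zip(sib, swaps)
        )
        cases = tuple(case for case, _ in pairing)
        configs.append(
            LabelConfiguration(
                case_samples=cases,
                pairing=pairing,
                constrained=True,
                properly_paired=n,
                is_observed=not any(swaps),
            )
        )
    return configs


def _residual_pairing(
    cases: tuple[str, ...],
    sib: list[tuple[str, str]],
    sample_order: list[str],
) -> tuple[tuple[tuple[str, str], ...], int]:
    """Pair a free split: intact sibling pairs first, then by sample index."""
    case_set = set(cases)
    pairing: list[tuple[str, str]] = []
    leftover_cases: list[str] = []
    leftover_controls: list[str] = []
    properly = 0
    for t, c in sib:
        in_case = (t in case_set, c in case_set)
        if in_case == (True, False):
            pairing.append((t, c))
            properly += 1
        elif in_case == (False, True):
            pairing.append((c, t))
            properly += 1
        elif in_case == (True, True):
            leftover_cases.extend([t, c])
        else:
            leftover_controls.extend([t, c])
    rank = {s: i for i, s in enumerate(sample_order)}
    leftover_cases.sort(key=rank.__getitem__)
    leftover_controls.sort(key=rank.__getitem__)
    pairing.extend(zip(leftover_cases, leftover_controls))
    return tuple(pairing), properly


def enumerate_group_splits(design: pd.DataFrame) -> list[LabelConfiguration]:
    """All C(2n, n) ordered case/control splits, ignoring sibship.

    The unordered-split count is half of this (each split and its global
    mirror).  Pairing for the paired test matches within intact sibling
    pairs where possible; remaining cases and controls are matched in
    ascending sample-index order (a deterministic convention).
    """
    sib = _design_pairs(design)
    samples = list(design["sample"])
    n = len(sib)
    observed_cases = frozenset(t for t, _ in sib)
    configs = []
    for combo in combinations(samples, n):
        cases = tuple(combo)
        pairing, properly = _residual_pairing(cases, sib, samples)
        configs.append(
            LabelConfiguration(
                case_samples=cases,
                pairing=pairing,
                constrained=False,
                properly_paired=properly,
                is_observed=frozenset(cases) == observed_cases,
            )
        )
    return configs


def pi0_per_configuration(
    incl: InclusionMatrix | pd.DataFrame,
    configs: list[LabelConfiguration],
    *,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> list[LabelConfiguration]:
    """Fill ``pi0`` for every configuration (plain paired t p-values).

    Uses the same estimator settings as the observed analysis; zero
    variance probesets are excluded from the pi0 input, exactly as in the
    main pipeline.
    """
    values = incl.values if isinstance(incl, InclusionMatrix) else incl
    for cfg in configs:
        table = paired_t_tests(values, design=None, pairing=list(cfg.pairing))
        p = table.loc[~table["zero_variance"], "p_plain"]
        cfg.pi0 = estimate_pi0(p, lambda_grid).pi0
    return configs


def empirical_p(configs: list[LabelConfiguration]) -> float:
    """Tie-inclusive fraction of ordered labelings with pi0 <= observed.

    The observed configuration is a member of the enumeration, and its
    global mirror always produces the same two-sided p-values, so the
    smallest attainable value is 2 / #configs.
    """
    if not configs:
        raise ValueError("empty enumeration")
    if any(c.pi0 is None for c in configs):
        raise ValueError("pi0 not computed for all configurations")
    observed = [c for c in configs if c.is_observed]
    if len(observed) != 1:
        raise ValueError("enumeration must contain the observed labeling "
                         "exactly once")
    obs = observed[0].pi0
    return sum(c.pi0 <= obs for c in configs) / len(configs)


def _mirror_representatives(
    configs: list[LabelConfiguration],
) -> list[LabelConfiguration]:
    seen: set[frozenset] = set()
    reps = []
    for cfg in configs:
        key = frozenset(cfg.case_samples)
        mirror = frozenset(
            frozenset(s for s, _ in cfg.pairing)
            | frozenset(s for _, s in cfg.pairing)
        ) - key
        pair_key = frozenset({key, frozenset(mirror)})
        if pair_key not in seen:
            seen.add(pair_key)
            reps.append(cfg)
    return reps


def pi0_pairing_correlation(
    configs: list[LabelConfiguration],
    *,
    collapse_mirrors: bool = True,
) -> dict:
    """Correlate pi0 with the properly-paired count across configurations.

    By default one representative per mirror class is used (a labeling and
    its global swap have identical pi0 and pairing count).  Pearson r uses
    the t-approximation p-value; Spearman rho uses mid-ranks for ties.
    A constant pi0 vector leaves the correlation undefined.
    """
    if any(c.pi0 is None for c in configs):
        raise ValueError("pi0 not computed for all configurations")
    use = _mirror_representatives(configs) if collapse_mirrors else configs
    paired = np.array([c.properly_paired for c in use], dtype=float)
    pi0 = np.array([c.pi0 for c in use], dtype=float)
    if len(np.unique(paired)) < 3:
        raise ValueError("need >= 3 distinct properly-paired values")
    out = {"n": len(use)}
    if np.allclose(pi0, pi0[0]):
        out.update({"pearson_r": np.nan, "pearson_p": np.nan,
                    "spearman_rho": np.nan, "spearman_p": np.nan,
                    "defined": False})
        return out
    r, rp = stats.pearsonr(pi0, paired)
    rho, rhop = stats.spearmanr(pi0, paired)
    out.update({"pearson_r": float(r), "pearson_p": float(rp),
                "spearman_rho": float(rho), "spearman_p": float(rhop),
                "defined": True})
    return out


@dataclass
class PermutationSummary:
    """Observed pi0, the enumerated configurations, and the summaries."""

    mode: str                          # 'within-pair' or 'splits'
    observed_pi0: float
    configs: list[LabelConfiguration] = field(repr=False, default_factory=list)
    empirical_p: float = np.nan
    correlation: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for cfg in self.configs:
            rows.append({
                "case_samples": ",".join(cfg.case_samples),
                "constrained": cfg.constrained,
                "properly_paired": cfg.properly_paired,
                "is_observed": cfg.is_observed,
                "pi0": cfg.pi0,
            })
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "observed_pi0": self.observed_pi0,
            "n_configurations": len(self.configs),
            "empirical_p": self.empirical_p,
            "correlation": {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.correlation.items()
            },
        }


def run_permutation_analysis(
    incl: InclusionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    *,
    mode: str = "within-pair",
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> PermutationSummary:
    """Enumerate, estimate pi0 per configuration, and summarise."""
    if mode == "within-pair":
        configs = enumerate_within_pair(design)
    elif mode == "splits":
        configs = enumerate_group_splits(design)
    else:
        raise ValueError("mode must be 'within-pair' or 'splits'")
    configs = pi0_per_configuration(incl, configs, lambda_grid=lambda_grid)
    observed = next(c for c in configs if c.is_observed)
    summary = PermutationSummary(
        mode=mode,
        observed_pi0=observed.pi0,
        configs=configs,
        empirical_p=empirical_p(configs),
    )
    try:
        summary.correlation = pi0_pairing_correlation(configs)
    except ValueError:
        summary.correlation = {"defined": False,
                               "reason": "not enough distinct pairing counts"}
    return summary
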