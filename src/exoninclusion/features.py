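"""Structural characterization of differentially included exons.

Probesets are mapped one-to-one onto exons (random partial bijection, to
avoid double-counting exons hit by several probesets), labelled Up / Down /
background from the moderated test results, and compared on eight
structural features: 5' and 3' splice-site scores, upstream and downstream
intron lengths, exon length, nucleotide content, distance from the 3' gene
end and gene length.  Group comparisons use the two-sided Wilcoxon rank-sum
test (exact distribution for small pooled sizes, normal approximation with
tie and continuity corrections otherwise) with Benjamini-Hochberg or
q-value correction across the tests of one table.

The exonic-splicing-enhancer (ESE) analysis counts hexamer motif
occurrences (overlaps allowed, sense strand) per group, normalised by the
summed exon length of the group, and can mask all motif instances out of
the sequences to re-examine base composition without them.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .difftest import compute_qvalues

__all__ = [
    "ESESet",
    "map_one_to_one",
    "assign_groups",
    "derive_features",
    "rank_sum_test",
    "compare_feature",
    "compare_feature_table",
    "nucleotide_content",
    "ese_prevalence",
    "mask_ese",
    "length_class_summaries",
]

SHORT_INTRON_BP = 250   # below: intron-definition class (strict <)
LONG_EXON_BP = 500      # above: too long for exon definition (strict >)


# ---------------------------------------------------------------------------
# probeset <-> exon mapping and grouping

def map_one_to_one(
    links: list[tuple[str, str]] | pd.DataFrame,
    seed: int,
) -> dict[str, str]:
    """Random partial bijection from a many-to-many probeset<->exon graph.

    Edges are visited in a seeded random order and greedily accepted when
    both endpoints are still free, so no probeset or exon appears twice
    (at most one exon per probeset and one probeset per exon).
    Reproducible for a fixed seed.
    """
    if isinstance(links, pd.DataFrame):
        edges = list(zip(links.iloc[:, 0], links.iloc[:, 1]))
    else:
        edges = list(links)
    if not edges:
        raise ValueError("empty link set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    mapping: dict[str, str] = {}
    used_exons: set[str] = set()
    for i in order:
        probeset, exon = edges[i]
        if probeset in mapping or exon in used_exons:
            continue
        mapping[probeset] = exon
        used_exons.add(exon)
    return mapping


def assign_groups(
    mapping: dict[str, str],
    results: pd.DataFrame,
    *,
    alpha: float = 0.01,
    p_column: str = "p_mod",
    t_column: str = "t_mod",
) -> pd.Series:
    """Label mapped exons Up / Down / background from the test results.

    Up: p <= alpha and t > 0 (higher inclusion in cases); Down: p <= alpha
    and t < 0; background: every other tested, mapped exon.  Probesets in
    the mapping but absent from the results are skipped.
    """
    labels = {}
    for probeset, exon in mapping.items():
        if probeset not in results.index:
            continue
        p = results.at[probeset, p_column]
        t = results.at[probeset, t_column]
        if np.isfinite(p) and np.isfinite(t) and p <= alpha and t > 0:
            labels[exon] = "Up"
        elif np.isfinite(p) and np.isfinite(t) and p <= alpha and t < 0:
            labels[exon] = "Down"
        else:
            labels[exon] = "background"
    return pd.Series(labels, name="group")


# ---------------------------------------------------------------------------
# feature derivation

def derive_features(
    annotation: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    splice_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Populate the eight structural features for every annotated exon.

    ``annotation`` is indexed by exon id with columns ``chrom``, ``start``,
    ``end`` (0-based half-open), ``strand``, ``gene_id``, ``gene_start``,
    ``gene_end``; optional precomputed ``intron_up``/``intron_dn`` columns
    are used for genes with a single annotated exon.  For multi-exon genes
    flanking intron lengths are derived from adjacent exons in transcript
    orientation (on the minus strand the upstream intron lies at higher
    genomic coordinates).  First/last exons get a missing value for the
    intron they lack.  ``dist3`` is the distance from the exon to the gene's
    3' terminus (0 for an exon ending there).  ``splice_scores`` supplies
    ``ss5_score``/``ss3_score`` columns on the same index; ``sequences``
    supply per-exon nucleotide counts.
    """
    ann = annotation.copy()
    required = {"chrom", "start", "end", "strand", "gene_id",
                "gene_start", "gene_end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if ((ann["start"] < ann["gene_start"]) |
            (ann["end"] > ann["gene_end"])).any():
        raise ValueError("exon outside its gene span")

    ann["exon_length"] = ann["end"] - ann["start"]
    ann["gene_length"] = ann["gene_end"] - ann["gene_start"]
    plus = ann["strand"] == "+"
    ann["dist3"] = np.where(
        plus, ann["gene_end"] - ann["end"], ann["start"] - ann["gene_start"]
    )

    up = pd.Series(np.nan, index=ann.index, dtype=float)
    dn = pd.Series(np.nan, index=ann.index, dtype=float)
    for gene, grp in ann.groupby("gene_id"):
        if len(grp) == 1:
            exon = grp.index[0]
            if "intron_up" in ann.columns:
                up.at[exon] = ann.at[exon, "intron_up"]
            if "intron_dn" in ann.columns:
                dn.at[exon] = ann.at[exon, "intron_dn"]
            continue
        grp = grp.sort_values("start")
        gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
        if (gaps < 0).any():
            raise ValueError(f"overlapping exons in gene {gene!r}")
        strand = grp["strand"].iloc[0]
        ids = list(grp.index)
        for k, exon in enumerate(ids):
            before = gaps[k - 1] if k > 0 else np.nan
            after = gaps[k] if k < len(gaps) else np.nan
            if strand == "+":
                up.at[exon], dn.at[exon] = before, after
            else:
                up.at[exon], dn.at[exon] = after, before
    ann["intron_up"] = up
    ann["intron_dn"] = dn

    if splice_scores is not None:
        ann["ss5_score"] = splice_scores.reindex(ann.index)["ss5_score"]
        ann["ss3_score"] = splice_scores.reindex(ann.index)["ss3_score"]

    if sequences is not None:
        counts = {b: [] for b in "ACGT"}
        for exon in ann.index:
            seq = sequences.get(exon, "")
            if seq and len(seq) != ann.at[exon, "exon_length"]:
                raise ValueError(
                    f"sequence length mismatch for exon {exon!r}")
            c = Counter(seq.upper())
            for b in "ACGT":
                counts[b].append(c.get(b, 0))
        for b in "ACGT":
            ann[f"count_{b}"] = counts[b]
    return ann


def nucleotide_content(sequence: str) -> dict[str, float]:
    """Base proportions over A, C, G, T only (case-folded).

    Ambiguity codes are excluded from both numerator and denominator; a
    sequence containing no unambiguous base is undefined (all NaN).
    """
    if not sequence:
        raise ValueError("empty sequence")
    c = Counter(sequence.upper())
    total = sum(c.get(b, 0) for b in "ACGT")
    if total == 0:
        return {b: math.nan for b in "ACGT"}
    return {b: c.get(b, 0) / total for b in "ACGT"}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with exact small-sample distribution

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by dynamic programming over midranks.

    Enumerates (by subset-sum counting) the distribution of the rank-sum
    of a size-``len(x)`` group over all C(N, len(x)) equally likely rank
    assignments, with midranks handling ties exactly.  p is the
    probability of a rank-sum at least as far from its mean as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # midranks
    r2 = np.round(ranks * 2).astype(int)    # doubled -> integers
    n1 = len(x)
    total = r2.sum()
    # dp[k, s] = number of size-k subsets with doubled-rank-sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    n_subsets = counts.sum()
    observed = int(np.round(ranks[:n1].sum() * 2))
    mean2 = n1 * (len(pooled) + 1)          # doubled mean rank-sum
    dev = abs(observed - mean2)
    sums = np.arange(total + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(counts[extreme].sum() / n_subsets)


def _normal_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


def rank_sum_test(x, y, *, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Uses the exact distribution (ties handled via midranks) when the
    pooled sample size is at most ``exact_max_n``, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    w = float(stats.rankdata(np.concatenate([x, y]))[: len(x)].sum())
    if len(x) + len(y) <= exact_max_n:
        return w, _exact_rank_sum_p(x, y)
    return w, _normal_rank_sum_p(x, y)


@dataclass
class FeatureComparison:
    """One group-vs-baseline rank test on one structural feature."""

    feature: str
    group: str
    n_group: int
    n_baseline: int
    statistic: float
    p_value: float
    group_mean: float
    group_median: float
    baseline_mean: float
    baseline_median: float
    adjusted: float = math.nan


def compare_feature(
    table: pd.DataFrame,
    feature: str,
    *,
    groups: tuple[str, ...] = ("Up", "Down"),
    baseline: str = "rest",
) -> list[FeatureComparison]:
    """Rank-sum comparison of each direction group against its baseline.

    ``baseline='rest'`` compares a group against all other tested exons
    (the published convention); ``baseline='background'`` compares against
    unaffected exons only.  Groups with no members are skipped.
    """
    if "group" not in table.columns:
        raise ValueError("table must carry a 'group' column")
    out = []
    for group in groups:
        gvals = table.loc[table["group"] == group, feature].dropna()
        if baseline == "rest":
            bvals = table.loc[table["group"] != group, feature].dropna()
        elif baseline == "background":
            bvals = table.loc[
                table["group"] == "background", feature].dropna()
        else:
            raise ValueError("baseline must be 'rest' or 'background'")
        if len(gvals) == 0 or len(bvals) == 0:
            continue
        w, p = rank_sum_test(gvals, bvals)
        out.append(FeatureComparison(
            feature=feature,
            group=group,
            n_group=len(gvals),
            n_baseline=len(bvals),
            statistic=w,
            p_value=p,
            group_mean=float(gvals.mean()),
            group_median=float(gvals.median()),
            baseline_mean=float(bvals.mean()),
            baseline_median=float(bvals.median()),
        ))
    return out


def compare_feature_table(
    table: pd.DataFrame,
    features: list[str],
    *,
    groups: tuple[str, ...] = ("Up", "Down"),
    baseline: str = "rest",
    correction: str = "bh",
) -> pd.DataFrame:
    """Run all group x feature comparisons and correct within the table.

    The correction family is the full set of Up/Down tests of this table;
    ``correction`` is ``'bh'`` (Benjamini-Hochberg) or ``'qvalue'``
    (q-values with pi0 estimated from these p-values when there are enough
    of them, else pi0 = 1).
    """
    comparisons: list[FeatureComparison] = []
    for feature in features:
        comparisons.extend(
            compare_feature(table, feature, groups=groups, baseline=baseline)
        )
    if not comparisons:
        return pd.DataFrame()
    pvals = np.array([c.p_value for c in comparisons])
    if correction == "bh":
        adjusted = multipletests(pvals, method="fdr_bh")[1]
    elif correction == "qvalue":
        # too few tests for a stable pi0 estimate -> conservative pi0 = 1
        adjusted = compute_qvalues(pvals, pi0=1.0)
    else:
        raise ValueError("correction must be 'bh' or 'qvalue'")
    rows = []
    for c, adj in zip(comparisons, adjusted):
        c.adjusted = float(adj)
        rows.append(vars(c))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESE hexamers

@dataclass
class ESESet:
    """A set of candidate exonic-splicing-enhancer hexamers."""

    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        motifs = tuple(m.upper() for m in self.motifs)
        for m in motifs:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"invalid hexamer motif {m!r}")
        if len(set(motifs)) != len(motifs):
            raise ValueError("duplicate motifs in ESE set")
        self.motifs = motifs

    def __len__(self) -> int:
        return len(self.motifs)

    @classmethod
    def from_file(cls, path) -> "ESESet":
        with open(path) as fh:
            motifs = [line.strip() for line in fh if line.strip()]
        return cls(tuple(motifs))


def _count_motif_hits(sequence: str, motifs: frozenset[str]) -> int:
    """Occurrences of any motif, overlaps allowed, sense strand."""
    seq = sequence.upper()
    k = 6
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] in motifs)


def ese_prevalence(
    groups: pd.Series,
    sequences: dict[str, str],
    eses: ESESet,
) -> pd.DataFrame:
    """Per-group ESE prevalence: motif occurrences per base pair.

    Occurrences of all motifs over all exons of a group (overlapping
    matches counted) divided by the summed exon length of the group.
    Duplicating every exon of a group leaves the prevalence unchanged.
    """
    motifs = frozenset(eses.motifs)
    rows = []
    for group, exon_ids in groups.groupby(groups).groups.items():
        hits = 0
        total_len = 0
        for exon in exon_ids:
            seq = sequences[exon]
            hits += _count_motif_hits(seq, motifs)
            total_len += len(seq)
        rows.append({
            "group": group,
            "n_exons": len(exon_ids),
            "n_hits": hits,
            "total_length": total_len,
            "prevalence": hits / total_len if total_len else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def mask_ese(sequence: str, eses: ESESet) -> str:
    """Remove every position covered by any ESE motif match.

    Returns the concatenation of the positions not covered by any
    (possibly overlapping) hexamer match, for re-computing composition
    with enhancer bases excluded.
    """
    seq = sequence.upper()
    motifs = frozenset(eses.motifs)
    k = 6
    covered = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - k + 1):
        if seq[i:i + k] in motifs:
            covered[i:i + k] = True
    return "".join(ch for ch, c in zip(seq, covered) if not c)


# ---------------------------------------------------------------------------
# length classes

def length_class_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group fractions of short introns (<250 bp) and long exons (>500 bp).

    Flanking introns are summarised separately for the upstream and
    downstream side and pooled; thresholds are strict inequalities.
    """
    rows = []
    for group, grp in table.groupby("group"):
        up = grp["intron_up"].dropna()
        dn = grp["intron_dn"].dropna()
        pooled = pd.concat([up, dn])
        exons = grp["exon_length"].dropna()
        rows.append({
            "group": group,
            "n_exons": len(grp),
            "frac_short_intron_up": (
                float((up < SHORT_INTRON_BP).mean()) if len(up) else np.nan),
            "frac_short_intron_dn": (
                float((dn < SHORT_INTRON_BP).mean()) if len(dn) else np.nan),
            "frac_short_intron_all": (
                float((pooled < SHORT_INTRON_BP).mean())
                if len(pooled) else np.nan),
            "frac_long_exon": (
                float((exons > LONG_EXON_BP).mean()) if len(exons)
                else np.nan),
            "median_exon_length": (
                float(exons.median()) if len(exons) else np.nan),
            "median_intron_up": (
                float(up.median()) if len(up) else np.nan),
            "median_intron_dn": (
                float(dn.median()) if len(dn) else np.nan),
        })
    return pd.DataFrame(rows).set_index("group")
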