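"""Synthetic paired exon-array data with known ground truth.

The generator emulates the statistical structure of a small paired design:
``n_pairs`` case/control sibling pairs, gene-level expression with a shared
within-pair random effect (siblings are more alike than strangers, which is
what makes the pairing informative), probeset-level inclusion offsets for a
chosen fraction ``1 - pi0_true`` of affected probesets, and a direction bias
toward higher inclusion in cases.  A companion annotation generator draws
per-exon structural features (lengths, flanking introns, composition,
splice-site scores, gene context) from distributions that differ between
affected and background exons, mirroring the contrasts the analysis is meant
to recover: affected exons shorter, A+T-rich, flanked by longer upstream
introns with few short (<250 bp) ones, farther from the 3' gene end and on
longer genes.

All randomness flows from a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inclusion import ExpressionBundle

__all__ = [
    "SimulationParams",
    "SyntheticAnnotationParams",
    "generate_dataset",
    "generate_annotation",
    "generate_ese_set",
]

# fraction of probesets flagged as cross-hybridizing in synthetic annotation
CROSS_HYB_RATE = 0.01
# metaprobeset (gene-summary) measurement noise, as a fraction of noise_sd:
# the gene-level summary pools many probes, so it is less noisy than a
# single probeset
META_NOISE_FRACTION = 0.5
# spread of the per-probeset baseline inclusion offset (log2 units)
PROBESET_BASELINE_SD = 0.5
# overall mean log2 intensity of the synthetic arrays
GRAND_MEAN = 8.0


@dataclass
class SimulationParams:
    """Parameters of the paired expression simulator.

    Defaults reproduce the study design the pipeline targets: 4 sibling
    pairs, ~80% truly null probesets, affected probesets shifted by an
    exponential effect with mean ``effect_size`` log2 units, positive
    (higher inclusion in cases) with probability ``direction_bias``.
    """

    n_pairs: int = 4
    n_genes: int = 2500
    probesets_per_gene: tuple[int, int] = (4, 10)
    pi0_true: float = 0.8
    effect_size: float = 0.5
    direction_bias: float = 0.8
    pair_sd: float = 0.5
    gene_sd: float = 1.0
    noise_sd: float = 0.25
    inclusion_pair_sd: float = 0.0
    detect_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi0_true", "direction_bias", "detect_fraction"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        for name in ("pair_sd", "gene_sd", "noise_sd", "effect_size",
                     "inclusion_pair_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 for a paired test")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.probesets_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probesets_per_gene must be 1 <= lo <= hi")


def _make_design(n_pairs: int) -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample": f"T{i}", "pair": f"P{i}", "status": "case"})
        rows.append({"sample": f"C{i}", "pair": f"P{i}", "status": "control"})
    return pd.DataFrame(rows)


def generate_dataset(
    params: SimulationParams,
) -> tuple[ExpressionBundle, pd.DataFrame]:
    """Draw a synthetic :class:`ExpressionBundle` and its truth table.

    The probeset model is

        X[p, s] = mu_g + b[g, pair(s)] + alpha_p + c[p, pair(s)]
                  + delta_p * 1[s is case] + eps[p, s]

    with gene baseline ``mu_g ~ N(GRAND_MEAN, gene_sd)``, gene-expression
    pair random effect ``b ~ N(0, pair_sd)`` shared by the two siblings of
    a pair, probeset baseline ``alpha_p ~ N(0, 0.5)``, a *splicing-level*
    family effect ``c ~ N(0, inclusion_pair_sd)`` per probeset x pair
    (siblings share genetic determinants of baseline exon inclusion, so
    each family has its own inclusion offset per exon; it enters the
    probeset intensity but not the transcript-level summary), effect
    ``delta_p`` zero for null probesets and
    ``sign * Exponential(mean=effect_size)`` otherwise, and iid noise
    ``eps ~ N(0, noise_sd)``.  The family inclusion effect is what makes
    the sibling pairing informative: it cancels from properly paired
    differences but inflates the variance of any case-control comparison
    that breaks the sibling pairs.

    The metaprobeset intensity is an independent measurement of the same
    gene-level signal, ``M[g, s] = mu_g + b[g, pair(s)] + eta[g, s]`` with
    ``eta ~ N(0, noise_sd / 2)``: it emulates a robust multi-probe
    transcript summary (RMA-style median polish), which tracks overall
    transcript abundance and is insensitive to the minority of
    differentially included exons.  Averaging the probesets themselves
    would leak the direction-biased effects into every null probeset's
    inclusion value, which the robust summary of the real pipeline does
    not do.  Detection calls are Bernoulli(``detect_fraction``) per
    probeset x sample.

    Returns the bundle and a truth table with one row per probeset
    (``probeset``, ``metaprobeset``, ``is_null``, ``delta``,
    ``is_affected``).
    """
    rng = np.random.default_rng(params.seed)
    design = _make_design(params.n_pairs)
    n_samples = 2 * params.n_pairs
    lo, hi = params.probesets_per_gene
    per_gene = rng.integers(lo, hi + 1, size=params.n_genes)
    m = int(per_gene.sum())
    gene_of = np.repeat(np.arange(params.n_genes), per_gene)

    probeset_ids = pd.Index(
        [f"ps{i:07d}" for i in range(m)], name="probeset"
    )
    gene_ids = np.array([f"mp{g:06d}" for g in range(params.n_genes)])

    mu = rng.normal(GRAND_MEAN, params.gene_sd, size=params.n_genes)
    pair_eff = rng.normal(
        0.0, params.pair_sd, size=(params.n_genes, params.n_pairs)
    )
    alpha = rng.normal(0.0, PROBESET_BASELINE_SD, size=m)

    is_null = rng.random(m) < params.pi0_true
    magnitude = rng.exponential(params.effect_size, size=m)
    sign = np.where(rng.random(m) < params.direction_bias, 1.0, -1.0)
    delta = np.where(is_null, 0.0, sign * magnitude)

    pair_idx = np.repeat(np.arange(params.n_pairs), 2)  # T_i, C_i per pair
    is_case = np.tile([1.0, 0.0], params.n_pairs)
    # sample columns ordered T1, C1, T2, C2, ...
    sample_order = [
        s for i in range(1, params.n_pairs + 1) for s in (f"T{i}", f"C{i}")
    ]
    design = (
        design.set_index("sample").loc[sample_order].reset_index()
    )

    family_incl = rng.normal(
        0.0, params.inclusion_pair_sd, size=(m, params.n_pairs))
    X = (
        mu[gene_of][:, None]
        + pair_eff[gene_of][:, pair_idx]
        + alpha[:, None]
        + family_incl[:, pair_idx]
        + delta[:, None] * is_case[None, :]
        + rng.normal(0.0, params.noise_sd, size=(m, n_samples))
    )
    probes = pd.DataFrame(X, index=probeset_ids, columns=sample_order)

    meta_noise = rng.normal(
        0.0, META_NOISE_FRACTION * params.noise_sd,
        size=(params.n_genes, n_samples),
    )
    M = mu[:, None] + pair_eff[:, pair_idx] + meta_noise
    meta = pd.DataFrame(M, index=pd.Index(gene_ids, name="metaprobeset"),
                        columns=sample_order)
    # keep only genes that received probesets (all of them, by construction)
    meta = meta.loc[np.unique(gene_ids[gene_of])]

    detection = pd.DataFrame(
        rng.random((m, n_samples)) < params.detect_fraction,
        index=probeset_ids,
        columns=sample_order,
    )

    annotation = pd.DataFrame(
        {
            "metaprobeset": gene_ids[gene_of],
            "probeset_set": "core",
            "region": "exonic",
            "splice_type": "na",
            "cross_hyb": rng.random(m) < CROSS_HYB_RATE,
        },
        index=probeset_ids,
    )

    truth = pd.DataFrame(
        {
            "probeset": probeset_ids,
            "metaprobeset": gene_ids[gene_of],
            "is_null": is_null,
            "delta": delta,
            "is_affected": ~is_null,
        }
    ).set_index("probeset")

    bundle = ExpressionBundle(
        probesets=probes,
        metaprobesets=meta,
        annotation=annotation,
        detection=detection,
        design=design,
    )
    return bundle, truth


def _validate_composition(vec: tuple[float, float, float, float],
                          name: str) -> None:
    if len(vec) != 4 or not math.isclose(sum(vec), 1.0, abs_tol=1e-9):
        raise ValueError(f"{name} must be 4 proportions summing to 1")
    if any(v < 0 for v in vec):
        raise ValueError(f"{name} has negative entries")


@dataclass
class SyntheticAnnotationParams:
    """Distribution parameters for synthetic exon structural features.

    Lengths are drawn log-normally (``logloc``/``logscale`` are the
    underlying normal's location and scale); flanking introns come from a
    two-component mixture of a short mode (mean < 250 bp, the intron-defined
    class) and a log-normal long mode.  Affected exons get a depleted short
    mode and a longer long mode upstream.  Composition vectors are base
    proportions in A, C, G, T order.
    """

    # exon length (bp)
    exon_logloc_bg: float = math.log(150.0)
    exon_logloc_affected: float = math.log(110.0)
    exon_logscale: float = 0.8
    # flanking intron mixture
    short_intron_weight_bg: float = 0.25
    short_intron_weight_affected: float = 0.08
    short_intron_mean: float = 120.0
    long_intron_logloc_bg: float = math.log(1800.0)
    long_intron_logloc_affected: float = math.log(2400.0)
    long_intron_logscale: float = 1.0
    # nucleotide composition (A, C, G, T)
    composition_bg: tuple[float, float, float, float] = (
        0.24, 0.26, 0.26, 0.24)
    composition_affected: tuple[float, float, float, float] = (
        0.31, 0.19, 0.19, 0.31)
    # gene context
    gene_logloc_bg: float = math.log(43000.0)
    gene_logloc_affected: float = math.log(54000.0)
    gene_logscale: float = 1.2
    three_prime_beta_bg: tuple[float, float] = (1.5, 2.8)
    three_prime_beta_affected: tuple[float, float] = (2.2, 2.4)
    # splice-site scores (MaxEnt-like scale)
    ss5_loc_bg: float = 8.1
    ss5_loc_affected: float = 8.6
    ss3_loc: float = 8.3
    ss_sd: float = 2.5

    def __post_init__(self) -> None:
        _validate_composition(self.composition_bg, "composition_bg")
        _validate_composition(self.composition_affected,
                              "composition_affected")
        for name in ("short_intron_weight_bg", "short_intron_weight_affected"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.short_intron_mean < 250:
            raise ValueError("short_intron_mean must lie in (0, 250) bp")


MIN_EXON_LEN = 25
MAX_EXON_LEN = 20_000
MIN_INTRON_LEN = 30


def _draw_intron(rng: np.random.Generator, n: int, weight_short: float,
                 params: SyntheticAnnotationParams,
                 logloc_long: float) -> np.ndarray:
    short = rng.random(n) < weight_short
    # short mode: shifted exponential, kept strictly below 250 bp
    short_len = MIN_INTRON_LEN + rng.exponential(
        params.short_intron_mean - MIN_INTRON_LEN, size=n
    )
    short_len = np.minimum(short_len, 249.0)
    long_len = np.exp(
        rng.normal(logloc_long, params.long_intron_logscale, size=n)
    )
    long_len = np.clip(long_len, 250.0, None)
    return np.where(short, short_len, long_len).astype(int)


def generate_annotation(
    params: SyntheticAnnotationParams,
    truth: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw one exon per probeset with structural features and a sequence.

    Each exon is placed inside its own synthetic gene record on one
    synthetic chromosome, so that gene length and distance from the 3' gene
    end are exact by construction (``distance_3prime <= gene_length`` and
    ``gene_length >= exon length``).  Flanking intron lengths are drawn from
    the mixture model and carried as annotation columns.  Coordinates are
    stored 0-based half-open.

    Returns the exon feature table (indexed by exon id) and a dict of
    sense-strand sequences whose length equals the recorded exon length.
    """
    if truth.index.duplicated().any():
        raise ValueError("truth table has duplicated probeset ids")
    rng = np.random.default_rng(seed)
    n = len(truth)
    affected = truth["is_affected"].to_numpy(dtype=bool)

    exon_len = np.exp(
        np.where(affected, params.exon_logloc_affected, params.exon_logloc_bg)
        + rng.normal(0.0, params.exon_logscale, size=n)
    )
    exon_len = np.clip(exon_len, MIN_EXON_LEN, MAX_EXON_LEN).astype(int)

    intron_up = np.empty(n, dtype=int)
    intron_dn = np.empty(n, dtype=int)
    for mask, w, loc in (
        (affected, params.short_intron_weight_affected,
         params.long_intron_logloc_affected),
        (~affected, params.short_intron_weight_bg,
         params.long_intron_logloc_bg),
    ):
        k = int(mask.sum())
        intron_up[mask] = _draw_intron(rng, k, w, params, loc)
        # downstream introns: background-like for both groups
        intron_dn[mask] = _draw_intron(
            rng, k, params.short_intron_weight_bg, params,
            params.long_intron_logloc_bg)

    gene_len = np.exp(
        np.where(affected, params.gene_logloc_affected, params.gene_logloc_bg)
        + rng.normal(0.0, params.gene_logscale, size=n)
    ).astype(int)
    gene_len = np.maximum(gene_len, exon_len + 10)

    a_bg, b_bg = params.three_prime_beta_bg
    a_af, b_af = params.three_prime_beta_affected
    frac = np.where(
        affected,
        rng.beta(a_af, b_af, size=n),
        rng.beta(a_bg, b_bg, size=n),
    )
    dist3 = np.floor(frac * (gene_len - exon_len)).astype(int)

    ss5 = rng.normal(
        np.where(affected, params.ss5_loc_affected, params.ss5_loc_bg),
        params.ss_sd,
    )
    ss3 = rng.normal(params.ss3_loc, params.ss_sd, size=n)

    strand = np.where(rng.random(n) < 0.5, "+", "-")

    # lay the synthetic genes head to tail on one chromosome
    gap = 1000
    gene_start = np.concatenate(
        [[gap], gap + np.cumsum(gene_len[:-1] + gap)]
    ).astype(np.int64)
    gene_end = gene_start + gene_len
    # distance from the 3' gene end, strand-aware
    exon_start = np.where(
        strand == "+", gene_end - dist3 - exon_len, gene_start + dist3
    ).astype(np.int64)
    exon_end = exon_start + exon_len

    probesets = truth.index.to_numpy()
    exon_ids = np.array([f"ex_{p}" for p in probesets])
    gene_ids = np.array([f"g_{p}" for p in probesets])

    table = pd.DataFrame(
        {
            "exon_id": exon_ids,
            "probeset": probesets,
            "chrom": "chrS",
            "start": exon_start,
            "end": exon_end,
            "strand": strand,
            "exon_length": exon_len,
            "intron_up": intron_up,
            "intron_dn": intron_dn,
            "gene_id": gene_ids,
            "gene_start": gene_start,
            "gene_end": gene_end,
            "gene_length": gene_len,
            "dist3": dist3,
            "ss5_score": ss5,
            "ss3_score": ss3,
            "is_affected": affected,
        }
    ).set_index("exon_id")

    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    comp_af = np.asarray(params.composition_affected)
    comp_bg = np.asarray(params.composition_bg)
    sequences: dict[str, str] = {}
    for i, exon_id in enumerate(exon_ids):
        comp = comp_af if affected[i] else comp_bg
        seq = rng.choice(bases, size=exon_len[i], p=comp)
        sequences[exon_id] = "".join(seq)
    return table, sequences


def generate_ese_set(n: int = 238, seed: int = 0,
                     a_fraction: float = 0.5) -> list[str]:
    """Draw a synthetic set of unique A-rich hexamer splicing-enhancer motifs.

    Stands in for a published candidate-ESE list (not shipped with the
    package); matches its cardinality (238) and approximate A-content
    (about half of all bases are A).
    """
    rng = np.random.default_rng(seed)
    rest = (1.0 - a_fraction) / 3.0
    probs = [a_fraction, rest, rest, rest]
    bases = np.array(list("ACGT"))
    motifs: set[str] = set()
    while len(motifs) < n:
        motifs.add("".join(rng.choice(bases, size=6, p=probs)))
    return sorted(motifs)
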