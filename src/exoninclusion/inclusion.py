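"""Detection filtering and the normalized exon-inclusion statistic.

Exon-array intensities arrive summarised at two levels: *probesets* (one per
exon-sized region) and *metaprobesets* (the transcript/gene-level aggregate).
Inclusion of an exon in its gene's transcripts is measured per sample as the
log-ratio of the two, i.e. on the log2 scale

    I[p, s] = X_probeset[p, s] - X_metaprobeset[g(p), s]

computed after removing probesets that are unreliable (rarely detected above
background, or flagged as cross-hybridizing) and metaprobesets whose
expression support is too thin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBundle",
    "InclusionMatrix",
    "FilterReport",
    "apply_detection_filters",
    "compute_inclusion",
]

#: columns required in a sample-design table
DESIGN_COLUMNS = ("sample", "pair", "status")

ANNOTATION_COLUMNS = (
    "metaprobeset",
    "probeset_set",   # 'core' or 'full'
    "region",         # 'exonic' or 'intronic'
    "splice_type",    # 'major' or 'minor' (intronic only; 'na' otherwise)
    "cross_hyb",      # bool
)


class DesignError(ValueError):
    """Sample design violates the paired-design invariants."""


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a design table: each pair has exactly one case and one control."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    if design["sample"].duplicated().any():
        raise DesignError("duplicated sample ids in design")
    bad = set(design["status"].unique()) - {"case", "control"}
    if bad:
        raise DesignError(f"unknown status values: {sorted(bad)}")
    for pair, grp in design.groupby("pair"):
        counts = grp["status"].value_counts()
        if counts.get("case", 0) != 1 or counts.get("control", 0) != 1:
            raise DesignError(
                f"pair {pair!r} must have exactly one case and one control"
            )
    return design


@dataclass
class ExpressionBundle:
    """Probeset and metaprobeset log2 intensities plus design and annotation.

    Attributes
    ----------
    probesets : DataFrame
        Probeset x sample log2 intensities.
    metaprobesets : DataFrame
        Metaprobeset x sample log2 intensities.
    annotation : DataFrame
        Indexed by probeset id; columns :data:`ANNOTATION_COLUMNS`.
    detection : DataFrame
        Boolean probeset x sample detected-above-background calls.
    design : DataFrame
        One row per sample with columns ``sample``, ``pair``, ``status``.
    """

    probesets: pd.DataFrame
    metaprobesets: pd.DataFrame
    annotation: pd.DataFrame
    detection: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        validate_design(self.design)
        samples = list(self.design["sample"])
        for name in ("probesets", "metaprobesets", "detection"):
            table = getattr(self, name)
            if list(table.columns) != samples:
                if set(table.columns) != set(samples):
                    raise DesignError(
                        f"{name} samples do not match design samples"
                    )
                # enforce one common sample ordering
                setattr(self, name, table[samples])
        unknown = self.probesets.index.difference(self.annotation.index)
        if len(unknown):
            raise ValueError(
                f"{len(unknown)} probesets missing from annotation"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.design["sample"])

    @property
    def n_pairs(self) -> int:
        return self.design["pair"].nunique()

    def probeset_to_metaprobeset(self) -> pd.Series:
        return self.annotation["metaprobeset"]

    def select(self, probeset_set: str | None = None,
               region: str | None = None) -> "ExpressionBundle":
        """Restrict to one array tier (core/full) and/or region class."""
        keep = pd.Series(True, index=self.probesets.index)
        ann = self.annotation.loc[self.probesets.index]
        if probeset_set is not None:
            # 'core' probesets are a subset of 'full'
            if probeset_set == "full":
                keep &= ann["probeset_set"].isin(["core", "full"])
            else:
                keep &= ann["probeset_set"] == probeset_set
        if region is not None:
            keep &= ann["region"] == region
        idx = self.probesets.index[keep]
        return self._subset(idx)

    def _subset(self, probeset_ids: pd.Index,
                metaprobeset_ids: pd.Index | None = None) -> "ExpressionBundle":
        ann = self.annotation.loc[probeset_ids]
        if metaprobeset_ids is None:
            metaprobeset_ids = self.metaprobesets.index.intersection(
                pd.Index(ann["metaprobeset"].unique())
            )
        return ExpressionBundle(
            probesets=self.probesets.loc[probeset_ids],
            metaprobesets=self.metaprobesets.loc[metaprobeset_ids],
            annotation=ann,
            detection=self.detection.loc[probeset_ids],
            design=self.design,
        )


@dataclass
class FilterReport:
    """Attrition record for the sequential detection filters."""

    n_input: int = 0
    n_removed_detection: int = 0
    n_removed_cross_hyb: int = 0
    n_removed_metaprobeset_rule: int = 0
    n_metaprobesets_removed: int = 0
    n_output: int = 0
    steps: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_detection": self.n_removed_detection,
            "n_removed_cross_hyb": self.n_removed_cross_hyb,
            "n_removed_metaprobeset_rule": self.n_removed_metaprobeset_rule,
            "n_metaprobesets_removed": self.n_metaprobesets_removed,
            "n_output": self.n_output,
            "steps": list(self.steps),
        }


@dataclass
class InclusionMatrix:
    """Normalized inclusion values ``I[p, s]`` for retained probesets."""

    values: pd.DataFrame
    filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("inclusion matrix contains non-finite values")

    @property
    def probesets(self) -> pd.Index:
        return self.values.index


def apply_detection_filters(
    bundle: ExpressionBundle,
) -> tuple[ExpressionBundle, FilterReport]:
    """Apply the three detection/quality filters, in order.

    1. Drop probesets detected above background in *fewer than half* of the
       samples (a probeset detected in exactly half is retained).
    2. Drop probesets flagged as cross-hybridizing.
    3. Keep only metaprobesets for which at least half of their annotated
       probesets are detected in *all* samples; drop failing metaprobesets
       together with their remaining probesets.  "Annotated probesets"
       counts every probeset of the metaprobeset present in the input
       bundle, before steps 1-2.
    """
    report = FilterReport(n_input=bundle.probesets.shape[0])
    n_samples = len(bundle.samples)
    det = bundle.detection

    # step 1: per-probeset detection rate
    detected_fraction = det.sum(axis=1) / n_samples
    keep1 = detected_fraction >= 0.5
    report.n_removed_detection = int((~keep1).sum())
    report.steps.append("probeset_detection_lt_half")

    # step 2: cross-hybridization flag
    cross = bundle.annotation.loc[det.index, "cross_hyb"].astype(bool)
    keep2 = keep1 & ~cross
    report.n_removed_cross_hyb = int((keep1 & cross).sum())
    report.steps.append("cross_hybridization")

    # step 3: metaprobeset support, counted on the *input* probeset roster
    # (before detection filtering) but excluding cross-hybridizing
    # probesets, which cannot vouch for their metaprobeset
    roster = det.index[~cross]
    all_sample_det = det.loc[roster].all(axis=1)
    meta_of = bundle.annotation.loc[roster, "metaprobeset"]
    n_annotated = meta_of.groupby(meta_of).size()
    n_solid = all_sample_det.groupby(meta_of).sum()
    meta_keep = n_solid.reindex(n_annotated.index, fill_value=0) >= (
        n_annotated / 2.0
    )
    kept_metas = pd.Index(n_annotated.index[meta_keep])
    meta_full = bundle.annotation.loc[det.index, "metaprobeset"]
    keep3 = keep2 & meta_full.isin(kept_metas)
    report.n_removed_metaprobeset_rule = int((keep2 & ~keep3).sum())
    report.n_metaprobesets_removed = int((~meta_keep).sum())
    report.steps.append("metaprobeset_half_in_all_samples")

    kept_probesets = det.index[keep3]
    report.n_output = len(kept_probesets)
    if report.n_output == 0:
        warnings.warn("all probesets removed by detection filters",
                      stacklevel=2)
    kept_meta_index = bundle.metaprobesets.index.intersection(kept_metas)
    filtered = bundle._subset(kept_probesets, kept_meta_index)
    return filtered, report


def compute_inclusion(
    bundle: ExpressionBundle,
    *,
    reverse_sign: bool = False,
    provenance: list[str] | None = None,
) -> InclusionMatrix:
    """Normalize probeset intensities against their metaprobesets.

    Returns ``I[p, s] = X_probeset[p, s] - X_metaprobeset[g(p), s]`` (both on
    the log2 scale, so I is the log2 probeset/metaprobeset ratio).  With
    ``reverse_sign=True`` the subtraction is reversed, matching the opposite
    normalization convention.

    Probesets whose metaprobeset is absent from the bundle are excluded with
    a warning.
    """
    meta_of = bundle.probeset_to_metaprobeset().loc[bundle.probesets.index]
    have_meta = meta_of.isin(bundle.metaprobesets.index)
    if not have_meta.all():
        warnings.warn(
            f"{int((~have_meta).sum())} probesets have no surviving "
            "metaprobeset; excluded from inclusion",
            stacklevel=2,
        )
    probes = bundle.probesets.loc[have_meta[have_meta].index]
    meta_rows = bundle.metaprobesets.loc[
        meta_of.loc[probes.index]
    ].to_numpy(dtype=float)
    values = probes.to_numpy(dtype=float) - meta_rows
    if reverse_sign:
        values = -values
    incl = pd.DataFrame(values, index=probes.index, columns=probes.columns)
    filters = list(provenance) if provenance else []
    filters.append("inclusion=" +
                   ("metaprobeset-probeset" if reverse_sign
                    else "probeset-metaprobeset"))
    return InclusionMatrix(values=incl, filters=filters)
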