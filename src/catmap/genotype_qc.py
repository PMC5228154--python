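"""Sample-level quality control and SNP conversion classification.

Samples are filtered on a per-sample dish-QC (DQC) scalar and their SNP
call rate; both thresholds are strict inequalities ("greater than").  SNPs
are then sorted into six conversion classes from their genotype-call
composition: PolyHighResolution (all three genotype clusters observed),
NoMinorHom (heterozygote plus one homozygote only), MonoHighResolution
(a single cluster), CallRateBelowThreshold, and the intensity-driven OTV
and Other classes, which cannot be derived from calls alone and are only
assigned through explicit simulation flags.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidConfigError
from .simulate.families import GenotypeMatrix

__all__ = [
    "SampleQC",
    "CLASSES",
    "sample_qc",
    "classify_snp_clusters",
    "classify_matrix",
    "ConversionSummary",
    "conversion_summary",
]

CLASSES = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "OTV",
    "CallRateBelowThreshold",
    "Other",
)


@dataclass
class SampleQC:
    sample_id: str
    dqc: float
    call_rate: float
    passed: bool


def sample_qc(
    matrix: GenotypeMatrix,
    dqc_scores: pd.Series,
    dqc_min: float = 0.85,
    cr_min: float = 0.95,
) -> pd.DataFrame:
    """Per-sample pass/fail on DQC > dqc_min and call rate > cr_min."""
    rates = matrix.call_rates()
    rows = []
    for sid in matrix.sample_ids:
        if sid not in dqc_scores.index:
            raise DataError(f"no DQC score for sample {sid}")
        d, cr = float(dqc_scores[sid]), float(rates[sid])
        rows.append(SampleQC(sid, d, cr, d > dqc_min and cr > cr_min))
    df = pd.DataFrame([vars(r) for r in rows]).set_index("sample_id")
    df.attrs["n_passed"] = int(df["passed"].sum())
    df.attrs["pass_rate"] = float(df["passed"].mean()) if len(df) else float("nan")
    return df


def classify_snp_clusters(
    calls: np.ndarray,
    cr_threshold: float = 0.97,
    otv: bool = False,
    other: bool = False,
) -> str:
    """Conversion class for one SNP from its genotype-call vector.

    ``calls`` is coded 0/1/2 with -1 missing.  ``otv``/``other`` are
    simulation-planted flags for the two intensity-space classes.
    """
    calls = np.asarray(calls)
    if calls.size == 0:
        raise DataError("empty call vector")
    if other:
        return "Other"
    if otv:
        return "OTV"
    called = calls[calls >= 0]
    if called.size / calls.size < cr_threshold:
        return "CallRateBelowThreshold"
    present = set(np.unique(called).tolist())
    if present == {0, 1, 2}:
        return "PolyHighResolution"
    if 1 in present and len(present) == 2:
        return "NoMinorHom"
    if len(present) <= 2:  # one or two homozygote clusters, no het
        return "MonoHighResolution" if len(present) == 1 else "PolyHighResolution"
    raise DataError("unreachable genotype composition")  # pragma: no cover


def classify_matrix(
    matrix: GenotypeMatrix,
    cr_threshold: float = 0.97,
    otv_markers: set | None = None,
    other_markers: set | None = None,
    offspring_only: bool = False,
) -> pd.Series:
    """Classify every marker; returns a Series marker_id -> class."""
    otv_markers = otv_markers or set()
    other_markers = other_markers or set()
    rows = matrix.codes
    if offspring_only:
        off = [s for fam in matrix.pedigrees for s in fam.offspring_ids]
        idx = [matrix.sample_ids.index(s) for s in off]
        rows = rows[idx]
    out = {}
    for j, mid in enumerate(matrix.marker_ids):
        out[mid] = classify_snp_clusters(
            rows[:, j], cr_threshold, otv=mid in otv_markers, other=mid in other_markers
        )
    return pd.Series(out, name="class")


@dataclass
class ConversionSummary:
    """Per-class counts with the polymorphic/converted roll-ups.

    polymorphic = PolyHighResolution + NoMinorHom;
    converted = polymorphic + MonoHighResolution.
    Rates are computed against ``total`` (the probe/SNP universe size).
    """

    counts: dict[str, int]
    total: int

    @property
    def polymorphic(self) -> int:
        return self.counts["PolyHighResolution"] + self.counts["NoMinorHom"]

    @property
    def converted(self) -> int:
        return self.polymorphic + self.counts["MonoHighResolution"]

    def rate(self, n: int) -> float:
        return n / self.total if self.total else float("nan")

    def as_dict(self) -> dict:
        d = {**self.counts, "polymorphic": self.polymorphic, "converted": self.converted,
             "total": self.total}
        if self.total:
            d["polymorphic_rate"] = self.rate(self.polymorphic)
            d["converted_rate"] = self.rate(self.converted)
        return d


def conversion_summary(classes: pd.Series | list, total: int | None = None) -> ConversionSummary:
    """Roll a per-SNP class vector up into a ConversionSummary."""
    s = pd.Series(classes)
    bad = set(s.unique()) - set(CLASSES)
    if bad:
        raise InvalidConfigError(f"unknown classes: {sorted(bad)}")
    counts = {c: int((s == c).sum()) for c in CLASSES}
    return ConversionSummary(counts, total if total is not None else len(s))
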