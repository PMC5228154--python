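"""Marker filtering for linkage analysis.

A marker is retained when, in at least ``min_inform_fams`` families, it is
informative (a genotyped parent is heterozygous), its per-family offspring
missing count is at most ``max_missing``, its per-family minor-allele count
is at least ``min_minor`` (a count, roughly 5% of the alleles sampled in a
family of ~120), and the combined segregation-distortion chi-square across
informative families is not significant at ``distortion_p``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import DataError, InvalidConfigError
from ..simulate.families import GenotypeMatrix, Pedigree

__all__ = ["segregation_chi2", "filter_markers", "cross_type"]


def cross_type(sire_code: int, dam_code: int) -> str | None:
    """Mendelian cross type at one marker, or None if uninformative.

    'ABxAA' covers a heterozygous x homozygous cross (1:1 segregation),
    'ABxAB' the double heterozygote (1:2:1).  Missing parents or two
    homozygous parents yield None.
    """
    if sire_code < 0 or dam_code < 0:
        return None
    s_het, d_het = sire_code == 1, dam_code == 1
    if s_het and d_het:
        return "ABxAB"
    if s_het or d_het:
        return "ABxAA"
    return None


def segregation_chi2(observed_counts, cross: str) -> tuple[float, float]:
    """Pearson chi-square of offspring counts against Mendelian ratios.

    ``cross`` is 'ABxAA' (two classes, 1:1) or 'ABxAB' (three classes,
    1:2:1); df = classes - 1.
    """
    obs = np.asarray(observed_counts, dtype=float)
    if obs.sum() == 0:
        raise DataError("all observed counts are zero")
    if cross == "ABxAA":
        if obs.shape != (2,):
            raise InvalidConfigError("ABxAA expects two genotype counts")
        expected = np.full(2, obs.sum() / 2.0)
    elif cross == "ABxAB":
        if obs.shape != (3,):
            raise InvalidConfigError("ABxAB expects three genotype counts")
        expected = obs.sum() * np.array([0.25, 0.5, 0.25])
    else:
        raise InvalidConfigError(f"unknown cross type {cross!r}")
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
    return chi2, p


def _family_counts(codes: np.ndarray, off_rows: np.ndarray, j: int):
    col = codes[off_rows, j]
    called = col[col >= 0]
    n_missing = int((col < 0).sum())
    n0, n1, n2 = int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
    minor = min(2 * n0 + n1, 2 * n2 + n1)  # minor-allele count among offspring alleles
    return n_missing, (n0, n1, n2), minor


def filter_markers(
    matrix: GenotypeMatrix,
    families: list[Pedigree] | None = None,
    max_missing: int = 12,
    min_minor: int = 6,
    min_inform_fams: int = 2,
    distortion_p: float = 0.005,
) -> pd.DataFrame:
    """Per-marker filter verdicts.

    Returns a frame indexed by marker_id with the per-family informative
    count, the combined distortion chi-square and p-value, and ``retained``.
    """
    families = families or matrix.pedigrees
    if not families:
        raise InvalidConfigError("no families given")
    fam_rows = {}
    for fam in families:
        try:
            sire = matrix.row(fam.sire_id)
            dam = matrix.row(fam.dam_id)
        except KeyError as exc:
            raise DataError(f"unknown parent in family {fam.family_id}: {exc}") from exc
        fam_rows[fam.family_id] = (sire, dam, matrix.offspring_rows(fam))

    records = []
    for j, mid in enumerate(matrix.marker_ids):
        n_inform = 0
        chi2_sum = 0.0
        df_sum = 0
        for fam in families:
            sire, dam, off = fam_rows[fam.family_id]
            ct = cross_type(int(sire[j]), int(dam[j]))
            if ct is None:
                continue
            n_missing, (n0, n1, n2), minor = _family_counts(matrix.codes, off, j)
            if n_missing > max_missing or minor < min_minor:
                continue
            if ct == "ABxAA":
                # offspring segregate between the two possible genotypes
                hom_parent = int(dam[j]) if int(sire[j]) == 1 else int(sire[j])
                pair = (n0, n1) if hom_parent == 0 else (n1, n2)
                if sum(pair) == 0:
                    continue
                chi2, _ = segregation_chi2(pair, "ABxAA")
                df = 1
            else:
                if n0 + n1 + n2 == 0:
                    continue
                chi2, _ = segregation_chi2((n0, n1, n2), "ABxAB")
                df = 2
            n_inform += 1
            chi2_sum += chi2
            df_sum += df
        p = float(stats.chi2.sf(chi2_sum, df=df_sum)) if df_sum else float("nan")
        retained = n_inform >= min_inform_fams and (df_sum == 0 or p >= distortion_p)
        records.append(
            {
                "marker_id": mid,
                "n_informative_families": n_inform,
                "distortion_chi2": chi2_sum,
                "distortion_df": df_sum,
                "distortion_pvalue": p,
                "retained": retained,
            }
        )
    return pd.DataFrame(records).set_index("marker_id")
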