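"""Two-point linkage estimation in outbred full-sib families.

Informative meioses are transmissions from a heterozygous parent.  With no
grandparents, the parental linkage phase is a per-family nuisance: the
likelihood is maximised over the (at most four) phase configurations per
family, which is equivalent to maximising over recombination fractions on
[0, 1] per parent and folding onto [0, 0.5].

Two computational paths are provided:

* :func:`estimate_two_point` — exact maximum likelihood for one marker
  pair, using the full two-locus offspring genotype distribution (it
  handles double-heterozygous crosses, where the heterozygous offspring
  class is ambiguous, by summing over the sixteen parental gamete
  combinations).
* :class:`TransmissionTables` + :func:`two_point_matrix` — a vectorised
  all-pairs engine that counts recombinants among *deducible* meioses,
  restricted per marker to families where the co-parent is homozygous
  (the restriction keeps the counting estimator unbiased).  This path
  powers linkage-group formation, where hundreds of thousands of pairwise
  LODs are needed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..errors import UndefinedPairError
from ..simulate.families import GenotypeMatrix, Pedigree

__all__ = [
    "TwoPointResult",
    "TransmissionTables",
    "estimate_two_point",
    "two_point_matrix",
    "pair_lod",
]

_EPS = 1e-9


@dataclass
class TwoPointResult:
    m1: str
    m2: str
    r_female: float
    r_male: float
    r_pooled: float
    lod: float
    n_informative_meioses: int


def _gamete_probs(c1: int, c2: int, r: float) -> np.ndarray | None:
    """Two-locus gamete distribution for a parent with genotype codes c1, c2.

    Returns probabilities over gametes (a1, a2) in order 00, 01, 10, 11
    under coupling phase (the phase flip is handled by r -> 1 - r), or
    None if either genotype is missing.
    """
    if c1 < 0 or c2 < 0:
        return None
    p1 = (1.0, 0.0) if c1 == 0 else (0.0, 1.0) if c1 == 2 else (0.5, 0.5)
    p2 = (1.0, 0.0) if c2 == 0 else (0.0, 1.0) if c2 == 2 else (0.5, 0.5)
    if c1 == 1 and c2 == 1:
        return np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    return np.array([p1[a] * p2[b] for a in (0, 1) for b in (0, 1)])


# consistency tensor: offspring cell (g1, g2) vs dam gamete x sire gamete
_CELLS = [(g1, g2) for g1 in range(3) for g2 in range(3)]
_CONSISTENT = np.zeros((9, 4, 4))
for _ci, (_g1, _g2) in enumerate(_CELLS):
    for _d in range(4):
        for _s in range(4):
            d1, d2 = _d >> 1, _d & 1
            s1, s2 = _s >> 1, _s & 1
            if d1 + s1 == _g1 and d2 + s2 == _g2:
                _CONSISTENT[_ci, _d, _s] = 1.0


def _family_cells(matrix: GenotypeMatrix, fam: Pedigree, i: int, j: int):
    """Joint genotype cell counts for one family at markers i, j."""
    off = matrix.offspring_rows(fam)
    g1 = matrix.codes[off, i]
    g2 = matrix.codes[off, j]
    ok = (g1 >= 0) & (g2 >= 0)
    counts = np.zeros(9)
    np.add.at(counts, (g1[ok] * 3 + g2[ok]).astype(int), 1.0)
    sire = (int(matrix.row(fam.sire_id)[i]), int(matrix.row(fam.sire_id)[j]))
    dam = (int(matrix.row(fam.dam_id)[i]), int(matrix.row(fam.dam_id)[j]))
    return counts, dam, sire


def _gamete_probs_batch(c1: int, c2: int, r: np.ndarray) -> np.ndarray | None:
    """Vectorised gamete distribution over a vector of r values: (G, 4)."""
    if c1 < 0 or c2 < 0:
        return None
    G = len(r)
    if c1 == 1 and c2 == 1:
        return np.stack([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2], axis=1)
    base = _gamete_probs(c1, c2, 0.0)
    return np.broadcast_to(base, (G, 4))


_CHANNEL_CACHE: dict[float, np.ndarray] = {}


def _consistency_with_error(e: float) -> np.ndarray:
    """Consistency tensor with the misclassification channel folded in."""
    if e <= 0:
        return _CONSISTENT
    key = round(float(e), 10)
    if key not in _CHANNEL_CACHE:
        E = _error_channel(e)
        # cell_obs = E.T @ cell_true @ E applied to the (g1, g2) table
        C = _CONSISTENT.reshape(3, 3, 4, 4)
        Ct = np.einsum("ab,bcds,cf->afds", E.T, C, E).reshape(9, 4, 4)
        _CHANNEL_CACHE[key] = Ct
    return _CHANNEL_CACHE[key]


def _family_loglik_batch(counts, dam, sire, r_f, r_m, e: float = 0.0) -> np.ndarray:
    """Phase-maximised family log-likelihood over grids of (r_f, r_m)."""
    G = len(r_f)
    best = np.full(G, -np.inf)
    dam_flips = (False, True) if dam[0] == 1 and dam[1] == 1 else (False,)
    sire_flips = (False, True) if sire[0] == 1 and sire[1] == 1 else (False,)
    Ct = _consistency_with_error(e)
    T = Ct.reshape(36, 4)
    nz = counts > 0
    for df in dam_flips:
        pd_ = _gamete_probs_batch(dam[0], dam[1], 1 - r_f if df else r_f)
        if pd_ is None:
            continue
        for sf in sire_flips:
            ps = _gamete_probs_batch(sire[0], sire[1], 1 - r_m if sf else r_m)
            if ps is None:
                continue
            Y = (ps @ T.T).reshape(G, 9, 4)
            cell = (Y * pd_[:, None, :]).sum(axis=2)
            with np.errstate(divide="ignore"):
                ll = (
                    counts[None, nz] * np.log(np.maximum(cell[:, nz], 1e-300))
                ).sum(axis=1)
            best = np.maximum(best, ll)
    return best


def _error_channel(e: float) -> np.ndarray:
    """Genotype misclassification matrix: true (rows) -> observed (cols).

    With probability ``e`` a call is replaced by one of the other two
    genotypes uniformly.
    """
    return np.full((3, 3), e / 2.0) + np.eye(3) * (1.0 - 1.5 * e)


def _family_loglik(counts, dam, sire, r_f: float, r_m: float, e: float = 0.0) -> float:
    """Max over phase configurations of the family log-likelihood."""
    best = -np.inf
    dam_flips = (False, True) if dam[0] == 1 and dam[1] == 1 else (False,)
    sire_flips = (False, True) if sire[0] == 1 and sire[1] == 1 else (False,)
    E = _error_channel(e) if e > 0 else None
    for df in dam_flips:
        pd_ = _gamete_probs(dam[0], dam[1], 1 - r_f if df else r_f)
        if pd_ is None:
            continue
        for sf in sire_flips:
            ps = _gamete_probs(sire[0], sire[1], 1 - r_m if sf else r_m)
            if ps is None:
                continue
            cell_p = np.einsum("cds,d,s->c", _CONSISTENT, pd_, ps)
            if E is not None:
                cell_p = (E.T @ cell_p.reshape(3, 3) @ E).reshape(9)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.sum(counts * np.log(np.maximum(cell_p, 1e-300))))
            best = max(best, ll)
    return best


def estimate_two_point(
    matrix: GenotypeMatrix,
    m1: str,
    m2: str,
    families: list[Pedigree] | None = None,
    error_rate: float = 0.0,
) -> TwoPointResult:
    """Maximum-likelihood two-point estimate for one marker pair.

    Sex-specific recombination fractions are estimated jointly across
    families (dam meioses -> female, sire meioses -> male); LOD is the
    log10 likelihood ratio against independence (r = 0.5 in both sexes).
    A nonzero ``error_rate`` folds a uniform genotype-misclassification
    channel into the cell probabilities, de-biasing the estimate on
    error-bearing data.
    """
    families = families or matrix.pedigrees
    i = matrix.marker_positions([m1])[0]
    j = matrix.marker_positions([m2])[0]
    fam_data = []
    n_meioses = 0
    any_female = any_male = False
    for fam in families:
        counts, dam, sire = _family_cells(matrix, fam, i, j)
        dam_inf = dam[0] == 1 and dam[1] == 1
        sire_inf = sire[0] == 1 and sire[1] == 1
        if not (dam_inf or sire_inf) or counts.sum() == 0:
            continue
        n_meioses += int(counts.sum()) * (int(dam_inf) + int(sire_inf))
        any_female |= dam_inf
        any_male |= sire_inf
        fam_data.append((counts, dam, sire))
    if not fam_data:
        raise UndefinedPairError(f"no informative meioses for pair ({m1}, {m2})")

    def negll(params) -> float:
        r_f = float(np.clip(params[0], _EPS, 0.5))
        r_m = float(np.clip(params[1], _EPS, 0.5))
        return -sum(
            _family_loglik(c, d, s, r_f, r_m, error_rate) for c, d, s in fam_data
        )

    # coarse grid start, then local refinement
    grid = np.linspace(_EPS, 0.5, 11)
    best_start, best_val = (0.25, 0.25), np.inf
    for rf in grid if any_female else [0.5]:
        for rm in grid if any_male else [0.5]:
            v = negll((rf, rm))
            if v < best_val:
                best_val, best_start = v, (rf, rm)
    res = minimize(
        negll, best_start, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
    )
    r_f = float(np.clip(res.x[0], 0.0, 0.5)) if any_female else 0.5
    r_m = float(np.clip(res.x[1], 0.0, 0.5)) if any_male else 0.5
    ll_hat = -negll(res.x)
    ll_null = -negll((0.5, 0.5))
    lod = (ll_hat - ll_null) / np.log(10.0)
    n_f = sum(int(c.sum()) for c, d, s in fam_data if d[0] == 1 and d[1] == 1)
    n_m = sum(int(c.sum()) for c, d, s in fam_data if s[0] == 1 and s[1] == 1)
    denom = n_f + n_m
    r_pooled = (n_f * r_f + n_m * r_m) / denom if denom else float("nan")
    return TwoPointResult(m1, m2, r_f, r_m, r_pooled, float(lod), n_meioses)


class TransmissionTables:
    """Deducible parental transmissions for the vectorised engine.

    For each (family, parent role) two offspring x marker arrays of
    transmitted alleles (0/1, NaN where not deducible) are stored:

    ``full``   — every deducible transmission: co-parent homozygous (all
                 non-missing Mendelian-consistent offspring), or co-parent
                 heterozygous with a homozygous offspring.
    ``strict`` — restricted to markers where the co-parent is homozygous.

    The strict table keeps the pairwise recombinant-counting estimator
    unbiased (in double-heterozygous crosses, conditioning on a homozygous
    offspring couples the two parents' gametes and shrinks the apparent
    recombination fraction for linked pairs).  The full table maximises
    the informative meiosis count; it is used where sensitivity matters
    more than unbiasedness — pairwise LOD screening for group formation
    and the ordering distance proxy — because it is exact under the null
    (r = 0.5) and only overstates linkage for truly linked pairs.
    """

    def __init__(self, matrix: GenotypeMatrix, families: list[Pedigree] | None = None):
        self.matrix = matrix
        self.families = families or matrix.pedigrees
        self.tables: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        for fam in self.families:
            sire = matrix.row(fam.sire_id).astype(int)
            dam = matrix.row(fam.dam_id).astype(int)
            off = matrix.codes[matrix.offspring_rows(fam)].astype(float)
            off[off < 0] = np.nan
            for role, parent, other in (("dam", dam, sire), ("sire", sire, dam)):
                het = parent == 1
                other_hom = (other == 0) | (other == 2)
                other_het = other == 1
                # co-parent hom 0: transmitted = g (g in {0,1}); hom 2: g - 1
                T_hom = off - np.where(other == 2, 1.0, 0.0)[None, :]
                T_hom[(T_hom != 0.0) & (T_hom != 1.0)] = np.nan
                T_hom[:, ~(het & other_hom)] = np.nan
                # co-parent het: homozygous offspring reveal both gametes
                T_het = np.where(off == 0.0, 0.0, np.where(off == 2.0, 1.0, np.nan))
                T_het[:, ~(het & other_het)] = np.nan
                T_full = np.where(np.isnan(T_hom), T_het, T_hom)
                self.tables.append((fam.family_id, role, T_full, het & other_hom))

    def strict_table(self, T_full: np.ndarray, strict_cols: np.ndarray) -> np.ndarray:
        T = T_full.copy()
        T[:, ~strict_cols] = np.nan
        return T

    def informativeness(self) -> np.ndarray:
        """Per-marker count of deducible meioses (all family-parents)."""
        n = self.matrix.n_markers
        out = np.zeros(n)
        for _, _, T, _ in self.tables:
            out += np.sum(~np.isnan(T), axis=0)
        return out


def two_point_matrix(tables: TransmissionTables, marker_idx: np.ndarray | None = None):
    """All-pairs recombination counts and LODs.

    Returns a dict of (k x k) arrays for the selected markers: ``N``,
    ``R``, ``r`` and ``lod`` from the full transmission tables (the
    sensitive screening path), plus strict per-sex counts ``N_f``/``R_f``
    (dam meioses) and ``N_m``/``R_m`` (sire) for unbiased estimation.
    Phase is resolved per family-parent (recombinant class = minority).
    """
    if marker_idx is None:
        marker_idx = np.arange(tables.matrix.n_markers)
    k = len(marker_idx)
    acc = {
        "N_f": np.zeros((k, k)), "R_f": np.zeros((k, k)),
        "N_m": np.zeros((k, k)), "R_m": np.zeros((k, k)),
    }
    lod = np.zeros((k, k))
    N_tot = np.zeros((k, k))
    R_tot = np.zeros((k, k))
    per_fp = []

    def counts(T: np.ndarray):
        M = (~np.isnan(T)).astype(np.float64)
        A = np.nan_to_num(T, nan=0.0)
        N = M.T @ M
        S = A.T @ M + M.T @ A - 2.0 * (A.T @ A)  # discordant transmissions
        return N, np.minimum(S, N - S)  # per-family phase: minority class

    for _, role, T_full, strict_cols in tables.tables:
        N, R = counts(T_full[:, marker_idx])
        N_tot += N
        R_tot += R
        per_fp.append((N, R))
        Ns, Rs = counts(tables.strict_table(T_full, strict_cols)[:, marker_idx])
        key = "f" if role == "dam" else "m"
        acc[f"N_{key}"] += Ns
        acc[f"R_{key}"] += Rs
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(N_tot > 0, R_tot / np.maximum(N_tot, 1.0), np.nan)
    r_safe = np.clip(np.nan_to_num(r, nan=0.5), 1e-6, 0.5)
    for N, R in per_fp:
        lod += (
            N * np.log10(2.0)
            + R * np.log10(r_safe)
            + (N - R) * np.log10(1.0 - r_safe)
        )
    lod[N_tot == 0] = 0.0
    np.fill_diagonal(lod, 0.0)
    return {**acc, "N": N_tot, "R": R_tot, "r": r, "lod": lod, "marker_idx": marker_idx}


def pair_lod(n: int, n_rec: int, r_hat: float | None = None) -> float:
    """Closed-form LOD for phase-known counts (n meioses, n_rec recombinants)."""
    if n == 0:
        return 0.0
    r = n_rec / n if r_hat is None else r_hat
    r = min(max(r, 0.0), 0.5)
    lod = n * np.log10(2.0)
    if n_rec > 0:
        lod += n_rec * np.log10(max(r, 1e-300))
    if n_rec < n:
        lod += (n - n_rec) * np.log10(1.0 - r)
    return float(lod)
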