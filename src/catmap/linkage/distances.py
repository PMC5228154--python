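"""Genetic distances along an ordered linkage group.

Pairwise recombination fractions between nearby markers are fitted by
two-locus maximum likelihood over the sex-specific fractions (dam meioses
give the female fraction, sire meioses the male one), with parental phase
maximised per family and a uniform genotype-misclassification channel
folded into the cell probabilities.  Without the error channel,
genotyping errors mimic double crossovers and inflate every interval;
modelling it makes the estimates consistent on error-bearing data.  The
misclassification rate is itself estimated from the data, from the rate
of Mendelian-impossible offspring calls in crosses that expose them.

Final positions are *not* a plain cumulative sum of adjacent-interval
estimates: at realistic densities the adjacent fractions sit at the
resolution limit of the cross, and summing ~200 noisy, zero-truncated
intervals (along an order that is itself uncertain between near-stacked
markers) inflates the map length severely — the familiar map-expansion
problem.  Instead, each marker is placed on the line by weighted
least-squares against the Kosambi distances to all markers within a
sliding order window (a banded multipoint placement); the per-sex
coordinates are then projected onto the shared marker order by isotonic
regression, which yields monotone non-negative increments and lets
sexes without information in some interval borrow placement from
longer-range pairs.

Sex-average fractions are the meiosis-count-weighted mean of the two sex
fractions.  The female-male contrast per group is a likelihood-ratio
G-test on the 2x2 table of recombinant vs non-recombinant deducible
meioses by sex.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from ..errors import DataError
from ..simulate.families import GenotypeMatrix, Pedigree
from .mapfun import kosambi, kosambi_inverse
from .twopoint import TransmissionTables, _family_cells, _family_loglik_batch

__all__ = [
    "interval_counts",
    "estimate_error_rate",
    "fit_interval",
    "isotonic_fit",
    "compute_map_distances",
    "g_test_2x2",
    "sex_difference_gtest",
]

_R_CAP = 0.4999
# coarse search grids, denser near zero where linked pairs live
_R_GRID = np.array(
    [0.001, 0.004, 0.008, 0.014, 0.022, 0.032, 0.045, 0.065, 0.09,
     0.12, 0.16, 0.21, 0.27, 0.34, 0.42, 0.499]
)
_R_GRID_FINE = np.concatenate([_R_GRID, (_R_GRID[:-1] + _R_GRID[1:]) / 2.0])


def interval_counts(
    tables: TransmissionTables, order_idx: np.ndarray, strict: bool = False
) -> pd.DataFrame:
    """Deducible recombinant counts per adjacent interval, split by sex.

    By default every deducible transmission is counted (maximising the
    meiosis count for the sex-contrast test); ``strict`` restricts to
    co-parent-homozygous transmissions, whose counts are unbiased.  Phase
    is resolved per family-parent and interval (minority class =
    recombinant).  One row per interval: N_f, R_f, N_m, R_m.
    """
    k = len(order_idx)
    if k < 2:
        return pd.DataFrame(columns=["N_f", "R_f", "N_m", "R_m"])
    N = {"f": np.zeros(k - 1), "m": np.zeros(k - 1)}
    R = {"f": np.zeros(k - 1), "m": np.zeros(k - 1)}
    for _, role, T_full, strict_cols in tables.tables:
        key = "f" if role == "dam" else "m"
        T = tables.strict_table(T_full, strict_cols) if strict else T_full
        Tk = T[:, order_idx]
        left, right = Tk[:, :-1], Tk[:, 1:]
        ok = ~np.isnan(left) & ~np.isnan(right)
        disc = (left != right) & ok
        n = ok.sum(axis=0).astype(float)
        s = disc.sum(axis=0).astype(float)
        N[key] += n
        R[key] += np.minimum(s, n - s)
    return pd.DataFrame({"N_f": N["f"], "R_f": R["f"], "N_m": N["m"], "R_m": R["m"]})


def estimate_error_rate(matrix: GenotypeMatrix, families: list[Pedigree] | None = None) -> float:
    """Global genotype-misclassification rate from impossible calls.

    Counts offspring genotypes that are Mendelian-impossible given the
    parents (the co-parent homozygote class in het x hom crosses, any
    non-expected class in hom x hom crosses) and inverts their expected
    rates under the uniform misclassification channel.
    """
    families = families or matrix.pedigrees
    n_imp = 0.0
    weight = 0.0
    for fam in families:
        sire = matrix.row(fam.sire_id).astype(int)
        dam = matrix.row(fam.dam_id).astype(int)
        off = matrix.codes[matrix.offspring_rows(fam)]
        called = off >= 0
        n_called = called.sum(axis=0).astype(float)
        for mask, imp_counts, coeff in _impossible_specs(sire, dam, off, called):
            n_imp += float(imp_counts[mask].sum())
            weight += float(coeff * n_called[mask].sum())
    return float(np.clip(n_imp / weight, 0.0, 0.5)) if weight > 0 else 0.0


def _impossible_specs(sire, dam, off, called):
    """(marker mask, per-marker impossible-call counts, e-coefficient)."""
    s_het, d_het = sire == 1, dam == 1
    s_hom, d_hom = (sire == 0) | (sire == 2), (dam == 0) | (dam == 2)
    out = []
    # het x hom: the homozygote opposite the hom parent is impossible (e/2)
    for het, hom, hom_code in ((s_het, d_hom, dam), (d_het, s_hom, sire)):
        mask = het & hom
        impossible_code = np.where(hom_code == 0, 2, 0)
        imp = ((off == impossible_code[None, :]) & called).sum(axis=0).astype(float)
        out.append((mask, imp, 0.5))
    # hom x hom same allele: only that homozygote is possible (rate e)
    same = s_hom & d_hom & (sire == dam)
    imp_same = ((off != sire[None, :]) & called).sum(axis=0).astype(float)
    out.append((same, imp_same, 1.0))
    # hom x hom different alleles: only the heterozygote is possible (rate e)
    diff = s_hom & d_hom & (sire != dam)
    imp_diff = ((off != 1) & called).sum(axis=0).astype(float)
    out.append((diff, imp_diff, 1.0))
    return out


def fit_interval(
    matrix: GenotypeMatrix,
    families: list[Pedigree],
    i: int,
    j: int,
    error_rate: float = 0.0,
) -> tuple[float, float, int, int]:
    """ML recombination fractions (female, male) for one marker pair.

    Returns (r_f, r_m, n_f, n_m) where n_f/n_m count meioses from parents
    heterozygous at both markers.  A sex with no informative meioses
    returns NaN for its fraction.
    """
    fam_data = []
    n_f = n_m = 0
    for fam in families:
        counts, dam, sire = _family_cells(matrix, fam, i, j)
        dam_inf = dam[0] == 1 and dam[1] == 1
        sire_inf = sire[0] == 1 and sire[1] == 1
        if not (dam_inf or sire_inf) or counts.sum() == 0:
            continue
        n_f += int(counts.sum()) if dam_inf else 0
        n_m += int(counts.sum()) if sire_inf else 0
        fam_data.append((counts, dam, sire))
    if not fam_data:
        return float("nan"), float("nan"), 0, 0

    # vectorised coarse grid: the phase maximisation makes the surface
    # multimodal, so local search alone is unreliable
    grid = _R_GRID if n_f and n_m else _R_GRID_FINE
    if n_f and n_m:
        gf, gm = np.meshgrid(grid, grid, indexing="ij")
        rf_vec, rm_vec = gf.ravel(), gm.ravel()
    elif n_f:
        rf_vec, rm_vec = grid, np.full_like(grid, 0.25)
    else:
        rf_vec, rm_vec = np.full_like(grid, 0.25), grid
    ll = np.zeros(len(rf_vec))
    for c, d, s in fam_data:
        ll += _family_loglik_batch(c, d, s, rf_vec, rm_vec, error_rate)
    best = int(np.argmax(ll))
    r_f, r_m = float(rf_vec[best]), float(rm_vec[best])

    # two vectorised zoom rounds around the coarse optimum
    step_f = step_m = 0.03
    for _ in range(2):
        gf = np.clip(r_f + np.linspace(-step_f, step_f, 9), 1e-9, 0.5) if n_f else np.array([r_f])
        gm = np.clip(r_m + np.linspace(-step_m, step_m, 9), 1e-9, 0.5) if n_m else np.array([r_m])
        mf, mm = np.meshgrid(gf, gm, indexing="ij")
        rf_vec, rm_vec = mf.ravel(), mm.ravel()
        ll = np.zeros(len(rf_vec))
        for c, d, s in fam_data:
            ll += _family_loglik_batch(c, d, s, rf_vec, rm_vec, error_rate)
        best = int(np.argmax(ll))
        r_f, r_m = float(rf_vec[best]), float(rm_vec[best])
        step_f *= 0.12
        step_m *= 0.12
    return (
        r_f if n_f else float("nan"),
        r_m if n_m else float("nan"),
        n_f,
        n_m,
    )


def isotonic_fit(y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Weighted isotonic (non-decreasing) regression by pool-adjacent-violators."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    blocks = [[y[i] * w[i], w[i], 1] for i in range(len(y))]  # sum, weight, count
    merged: list[list[float]] = []
    for b in blocks:
        merged.append(list(b))
        while len(merged) > 1 and (
            merged[-2][0] / max(merged[-2][1], 1e-300)
            > merged[-1][0] / max(merged[-1][1], 1e-300)
        ):
            s2, w2, c2 = merged.pop()
            merged[-1][0] += s2
            merged[-1][1] += w2
            merged[-1][2] += c2
    out = np.empty_like(y)
    pos = 0
    for s, wt, c in merged:
        out[pos : pos + int(c)] = s / max(wt, 1e-300)
        pos += int(c)
    return out


def count_crossovers(tables: TransmissionTables, order_idx: np.ndarray) -> dict:
    """Crossover counts per sex along an ordered marker set.

    For every meiosis the deducible transmission sequence is scanned;
    single-marker haplotype blips (a value differing from both deducible
    neighbours, or a discordant end marker) are attributed to genotyping
    error and removed, and the remaining haplotype switches are counted
    as crossovers.  Each meiosis contributes an effective coverage weight
    (span of its deducible markers as a fraction of the group), so the
    returned lengths are per-meiosis crossover rates in cM:

        L_sex = 100 * total crossovers / total effective meioses.

    This event-counting estimator approaches the Poisson sampling bound
    of the realised crossover process and is far less noisy than summing
    per-interval recombination-fraction estimates.
    """
    k = len(order_idx)
    tallies = {"f": [0.0, 0.0], "m": [0.0, 0.0]}  # crossovers, effective meioses
    for _, role, T_full, _ in tables.tables:
        key = "f" if role == "dam" else "m"
        Tk = T_full[:, order_idx].copy()
        # resolve the parent's linkage phase along the group: align each
        # informative marker with its predecessor so that recombinant
        # transmissions are the minority class, then XOR the alleles into
        # haplotype-origin indicators
        inform = np.flatnonzero(~np.isnan(Tk).all(axis=0))
        last = np.full(Tk.shape[0], np.nan)
        for col in inform:
            cur = Tk[:, col]
            ok = ~np.isnan(cur) & ~np.isnan(last)
            s = int(((cur != last) & ok).sum())
            if s * 2 > int(ok.sum()):
                Tk[:, col] = 1.0 - cur
                cur = Tk[:, col]
            last = np.where(~np.isnan(cur), cur, last)
        for row in Tk:
            idx = np.flatnonzero(~np.isnan(row))
            if len(idx) < 3 or k < 2:
                continue
            s = row[idx]
            keep = np.ones(len(s), dtype=bool)
            interior = (s[1:-1] != s[:-2]) & (s[1:-1] != s[2:])
            keep[1:-1] = ~interior
            if s[0] != s[1]:
                keep[0] = False
            if s[-1] != s[-2]:
                keep[-1] = False
            s2 = s[keep]
            if len(s2) < 2:
                continue
            crossovers = float(np.sum(np.diff(s2) != 0))
            span = (idx[-1] - idx[0]) / (k - 1)
            tallies[key][0] += crossovers
            tallies[key][1] += span
    out = {}
    for key, (c, m) in tallies.items():
        out[f"crossovers_{key}"] = c
        out[f"meioses_{key}"] = m
        out[f"length_{key}"] = 100.0 * c / m if m > 0 else float("nan")
    denom = tallies["f"][1] + tallies["m"][1]
    out["length_avg"] = (
        100.0 * (tallies["f"][0] + tallies["m"][0]) / denom if denom > 0 else float("nan")
    )
    return out


def _segment_arrangement(d_end, n_seg):
    """Best path over segments with orientations; exhaustive for small counts.

    ``d_end[a, oa, b, ob]`` is the junction distance when segment ``a`` in
    orientation ``oa`` is followed by segment ``b`` in orientation ``ob``.
    Returns (permutation, orientations).
    """
    from itertools import permutations, product

    best, best_cost = None, np.inf
    for perm in permutations(range(n_seg)):
        if perm[0] > perm[-1]:
            continue
        for orient in product((0, 1), repeat=n_seg):
            cost = 0.0
            for a, b in zip(perm, perm[1:]):
                cost += d_end[a, orient[perm.index(a)], b, orient[perm.index(b)]]
                if cost >= best_cost:
                    break
            if cost < best_cost:
                best_cost, best = cost, (list(perm), list(orient))
    return best


def _repair_segments(order, adj_d, matrix, families, order_idx, error_rate,
                     max_segments=7, jump_factor=5.0, jump_floor=12.0):
    """Re-arrange grossly misplaced order segments.

    The seriation can fold a chromosome-end segment into the interior,
    beyond the banded window's reach.  Junctions whose fitted adjacent
    distance exceeds max(jump_floor, jump_factor * median) split the order
    into segments; the segments are re-assembled (with orientation) by
    exhaustive search over their endpoint-to-endpoint ML distances.
    Returns the repaired order (list of local indices) or None.
    """
    finite = adj_d[np.isfinite(adj_d)]
    if len(finite) < 3:
        return None
    cut = max(jump_floor, jump_factor * float(np.median(finite)))
    junctions = [t for t in range(len(adj_d)) if np.isfinite(adj_d[t]) and adj_d[t] > cut]
    if not junctions:
        return None
    bounds = [0] + [t + 1 for t in junctions] + [len(order)]
    segments = [order[a:b] for a, b in zip(bounds, bounds[1:])]
    n_seg = len(segments)
    if n_seg < 2 or n_seg > max_segments:
        return None

    def endpoint(seg, orient, which):
        s = seg if orient == 0 else seg[::-1]
        return s[-1] if which == "tail" else s[0]

    d_end = np.full((n_seg, 2, n_seg, 2), 300.0)
    cache: dict[tuple[int, int], float] = {}

    def pair_d(a, b):
        key = (min(a, b), max(a, b))
        if key not in cache:
            rf, rm, nf, nm = fit_interval(
                matrix, families, order_idx[key[0]], order_idx[key[1]], error_rate
            )
            tot = nf + nm
            if tot == 0:
                cache[key] = 300.0
            else:
                r = (np.nan_to_num(rf) * nf + np.nan_to_num(rm) * nm) / tot
                cache[key] = float(kosambi(min(max(r, 0.0), _R_CAP)))
        return cache[key]

    for a in range(n_seg):
        for b in range(n_seg):
            if a == b:
                continue
            for oa in (0, 1):
                for ob in (0, 1):
                    d_end[a, oa, b, ob] = pair_d(
                        endpoint(segments[a], oa, "tail"), endpoint(segments[b], ob, "head")
                    )
    best = _segment_arrangement(d_end, n_seg)
    if best is None:
        return None
    perm, orient = best
    if perm == list(range(n_seg)) and all(o == 0 for o in orient):
        return None
    identity_cost = sum(d_end[a, 0, a + 1, 0] for a in range(n_seg - 1))
    best_cost = sum(
        d_end[a, orient[perm.index(a)], b, orient[perm.index(b)]]
        for a, b in zip(perm, perm[1:])
    )
    if best_cost > identity_cost - 10.0:  # demand a decisive improvement
        return None
    repaired: list[int] = []
    for pos, seg_i in enumerate(perm):
        seg = segments[seg_i]
        repaired.extend(seg if orient[pos] == 0 else seg[::-1])
    return repaired


def _banded_fits(matrix, families, order_idx, window, error_rate):
    """ML fits for all pairs within ``window`` order positions."""
    k = len(order_idx)
    shape = (k, k)
    r_f = np.full(shape, np.nan)
    r_m = np.full(shape, np.nan)
    n_f = np.zeros(shape)
    n_m = np.zeros(shape)
    for a in range(k):
        for b in range(a + 1, min(a + window + 1, k)):
            rf, rm, nf, nm = fit_interval(
                matrix, families, order_idx[a], order_idx[b], error_rate
            )
            r_f[a, b] = r_f[b, a] = rf
            r_m[a, b] = r_m[b, a] = rm
            n_f[a, b] = n_f[b, a] = nf
            n_m[a, b] = n_m[b, a] = nm
    return r_f, r_m, n_f, n_m


def _embed(d: np.ndarray, w: np.ndarray, x0: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """1-D weighted LS placement: minimise sum w_ij (|x_i-x_j| - d_ij)^2.

    With the sign pattern s_ij = sign(x_i - x_j) held fixed the objective
    is an ordinary weighted least squares whose normal equations form a
    graph Laplacian system, solved exactly; a few outer iterations update
    the signs from the previous solution.  Rank ties in ``x0`` break by
    index so the system stays consistent.
    """
    n = len(x0)
    if n == 1:
        return np.zeros(1)
    wm = np.where(np.isfinite(d), w, 0.0)
    np.fill_diagonal(wm, 0.0)
    dm = np.nan_to_num(d, nan=0.0)
    rank = np.argsort(np.argsort(x0, kind="stable"))
    x = x0.astype(float).copy()
    prev_sign = np.sign(np.subtract.outer(rank, rank)).astype(float)
    for _ in range(n_iter):
        s = np.sign(np.subtract.outer(x, x))
        s = np.where(s == 0, prev_sign, s)
        prev_sign = s
        L = np.diag(wm.sum(axis=1)) - wm
        b = (wm * s * dm).sum(axis=1)
        # pin the translation mode; the tiny ridge anchors any component
        # that is disconnected in this weight graph near its start value
        eps = 1e-6 * max(float(wm.sum()) / n, 1.0)
        L_reg = L + np.full((n, n), 1.0 / n) + eps * np.eye(n)
        x = np.linalg.solve(L_reg, b + eps * x0)
    return x - x.min()


def compute_map_distances(
    tables: TransmissionTables,
    ordered_markers: list[str],
    error_rate: float | None = None,
    method: str = "embedding",
    window: int = 8,
) -> pd.DataFrame:
    """cM positions (sex-average, female, male) along an ordered group.

    ``error_rate`` None means estimate it from Mendelian-impossible calls;
    pass 0.0 to disable the error channel.  ``method`` 'embedding' (the
    default) places markers by banded weighted least squares and may
    locally refine the input order; 'adjacent' accumulates per-interval
    estimates exactly in the given order.  Intervals without informative
    meioses in a sex inherit a zero gap (with a warning under the
    'adjacent' method).  Returns one row per marker in final order; the
    per-interval table is attached as ``df.attrs['intervals']``.
    """
    matrix = tables.matrix
    families = tables.families
    k = len(ordered_markers)
    if k == 0:
        raise DataError("empty marker order")
    if error_rate is None:
        error_rate = estimate_error_rate(matrix, families)
    order_idx = matrix.marker_positions(ordered_markers)

    if method == "adjacent" or k <= 3:
        return _adjacent_path(tables, list(ordered_markers), order_idx, error_rate)
    if method != "embedding":
        raise DataError(f"unknown method {method!r}")

    def cumulative_adjacent(d):
        adj = np.nan_to_num(np.diagonal(d, offset=1), nan=0.0)
        return np.concatenate([[0.0], np.cumsum(adj)])

    def dist(r):
        return np.where(np.isfinite(r), kosambi(np.clip(np.nan_to_num(r), 0, _R_CAP)), np.nan)

    markers = list(ordered_markers)
    for _attempt in range(2):
        order_idx = matrix.marker_positions(markers)
        r_f, r_m, n_f, n_m = _banded_fits(matrix, families, order_idx, window, error_rate)
        n_tot = n_f + n_m
        with np.errstate(invalid="ignore"):
            r_avg = (
                np.nan_to_num(r_f) * n_f + np.nan_to_num(r_m) * n_m
            ) / np.maximum(n_tot, 1e-12)
        r_avg[n_tot == 0] = np.nan
        d_avg, d_f, d_m = dist(r_avg), dist(r_f), dist(r_m)

        # round 1: embed from the (possibly jittered) input order, reorder
        x_avg = _embed(d_avg, n_tot, cumulative_adjacent(d_avg))
        final = np.argsort(x_avg, kind="stable")
        if list(final) != list(range(k)):
            markers = [markers[i] for i in final]
            order_idx = order_idx[final]
            perm = np.ix_(final, final)
            d_avg, d_f, d_m = d_avg[perm], d_f[perm], d_m[perm]
            n_f, n_m, n_tot = n_f[perm], n_m[perm], n_tot[perm]
            # round 2: re-embed from the cleaner cumulative-adjacent start
            x_avg = _embed(d_avg, n_tot, cumulative_adjacent(d_avg))
            resort = np.argsort(x_avg, kind="stable")
            markers = [markers[i] for i in resort]
            order_idx = order_idx[resort]
            perm = np.ix_(resort, resort)
            d_avg, d_f, d_m = d_avg[perm], d_f[perm], d_m[perm]
            n_f, n_m, n_tot = n_f[perm], n_m[perm], n_tot[perm]
            x_avg = x_avg[resort]
        # gross-misplacement repair: re-arrange segments split at outsized
        # adjacent distances, then refit from scratch
        repaired = _repair_segments(
            list(range(k)), np.diagonal(d_avg, offset=1), matrix, families,
            order_idx, error_rate,
        )
        if repaired is None:
            break
        markers = [markers[i] for i in repaired]
    if k > 1 and order_idx[0] > order_idx[-1]:  # canonical orientation
        markers = markers[::-1]
        order_idx = order_idx[::-1]
        flip = np.ix_(range(k - 1, -1, -1), range(k - 1, -1, -1))
        d_avg, d_f, d_m = d_avg[flip], d_f[flip], d_m[flip]
        n_f, n_m, n_tot = n_f[flip], n_m[flip], n_tot[flip]
        x_avg = x_avg.max() - x_avg[::-1]
    ordered = list(markers)

    pos_avg = isotonic_fit(x_avg, np.maximum(n_tot.sum(axis=1), 1e-9))
    pos_avg -= pos_avg[0]
    x_f = _embed(d_f, n_f, cumulative_adjacent(d_f))
    x_m = _embed(d_m, n_m, cumulative_adjacent(d_m))
    pos_f = isotonic_fit(x_f, np.maximum(n_f.sum(axis=1), 1e-9))
    pos_m = isotonic_fit(x_m, np.maximum(n_m.sum(axis=1), 1e-9))
    pos_f -= pos_f[0]
    pos_m -= pos_m[0]
    # total lengths come from the crossover-event counts, the efficient
    # estimator; the embedded/isotonic coordinates provide the relative
    # placement and are rescaled to those totals
    xo = count_crossovers(tables, order_idx)
    for key, pos in (("length_f", pos_f), ("length_m", pos_m), ("length_avg", pos_avg)):
        total = xo[key if key != "length_avg" else "length_avg"]
        if np.isfinite(total) and pos[-1] > 0:
            pos *= total / pos[-1]

    counts = interval_counts(tables, order_idx)
    df = pd.DataFrame(
        {
            "marker_id": ordered,
            "cM_avg": pos_avg,
            "cM_female": pos_f,
            "cM_male": pos_m,
        }
    )
    adj_f = np.diagonal(d_f, offset=1)
    adj_m = np.diagonal(d_m, offset=1)
    intervals = counts.assign(
        r_female=kosambi_inverse(np.nan_to_num(adj_f, nan=0.0)),
        r_male=kosambi_inverse(np.nan_to_num(adj_m, nan=0.0)),
        d_female=np.diff(pos_f),
        d_male=np.diff(pos_m),
        d_avg=np.diff(pos_avg),
    )
    df.attrs["intervals"] = intervals
    df.attrs["crossovers"] = xo
    df.attrs["error_rate"] = error_rate
    return df


def _adjacent_path(tables, ordered, order_idx, error_rate):
    matrix, families = tables.matrix, tables.families
    k = len(ordered)
    counts = interval_counts(tables, order_idx)
    r_f = np.zeros(max(k - 1, 0))
    r_m = np.zeros(max(k - 1, 0))
    n_f = np.zeros(max(k - 1, 0))
    n_m = np.zeros(max(k - 1, 0))
    for t in range(k - 1):
        r_f[t], r_m[t], n_f[t], n_m[t] = fit_interval(
            matrix, families, order_idx[t], order_idx[t + 1], error_rate
        )
    for key, n in (("female", n_f), ("male", n_m)):
        if np.any(n == 0) and k > 1:
            warnings.warn(
                f"{int((n == 0).sum())} interval(s) without informative "
                f"{key} meioses; zero gap assigned",
                stacklevel=3,
            )
    r_f = np.clip(np.nan_to_num(r_f), 0.0, _R_CAP)
    r_m = np.clip(np.nan_to_num(r_m), 0.0, _R_CAP)
    tot = np.maximum(n_f + n_m, 1.0)
    r_avg = np.clip((n_f * r_f + n_m * r_m) / tot, 0.0, _R_CAP)

    def positions(r):
        return np.concatenate([[0.0], np.cumsum(kosambi(r))]) if k > 1 else np.zeros(1)

    df = pd.DataFrame(
        {
            "marker_id": ordered,
            "cM_avg": positions(r_avg),
            "cM_female": positions(r_f),
            "cM_male": positions(r_m),
        }
    )
    df.attrs["intervals"] = counts.assign(
        r_female=r_f, r_male=r_m,
        d_female=kosambi(r_f), d_male=kosambi(r_m), d_avg=kosambi(r_avg),
    )
    df.attrs["error_rate"] = error_rate
    return df


def g_test_2x2(table: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio G statistic and p-value (df 1) for a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise DataError("expected a 2x2 table")
    total = obs.sum()
    if total == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    return g, float(stats.chi2.sf(g, df=1))


def sex_difference_gtest(
    interval_table: pd.DataFrame,
    length_female: float | None = None,
    length_male: float | None = None,
    meioses_female: float | None = None,
    meioses_male: float | None = None,
) -> dict:
    """Female-male recombination contrast for one linkage group.

    The 2x2 table holds recombinant vs non-recombinant meiosis-interval
    trials by sex.  When meiosis counts are given, the recombinant cells
    are the crossover counts implied by the fitted map lengths
    (length in Morgans x meioses) — raw deducible-transmission counts
    carry sex-symmetric genotyping-error flips that mask the contrast, so
    the inferred-count table is the more powerful screen; without meiosis
    counts the raw summed counts are used.  Returns G, the p-value (df 1),
    the two lengths, and the female:male ratio (NaN for zero male length).
    """
    len_f = (
        float(interval_table["d_female"].sum()) if length_female is None else length_female
    )
    len_m = float(interval_table["d_male"].sum()) if length_male is None else length_male
    n_intervals = max(len(interval_table), 1)
    if meioses_female is not None and meioses_male is not None:
        R_f = meioses_female * len_f / 100.0
        R_m = meioses_male * len_m / 100.0
        T_f = meioses_female * n_intervals
        T_m = meioses_male * n_intervals
    else:
        R_f, T_f = float(interval_table["R_f"].sum()), float(interval_table["N_f"].sum())
        R_m, T_m = float(interval_table["R_m"].sum()), float(interval_table["N_m"].sum())
    g, p = g_test_2x2(np.array([[R_f, max(T_f - R_f, 0.0)], [R_m, max(T_m - R_m, 0.0)]]))
    ratio = len_f / len_m if len_m > 0 else float("nan")
    return {
        "G": g,
        "pvalue": p,
        "length_female": len_f,
        "length_male": len_m,
        "fm_ratio": ratio,
    }
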