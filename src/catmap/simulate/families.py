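"""Full-sib family simulator with sex-specific recombination.

Generates founder parents, gametes with crossovers, and offspring genotype
matrices with configurable genotyping error and missingness, retaining the
full ground truth (haplotypes, crossover points, true marker positions) for
parameter-recovery tests.

Model
-----
Marker positions are given on a *base* (male) genetic map in cM; the female
map is the base map multiplied by ``female_scale`` (default 1.4, the typical
genome-wide female:male map-length ratio in channel catfish), optionally
overridden per chromosome.  Crossovers follow an interference-free process:
between adjacent markers a gamete switches parental haplotype with
probability equal to the *inverse Kosambi* transform of the sex-specific cM
gap, so that re-estimating distances with the Kosambi function recovers the
simulated truth in expectation.

Genotyping error replaces a call with one of the other two genotypes
uniformly; missingness replaces it with -1.  Parents are genotyped without
error by default (their genotypes anchor cross-type determination).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidConfigError
from ..linkage.mapfun import kosambi, kosambi_inverse

__all__ = [
    "Pedigree",
    "PedigreeSpec",
    "TrueMapConfig",
    "GenotypeMatrix",
    "SimTruth",
    "simulate_families",
    "simulate_dqc",
]


@dataclass
class Pedigree:
    """One full-sib family: a sire, a dam, and their offspring."""

    family_id: str
    sire_id: str
    dam_id: str
    offspring_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.offspring_ids)) != len(self.offspring_ids):
            raise InvalidConfigError(f"duplicate offspring ids in family {self.family_id}")


@dataclass(frozen=True)
class PedigreeSpec:
    """Family structure request: offspring counts and shared-sire links.

    ``shared_sire`` names the indices of families generated from one sire
    (the default mirrors a four-family design totalling 478 offspring in
    which two families share a sire).
    """

    offspring_counts: tuple[int, ...] = (120, 119, 120, 119)
    shared_sire: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if not self.offspring_counts or any(n < 1 for n in self.offspring_counts):
            raise InvalidConfigError("every family needs at least one offspring")
        if any(i >= len(self.offspring_counts) for i in self.shared_sire):
            raise InvalidConfigError("shared_sire indices out of range")


@dataclass
class TrueMapConfig:
    """Ground-truth map for the simulator.

    ``marker_positions``: per-chromosome sorted cM arrays on the base
    (male) map.  ``female_scale`` multiplies the female map genome-wide;
    ``female_scale_per_chrom`` overrides it per chromosome.
    """

    marker_positions: list[np.ndarray]
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    female_scale: float = 1.4
    female_scale_per_chrom: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.marker_positions or any(len(p) == 0 for p in self.marker_positions):
            raise InvalidConfigError("each chromosome needs at least one marker")
        self.marker_positions = [np.asarray(p, dtype=float) for p in self.marker_positions]
        for p in self.marker_positions:
            if np.any(np.diff(p) < 0) or np.any(p < 0):
                raise InvalidConfigError("marker positions must be sorted and non-negative")
        for rate in (self.genotyping_error_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise InvalidConfigError("rates must lie in [0, 1]")
        if self.female_scale_per_chrom is not None and len(self.female_scale_per_chrom) != len(
            self.marker_positions
        ):
            raise InvalidConfigError("one female scale per chromosome required")

    @property
    def n_chromosomes(self) -> int:
        return len(self.marker_positions)

    def scale_for(self, chrom_index: int) -> float:
        if self.female_scale_per_chrom is not None:
            return self.female_scale_per_chrom[chrom_index]
        return self.female_scale

    @classmethod
    def regular(
        cls,
        n_chromosomes: int,
        chrom_lengths_cM,
        markers_per_chrom: int,
        **kwargs,
    ) -> "TrueMapConfig":
        """Evenly spaced markers over chromosomes of the given lengths."""
        lengths = np.broadcast_to(np.asarray(chrom_lengths_cM, dtype=float), (n_chromosomes,))
        positions = [np.linspace(0.0, L, markers_per_chrom) for L in lengths]
        return cls(positions, **kwargs)


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype calls tied to pedigrees.

    ``codes`` holds the dosage of the B allele: 0 (AA), 1 (AB), 2 (BB),
    -1 missing, as int8.  Parents appear as rows alongside offspring.
    ``markers`` carries per-marker metadata (at least ``marker_id``).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    pedigrees: list[Pedigree] = field(default_factory=list)
    markers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise InvalidConfigError("codes shape does not match sample/marker ids")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._marker_index = {m: i for i, m in enumerate(self.marker_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.codes[self._sample_index[sample_id]]

    def marker_column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self._marker_index[marker_id]]

    def marker_positions(self, marker_ids) -> np.ndarray:
        return np.array([self._marker_index[m] for m in marker_ids])

    def offspring_rows(self, family: Pedigree) -> np.ndarray:
        return np.array([self._sample_index[s] for s in family.offspring_ids])

    def call_rates(self) -> pd.Series:
        rates = (self.codes >= 0).mean(axis=1)
        return pd.Series(rates, index=self.sample_ids, name="call_rate")

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = self.marker_positions(marker_ids)
        meta = None
        if self.markers is not None:
            meta = self.markers.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            list(self.sample_ids), list(marker_ids), self.codes[:, idx], self.pedigrees, meta
        )


@dataclass
class SimTruth:
    """Ground truth retained by the simulator for oracle tests."""

    chrom_of_marker: np.ndarray  # int chromosome index per marker
    base_cM: np.ndarray  # base-map position per marker
    r_female: list[np.ndarray]  # adjacent recombination fractions per chromosome
    r_male: list[np.ndarray]
    lengths_female: np.ndarray
    lengths_male: np.ndarray
    lengths_sex_average: np.ndarray
    parent_haplotypes: dict[str, list[np.ndarray]]  # parent -> per-chrom (2, n) arrays
    crossovers: dict[tuple[str, str], list[list[np.ndarray]]]
    # (family_id, parent_role) -> per-offspring list of per-chrom switch-interval indices
    clean_codes: np.ndarray  # genotypes before error/missing injection


def _meiosis(haplo: np.ndarray, r: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a (2, n_markers) haplotype pair; returns (gamete, switches)."""
    n = haplo.shape[1]
    start = rng.integers(2)
    switches = rng.random(n - 1) < r if n > 1 else np.zeros(0, dtype=bool)
    path = np.empty(n, dtype=np.int8)
    path[0] = start
    if n > 1:
        path[1:] = start ^ np.cumsum(switches.astype(np.int8)) % 2
    return haplo[path, np.arange(n)], np.flatnonzero(switches)


def simulate_families(
    map_config: TrueMapConfig,
    pedigree_spec: PedigreeSpec | None = None,
    seed: int = 0,
) -> tuple[list[Pedigree], GenotypeMatrix, SimTruth]:
    """Simulate genotyped full-sib families on a known genetic map.

    Returns the pedigrees, the combined parent+offspring genotype matrix,
    and the retained ground truth.  Deterministic for a fixed seed.
    """
    spec = pedigree_spec or PedigreeSpec()
    rng = np.random.default_rng(seed)
    n_fam = len(spec.offspring_counts)
    chroms = map_config.marker_positions
    n_markers = int(sum(len(p) for p in chroms))

    marker_ids: list[str] = []
    chrom_of_marker = np.empty(n_markers, dtype=int)
    base_cM = np.empty(n_markers)
    k = 0
    for ci, pos in enumerate(chroms):
        for j, p in enumerate(pos):
            marker_ids.append(f"c{ci + 1:02d}_m{j + 1:04d}")
            chrom_of_marker[k] = ci
            base_cM[k] = p
            k += 1

    r_female, r_male = [], []
    lf, lm, lavg = [], [], []
    for ci, pos in enumerate(chroms):
        gaps = np.diff(pos)
        scale = map_config.scale_for(ci)
        rf = kosambi_inverse(gaps * scale)
        rm = kosambi_inverse(gaps)
        r_female.append(rf)
        r_male.append(rm)
        lf.append(float(np.sum(kosambi(rf))) if len(rf) else 0.0)
        lm.append(float(np.sum(kosambi(rm))) if len(rm) else 0.0)
        lavg.append(float(np.sum(kosambi((rf + rm) / 2.0))) if len(rf) else 0.0)

    # founders: one dam per family; families listed in shared_sire reuse sire 1
    sire_of_family: list[str] = []
    shared = set(spec.shared_sire) if len(spec.shared_sire) > 1 else set()
    shared_name: str | None = None
    next_sire = 1
    for i in range(n_fam):
        if i in shared:
            if shared_name is None:
                shared_name = f"sire{next_sire}"
                next_sire += 1
            sire_of_family.append(shared_name)
        else:
            sire_of_family.append(f"sire{next_sire}")
            next_sire += 1
    dam_of_family = [f"dam{i + 1}" for i in range(n_fam)]

    parents = sorted(set(sire_of_family)) + dam_of_family
    parent_haplotypes: dict[str, list[np.ndarray]] = {}
    for pid in parents:
        parent_haplotypes[pid] = [
            rng.integers(0, 2, size=(2, len(pos))).astype(np.int8) for pos in chroms
        ]

    pedigrees: list[Pedigree] = []
    sample_ids: list[str] = list(parents)
    rows: list[np.ndarray] = [
        np.concatenate([h.sum(axis=0) for h in parent_haplotypes[pid]]).astype(np.int8)
        for pid in parents
    ]
    crossovers: dict[tuple[str, str], list[list[np.ndarray]]] = {}

    for fi, n_off in enumerate(spec.offspring_counts):
        fam_id = f"fam{fi + 1}"
        sire, dam = sire_of_family[fi], dam_of_family[fi]
        offspring_ids = [f"{fam_id}_o{j + 1:03d}" for j in range(n_off)]
        pedigrees.append(Pedigree(fam_id, sire, dam, offspring_ids))
        xo_sire: list[list[np.ndarray]] = []
        xo_dam: list[list[np.ndarray]] = []
        for oid in offspring_ids:
            geno_parts = []
            xs: list[np.ndarray] = []
            xd: list[np.ndarray] = []
            for ci in range(len(chroms)):
                g_dam, sw_d = _meiosis(parent_haplotypes[dam][ci], r_female[ci], rng)
                g_sire, sw_s = _meiosis(parent_haplotypes[sire][ci], r_male[ci], rng)
                geno_parts.append(g_dam + g_sire)
                xd.append(sw_d)
                xs.append(sw_s)
            sample_ids.append(oid)
            rows.append(np.concatenate(geno_parts).astype(np.int8))
            xo_dam.append(xd)
            xo_sire.append(xs)
        crossovers[(fam_id, "dam")] = xo_dam
        crossovers[(fam_id, "sire")] = xo_sire

    codes = np.vstack(rows)
    clean = codes.copy()

    n_parents = len(parents)
    off_slice = slice(n_parents, None)
    e = map_config.genotyping_error_rate
    if e > 0:
        err_mask = rng.random(codes[off_slice].shape) < e
        shift = rng.integers(1, 3, size=codes[off_slice].shape).astype(np.int8)
        block = codes[off_slice]
        codes[off_slice] = np.where(err_mask, (block + shift) % 3, block)
    m = map_config.missing_rate
    if m > 0:
        miss_mask = rng.random(codes[off_slice].shape) < m
        block = codes[off_slice]
        codes[off_slice] = np.where(miss_mask, np.int8(-1), block)

    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": [f"chr{c + 1:02d}" for c in chrom_of_marker],
            "cM_base": base_cM,
        }
    )
    matrix = GenotypeMatrix(sample_ids, marker_ids, codes, pedigrees, markers)
    truth = SimTruth(
        chrom_of_marker=chrom_of_marker,
        base_cM=base_cM,
        r_female=r_female,
        r_male=r_male,
        lengths_female=np.array(lf),
        lengths_male=np.array(lm),
        lengths_sex_average=np.array(lavg),
        parent_haplotypes=parent_haplotypes,
        crossovers=crossovers,
        clean_codes=clean,
    )
    return pedigrees, matrix, truth


def simulate_dqc(
    sample_ids,
    seed: int = 0,
    fail_rate: float = 0.015,
    good_beta=(90.0, 6.0),
    bad_range=(0.55, 0.84),
) -> pd.Series:
    """Per-sample dish-QC scores: an opaque array-quality scalar in [0, 1].

    A ``fail_rate`` share of samples is drawn from a low uniform band, the
    rest from a tight Beta centred near 0.94, so default thresholds retain
    roughly 98.5% of samples.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    good = rng.beta(*good_beta, size=n)
    bad = rng.uniform(*bad_range, size=n)
    is_bad = rng.random(n) < fail_rate
    return pd.Series(np.where(is_bad, bad, good), index=sample_ids, name="dqc")
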