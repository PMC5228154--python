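"""SNP array probe selection.

Implements the selection cascade used to design a high-density genotyping
array from a candidate variant pool:

1. flank extraction (71-mers: 35 bp either side of the SNP base);
2. hard filters — multi-locus flanks, neighbouring SNPs within 35 bp,
   low-complexity flanks, non-bi-allelic sites, flank GC outside 30-70%;
3. soft flags — A/T and C/G allele pairs, minor allele frequency <= 0.1 —
   which demote a SNP to a second selection tier rather than excluding it;
4. category classification (channel-specific, blue-specific, fixed
   interspecific differences, shared) with strain-private refinement;
5. greedy spacing selection, genic SNPs first (200 bp exclusion zones),
   then intergenic (350 bp), then species/strain-diagnostic SNPs, with
   unmapped-source SNPs admitted regardless of spacing;
6. per-probe conversion-score thresholding (keep the better probe when at
   least one passes; tile both probes for flagged less-unique flanks);
7. non-polymorphic QC probe selection (half A/T, half G/C at base 31);
8. manifest assembly with arithmetic invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FlankTruncationError, InvalidConfigError, ShortfallError
from .simulate.genome import GenomeModel
from .simulate.variants import CandidateSNP, PopulationSpec, default_populations

__all__ = [
    "FilterVerdict",
    "extract_flank",
    "filter_unique_flanks",
    "filter_candidate",
    "filter_candidates",
    "classify_snp",
    "strain_private_population",
    "greedy_spacing_select",
    "flag_less_unique",
    "apply_pconvert_threshold",
    "select_qc_probes",
    "ArrayManifest",
    "build_manifest",
    "design_array",
]

HARD_CODES = frozenset(
    {"multi_locus", "adjacent_snp_35bp", "low_complexity_repeat", "not_biallelic",
     "gc_out_of_range", "low_pconvert"}
)
SOFT_CODES = frozenset({"at_cg_pair", "low_maf"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FilterVerdict:
    """Outcome of the hard-filter cascade for one SNP.

    ``passed`` is true iff ``reason_codes`` (hard failures) is empty;
    ``soft_codes`` demote the SNP to tier 2 of the spacing selection
    without excluding it.
    """

    snp_id: str
    reason_codes: set = field(default_factory=set)
    soft_codes: set = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.reason_codes

    @property
    def tier(self) -> int:
        return 2 if self.soft_codes else 1


def extract_flank(genome: GenomeModel, scaffold_id: str, pos: int) -> str:
    """71-mer spanning a SNP: bases 1-35 upstream, 36 the site, 37-71 down.

    Raises :class:`FlankTruncationError` when the SNP sits within 35 bp of
    a scaffold edge (such SNPs are excluded from array design).
    """
    length = genome.scaffolds.get(scaffold_id)
    if length is None or not 1 <= pos <= length:
        raise DataError(f"position {pos} outside scaffold {scaffold_id!r}")
    if pos < 36 or pos > length - 35:
        raise FlankTruncationError(
            f"{scaffold_id}:{pos} within 35 bp of a scaffold edge; no full flank"
        )
    return genome.fetch(scaffold_id, pos - 35, pos + 35)


def _count_occurrences(haystack: str, needle: str, limit: int = 2) -> int:
    """Overlapping occurrence count, stopping early at ``limit``."""
    count = start = 0
    while count < limit:
        idx = haystack.find(needle, start)
        if idx < 0:
            break
        count += 1
        start = idx + 1
    return count


def _genome_text(genome: GenomeModel) -> str:
    if genome.sequences is None:
        raise InvalidConfigError("flank uniqueness needs genome base sequence")
    return "#".join(genome.sequences.values())


def filter_unique_flanks(
    snps: list[CandidateSNP], genome: GenomeModel, k: int = 71
) -> dict[str, bool]:
    """True per snp_id iff its flank occurs at exactly one genomic locus.

    Exact k-mer matching on both strands; a flank whose sequence (or its
    reverse complement) appears more than once anywhere in the genome fails
    with reason ``multi_locus``.  SNPs without a full flank also fail.
    """
    text = _genome_text(genome)
    out: dict[str, bool] = {}
    for snp in snps:
        flank = snp.flank
        if flank is None or len(flank) != k:
            out[snp.snp_id] = False
            continue
        n = _count_occurrences(text, flank, limit=2)
        if n < 2:
            rc = revcomp(flank)
            n += _count_occurrences(text, rc, limit=2)
            if rc == flank:  # palindromic flank counted twice
                n //= 2
        out[snp.snp_id] = n == 1
    return out


def has_low_complexity_run(seq: str, min_run: int = 8) -> bool:
    """Homopolymer or dinucleotide repeat of at least ``min_run`` bp."""
    n = len(seq)
    for period in (1, 2):
        run = period
        for i in range(period, n):
            if seq[i] == seq[i - period]:
                run += 1
                if run >= min_run:
                    return True
            else:
                run = period
    return False


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _neighbor_within(snp: CandidateSNP, positions_by_scaffold: dict[str, np.ndarray], bp: int) -> bool:
    pos = positions_by_scaffold.get(snp.scaffold_id)
    if pos is None or len(pos) < 2:
        return False
    i = np.searchsorted(pos, snp.pos)
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(pos) and pos[j] != snp.pos and abs(int(pos[j]) - snp.pos) <= bp:
            return True
    return False


def filter_candidate(
    snp: CandidateSNP,
    unique_flank: bool = True,
    neighbor_positions: dict[str, np.ndarray] | None = None,
    maf_pref: float = 0.1,
    gc_range: tuple[float, float] = (0.30, 0.70),
    complexity_run: int = 8,
) -> FilterVerdict:
    """All applicable filter codes for one SNP (never short-circuited)."""
    v = FilterVerdict(snp.snp_id)
    if not unique_flank:
        v.reason_codes.add("multi_locus")
    if neighbor_positions is not None and _neighbor_within(snp, neighbor_positions, 35):
        v.reason_codes.add("adjacent_snp_35bp")
    if not snp.is_biallelic:
        v.reason_codes.add("not_biallelic")
    if snp.flank is not None:
        if has_low_complexity_run(snp.flank, complexity_run):
            v.reason_codes.add("low_complexity_repeat")
        gc = gc_fraction(snp.flank)
        if not gc_range[0] <= gc <= gc_range[1]:
            v.reason_codes.add("gc_out_of_range")
    alleles = {snp.ref_allele, snp.alt_alleles[0]}
    if alleles in ({"A", "T"}, {"C", "G"}):
        v.soft_codes.add("at_cg_pair")
    if not snp.per_population_freqs:
        raise InvalidConfigError(f"{snp.snp_id}: missing population frequencies")
    if snp.pooled_maf <= maf_pref:
        v.soft_codes.add("low_maf")
    return v


def filter_candidates(
    snps: list[CandidateSNP],
    genome: GenomeModel | None = None,
    maf_pref: float = 0.1,
    gc_range: tuple[float, float] = (0.30, 0.70),
    complexity_run: int = 8,
    check_uniqueness: bool = True,
) -> dict[str, FilterVerdict]:
    """Run the full hard/soft filter cascade over a pool."""
    uniq: dict[str, bool] = {}
    if genome is not None and genome.sequences is not None and check_uniqueness:
        uniq = filter_unique_flanks(snps, genome)
    positions = {
        sid: np.sort(np.array([s.pos for s in snps if s.scaffold_id == sid]))
        for sid in {s.scaffold_id for s in snps}
    }
    return {
        s.snp_id: filter_candidate(
            s,
            unique_flank=uniq.get(s.snp_id, True),
            neighbor_positions=positions,
            maf_pref=maf_pref,
            gc_range=gc_range,
            complexity_run=complexity_run,
        )
        for s in snps
    }


def strain_private_population(
    freqs: dict[str, float], populations: list[PopulationSpec], tol: float = 0.0
) -> str | None:
    """Channel population in which the SNP is privately polymorphic, if any."""
    channel = [p for p in populations if p.species == "channel"]
    poly = [p for p in channel if tol < freqs.get(p.name, 0.0) < 1.0 - tol]
    if len(poly) == 1:
        return poly[0].name
    return None


def classify_snp(
    freqs: dict[str, float],
    populations: list[PopulationSpec] | None = None,
    fixed_tol: float = 0.0,
    strain_level: bool = False,
) -> str:
    """Mutually exclusive SNP category from per-population frequencies.

    Polymorphic only among channel populations -> ``channel_specific``;
    only in blue -> ``blue_specific``; fixed within each species for
    different alleles (within ``fixed_tol``) -> ``interspecific_fixed``;
    polymorphic in both -> ``shared_heterozygous``.  With ``strain_level``,
    channel-specific SNPs private to one population refine to
    ``strain_specific:<name>`` (or ``wild_specific`` for wild populations).
    """
    if populations is None:
        populations = default_populations()
    channel = [freqs.get(p.name, 0.0) for p in populations if p.species == "channel"]
    blue = [freqs.get(p.name, 0.0) for p in populations if p.species == "blue"]
    if not channel or not blue:
        raise InvalidConfigError("frequencies for both species pools are required")

    def poly(fs):
        return any(fixed_tol < f < 1.0 - fixed_tol for f in fs)

    def fixed_allele(fs):
        if all(f <= fixed_tol for f in fs):
            return 0
        if all(f >= 1.0 - fixed_tol for f in fs):
            return 1
        return None

    c_poly, b_poly = poly(channel), poly(blue)
    if c_poly and b_poly:
        return "shared_heterozygous"
    if c_poly:
        if strain_level:
            private = strain_private_population(freqs, populations, fixed_tol)
            if private is not None:
                kind = next(p.kind for p in populations if p.name == private)
                return "wild_specific" if kind == "wild" else f"strain_specific:{private}"
        return "channel_specific"
    if b_poly:
        return "blue_specific"
    ca, ba = fixed_allele(channel), fixed_allele(blue)
    if ca is not None and ba is not None and ca != ba:
        return "interspecific_fixed"
    return "monomorphic"


def greedy_spacing_select(
    snps: list[CandidateSNP],
    verdicts: dict[str, FilterVerdict],
    genic_gap: int = 200,
    intergenic_gap: int = 350,
) -> list[str]:
    """Greedy spacing selection; returns selected snp_ids in stage order.

    Stage 1 takes genic SNPs (gap ``genic_gap``), stage 2 intergenic SNPs
    (gap ``intergenic_gap``), stage 3 adds species/strain-diagnostic SNPs
    left behind; gaps are enforced within each stage only.  Within a stage,
    tier-1 SNPs (no soft flags) are scanned left to right by position, tie
    broken by higher pooled MAF then snp_id; tier-2 SNPs (A/T-C/G pairs or
    low MAF) are admitted only inside holes where the tier-1 selection left
    more than twice the stage gap.  SNPs from unmapped sources are included
    regardless of spacing.
    """
    passing = [s for s in snps if verdicts[s.snp_id].passed]
    selected: list[str] = []
    taken: set[str] = set()

    mapped = [s for s in passing if s.source == "genome"]
    unmapped = [s for s in passing if s.source != "genome"]

    def scan(stage_snps: list[CandidateSNP], gap: int) -> list[str]:
        chosen: list[str] = []
        by_scaffold: dict[str, list[CandidateSNP]] = {}
        for s in stage_snps:
            by_scaffold.setdefault(s.scaffold_id, []).append(s)
        for sid in sorted(by_scaffold):
            group = sorted(
                by_scaffold[sid], key=lambda s: (s.pos, -s.pooled_maf, s.snp_id)
            )
            tier1 = [s for s in group if verdicts[s.snp_id].tier == 1]
            tier2 = [s for s in group if verdicts[s.snp_id].tier == 2]
            picked_pos: list[int] = []
            t1_pos: list[int] = []
            last = -gap - 1
            for s in tier1:
                if s.pos - last >= gap:
                    chosen.append(s.snp_id)
                    picked_pos.append(s.pos)
                    t1_pos.append(s.pos)
                    last = s.pos
            t1_arr = np.array(t1_pos)
            all_pos = sorted(picked_pos)
            for s in tier2:
                i = np.searchsorted(t1_arr, s.pos)
                prev1 = t1_arr[i - 1] if i > 0 else None
                next1 = t1_arr[i] if i < len(t1_arr) else None
                hole = (next1 if next1 is not None else np.inf) - (
                    prev1 if prev1 is not None else -np.inf
                )
                if hole <= 2 * gap:
                    continue
                j = np.searchsorted(all_pos, s.pos)
                near = [all_pos[k] for k in (j - 1, j) if 0 <= k < len(all_pos)]
                if all(abs(s.pos - p) >= gap for p in near):
                    chosen.append(s.snp_id)
                    all_pos.insert(j, s.pos)
        return chosen

    # stage 1: genic; stage 2: intergenic
    for stage_snps, gap in (
        ([s for s in mapped if s.genic], genic_gap),
        ([s for s in mapped if not s.genic], intergenic_gap),
    ):
        for sid in scan([s for s in stage_snps if s.snp_id not in taken], gap):
            selected.append(sid)
            taken.add(sid)

    # stage 3: species/strain-diagnostic SNPs not yet selected
    diag_cats = {"blue_specific", "interspecific_fixed"}
    by_id = {s.snp_id: s for s in snps}
    diagnostics = []
    for s in mapped:
        if s.snp_id in taken:
            continue
        cat = classify_snp(s.per_population_freqs, strain_level=True)
        if cat in diag_cats or cat.startswith("strain_specific") or cat == "wild_specific":
            diagnostics.append(s)
    for sid in scan(diagnostics, min(genic_gap, intergenic_gap)):
        selected.append(sid)
        taken.add(sid)

    for s in unmapped:  # no spacing constraint
        if s.snp_id not in taken:
            selected.append(s.snp_id)
            taken.add(s.snp_id)
    return selected


def flag_less_unique(
    snps: list[CandidateSNP], genome: GenomeModel, arm_k: int = 35
) -> set[str]:
    """SNPs whose flank passes uniqueness but has a repeated 35 bp arm.

    These are the 'cover anyway' SNPs that receive both probes even when
    neither passes the conversion-score threshold.
    """
    text = _genome_text(genome)
    flagged: set[str] = set()
    for snp in snps:
        if snp.flank is None:
            continue
        for arm in (snp.flank[:arm_k], snp.flank[-arm_k:]):
            n = _count_occurrences(text, arm, limit=2) + _count_occurrences(
                text, revcomp(arm), limit=2
            )
            if n > 1:
                flagged.add(snp.snp_id)
                break
    return flagged


def apply_pconvert_threshold(
    snp_ids,
    scores: pd.DataFrame,
    tau: float = 0.6,
    cover_anyway: set | None = None,
) -> pd.DataFrame:
    """Probe retention by conversion score.

    When at least one of the two probes scores above ``tau`` the better one
    is kept (single-probe SNP).  When both fall below, the SNP is dropped
    unless flagged cover-anyway, in which case both probes are tiled
    (dual-probe SNP).  Returns a frame with one row per retained SNP:
    ``n_probes`` (1 or 2), ``direction`` and ``score`` of the chosen probe.
    """
    cover_anyway = cover_anyway or set()
    rows = []
    for sid in snp_ids:
        if sid not in scores.index:
            raise DataError(f"no conversion scores for {sid}")
        fwd, rev = float(scores.at[sid, "forward"]), float(scores.at[sid, "reverse"])
        best_dir, best = ("forward", fwd) if fwd >= rev else ("reverse", rev)
        if best > tau:
            rows.append((sid, 1, best_dir, best))
        elif sid in cover_anyway:
            rows.append((sid, 2, "both", best))
    return pd.DataFrame(rows, columns=["snp_id", "n_probes", "direction", "score"]).set_index(
        "snp_id"
    )


def select_qc_probes(
    genome: GenomeModel,
    snps: list[CandidateSNP],
    n: int = 2000,
) -> pd.DataFrame:
    """Non-polymorphic 71-mer QC probes, half A/T and half G/C at base 31.

    Eligible windows lie fully inside a scaffold and keep clear of every
    candidate SNP's flank region (SNP position +/- 35 bp).  Picks are spread
    evenly along the genome; a shortfall of either class raises
    :class:`ShortfallError`.
    """
    if n % 2:
        raise InvalidConfigError("n must be even (equal A/T and G/C halves)")
    if genome.sequences is None:
        raise InvalidConfigError("QC probe selection needs genome sequence")
    snp_pos: dict[str, list[int]] = {}
    for s in snps:
        snp_pos.setdefault(s.scaffold_id, []).append(s.pos)

    at_sites: list[tuple[str, int]] = []
    gc_sites: list[tuple[str, int]] = []
    for sid, length in genome.scaffolds.items():
        if length < 71:
            continue
        blocked = np.zeros(length + 2, dtype=bool)
        for p in snp_pos.get(sid, []):
            blocked[max(1, p - 35) : min(length, p + 35) + 1] = True
        ok = ~blocked[1 : length + 1]
        # window starting at 1-based s covers [s, s+70]
        window_ok = np.ones(length - 70, dtype=bool)
        bad = np.flatnonzero(~ok) + 1
        for b in bad:
            lo = max(1, b - 70)
            hi = min(length - 70, b)
            if lo <= hi:
                window_ok[lo - 1 : hi] = False
        seq = genome.sequences[sid]
        for start in np.flatnonzero(window_ok) + 1:
            base31 = seq[start - 1 + 30]
            if base31 in "AT":
                at_sites.append((sid, int(start)))
            elif base31 in "GC":
                gc_sites.append((sid, int(start)))

    half = n // 2
    if len(at_sites) < half or len(gc_sites) < half:
        raise ShortfallError(
            f"only {len(at_sites)} A/T and {len(gc_sites)} G/C eligible sites for n={n}"
        )
    rows = []
    for sites, label in ((at_sites, "AT"), (gc_sites, "GC")):
        idx = np.unique(np.linspace(0, len(sites) - 1, half).round().astype(int))
        k = 0
        chosen = set()
        for i in idx:
            chosen.add(i)
        while len(chosen) < half:  # top up after rounding collisions
            if k not in chosen:
                chosen.add(k)
            k += 1
        for i in sorted(chosen):
            sid, start = sites[i]
            rows.append((f"qc_{label}_{sid}_{start}", sid, start, label,
                         genome.fetch(sid, start, start + 70)))
    return pd.DataFrame(
        rows, columns=["probe_id", "scaffold_id", "start", "class31", "seq"]
    ).set_index("probe_id")


@dataclass
class ArrayManifest:
    """Final array content with composition counts.

    Invariants: total_snps = genic + intergenic; total_probes =
    single_probe + 2 * dual_probe; the four mutually exclusive category
    counts sum to total_snps.  Strain-private counts are an overlay of the
    channel-specific class, not part of the partition.
    """

    snps: pd.DataFrame  # snp_id, scaffold_id, pos, ref, alt, genic, category, n_probes, score
    qc_probes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def total_snps(self) -> int:
        return len(self.snps)

    @property
    def total_probes(self) -> int:
        return int(self.snps["n_probes"].sum()) if len(self.snps) else 0

    def counts(self) -> dict[str, int]:
        df = self.snps
        cats = df["category"].value_counts().to_dict() if len(df) else {}
        out = {
            "total_snps": self.total_snps,
            "genic": int(df["genic"].sum()) if len(df) else 0,
            "intergenic": int((~df["genic"].astype(bool)).sum()) if len(df) else 0,
            "single_probe": int((df["n_probes"] == 1).sum()) if len(df) else 0,
            "dual_probe": int((df["n_probes"] == 2).sum()) if len(df) else 0,
            "total_probes": self.total_probes,
            "channel_specific": int(cats.get("channel_specific", 0)),
            "blue_specific": int(cats.get("blue_specific", 0)),
            "interspecific_fixed": int(cats.get("interspecific_fixed", 0)),
            "shared_heterozygous": int(cats.get("shared_heterozygous", 0)),
            "qc_probes": 0 if self.qc_probes is None else len(self.qc_probes),
        }
        strain = df["strain_private"].dropna() if "strain_private" in df else pd.Series([], dtype=object)
        out["strain_private"] = {k: int(v) for k, v in strain.value_counts().items()}
        return out

    def validate(self) -> None:
        c = self.counts()
        if c["genic"] + c["intergenic"] != c["total_snps"]:
            raise DataError("genic + intergenic != total_snps")
        if c["single_probe"] + 2 * c["dual_probe"] != c["total_probes"]:
            raise DataError("probe arithmetic violated")
        cat_sum = (
            c["channel_specific"] + c["blue_specific"] + c["interspecific_fixed"]
            + c["shared_heterozygous"]
        )
        n_cat = int((self.snps["category"] != "monomorphic").sum()) if len(self.snps) else 0
        if cat_sum != n_cat:
            raise DataError("category counts do not sum to categorised SNPs")


def build_manifest(
    snps: list[CandidateSNP],
    probe_table: pd.DataFrame,
    populations: list[PopulationSpec] | None = None,
    qc_probes: pd.DataFrame | None = None,
) -> ArrayManifest:
    """Assemble the manifest for SNPs retained after probe thresholding."""
    by_id = {s.snp_id: s for s in snps}
    rows = []
    for sid, prow in probe_table.iterrows():
        s = by_id[sid]
        cat = classify_snp(s.per_population_freqs, populations)
        refined = classify_snp(s.per_population_freqs, populations, strain_level=True)
        strain = None
        if refined.startswith("strain_specific:"):
            strain = refined.split(":", 1)[1]
        elif refined == "wild_specific":
            strain = "Wild"
        rows.append(
            {
                "snp_id": sid,
                "scaffold_id": s.scaffold_id,
                "pos": s.pos,
                "ref": s.ref_allele,
                "alt": ",".join(s.alt_alleles),
                "genic": bool(s.genic),
                "source": s.source,
                "category": cat,
                "strain_private": strain,
                "n_probes": int(prow["n_probes"]),
                "direction": prow["direction"],
                "score": float(prow["score"]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "scaffold_id", "pos", "ref", "alt", "genic", "source",
            "category", "strain_private", "n_probes", "direction", "score",
        ],
    )
    return ArrayManifest(df, qc_probes)


def design_array(
    genome: GenomeModel,
    snps: list[CandidateSNP],
    scores: pd.DataFrame,
    populations: list[PopulationSpec] | None = None,
    genic_gap: int = 200,
    intergenic_gap: int = 350,
    pconvert_tau: float = 0.6,
    maf_pref: float = 0.1,
    gc_range: tuple[float, float] = (0.30, 0.70),
    n_qc_probes: int | None = None,
) -> ArrayManifest:
    """Run the complete selection cascade and return the manifest."""
    verdicts = filter_candidates(snps, genome, maf_pref=maf_pref, gc_range=gc_range)
    selected = greedy_spacing_select(snps, verdicts, genic_gap, intergenic_gap)
    cover = flag_less_unique([s for s in snps if s.snp_id in set(selected)], genome)
    probes = apply_pconvert_threshold(selected, scores, pconvert_tau, cover)
    qc = None
    if n_qc_probes:
        qc = select_qc_probes(genome, snps, n_qc_probes)
    return build_manifest(snps, probes, populations, qc)
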