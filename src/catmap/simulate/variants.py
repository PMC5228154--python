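"""Synthetic candidate SNP pools with per-population allele frequencies.

The generator stands in for the output of a read-mapping + variant-calling
chain: it emits bi- and tri-allelic SNPs with 71-mer flanks, per-population
alternate-allele frequencies for two species (channel and blue catfish) and
several channel strains, and it only emits SNPs whose pooled minor allele
frequency is at least ``min_pooled_maf`` (0.05 by default), mirroring the
calling thresholds applied upstream of array design.

Frequencies are drawn hierarchically: each SNP gets a latent category
(channel-specific, blue-specific, fixed interspecific difference, shared, or
strain-specific) and population frequencies consistent with it, with
channel strains correlated through a species-level Beta draw.  This single
generator therefore produces every SNP category the array composition
report distinguishes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidConfigError
from .genome import GenomeModel

__all__ = [
    "PopulationSpec",
    "CandidateSNP",
    "default_populations",
    "simulate_variant_pool",
    "simulate_pconvert",
]

_BASES = "ACGT"

# Probe-quality Beta defaults: chosen so the maximum of the two probe scores
# has mean 0.71 with 97% of SNPs above 0.65 (the retained-set summaries the
# generator is calibrated to reproduce).
PCONVERT_BETA_A = 92.4
PCONVERT_BETA_B = 42.0


@dataclass(frozen=True)
class PopulationSpec:
    """One genotyped population contributing allele frequencies.

    ``species`` is 'channel' or 'blue'; ``kind`` distinguishes domestic
    strains, wild populations, and whole-species pools.  ``beta_a/beta_b``
    parameterise the Beta distribution the polymorphic-frequency draws use.
    """

    name: str
    species: str
    kind: str = "domestic_strain"
    beta_a: float = 1.2
    beta_b: float = 1.2

    def __post_init__(self) -> None:
        if self.species not in ("channel", "blue"):
            raise InvalidConfigError(f"unknown species {self.species!r}")
        if self.kind not in ("domestic_strain", "wild", "species_pool"):
            raise InvalidConfigError(f"unknown population kind {self.kind!r}")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise InvalidConfigError("Beta parameters must be positive")


def default_populations() -> list[PopulationSpec]:
    """Five channel catfish populations plus one blue catfish pool."""
    strains = ["Thompson", "Hatchery", "Marion", "USDA103"]
    pops = [PopulationSpec(s, "channel", "domestic_strain") for s in strains]
    pops.append(PopulationSpec("Wild", "channel", "wild"))
    pops.append(PopulationSpec("Blue", "blue", "species_pool"))
    return pops


@dataclass
class CandidateSNP:
    """One candidate variant with flanks and per-population frequencies."""

    snp_id: str
    scaffold_id: str
    pos: int  # 1-based position of the SNP base
    ref_allele: str
    alt_alleles: list[str]
    flank: str | None = None  # 71-mer: 35 up + SNP + 35 down, None if truncated
    per_population_freqs: dict[str, float] = field(default_factory=dict)
    genic: bool = False
    source: str = "genome"  # genome | unmapped_scaffold | transcript | BES

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise InvalidConfigError(f"{self.snp_id}: alt_alleles must be non-empty")
        if self.flank is not None and len(self.flank) != 71:
            raise InvalidConfigError(f"{self.snp_id}: flank must be a 71-mer")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    def pooled_alt_freq(self, populations: list[PopulationSpec] | None = None) -> float:
        freqs = list(self.per_population_freqs.values())
        return float(np.mean(freqs)) if freqs else float("nan")

    @property
    def pooled_maf(self) -> float:
        f = self.pooled_alt_freq()
        return min(f, 1.0 - f)


# default latent-category weights, proportional to the array composition
# (channel-specific : blue-specific : interspecific fixed : shared)
DEFAULT_CATEGORY_WEIGHTS = {
    "channel_specific": 0.8412,
    "blue_specific": 0.0647,
    "interspecific_fixed": 0.0277,
    "shared_heterozygous": 0.0664,
}
# fraction of channel-specific SNPs that are private to a single channel
# population (strain-specific / wild-specific), cf. 55,056 / 581,002
STRAIN_PRIVATE_FRACTION = 0.095


def _draw_freqs(category, pops, rng, strain_concentration=8.0):
    """Per-population alternate-allele frequencies for one SNP."""
    channel = [p for p in pops if p.species == "channel"]
    blue = [p for p in pops if p.species == "blue"]
    freqs: dict[str, float] = {p.name: 0.0 for p in pops}

    def correlated(base: float, pop: PopulationSpec) -> float:
        a = max(1e-3, strain_concentration * base)
        b = max(1e-3, strain_concentration * (1.0 - base))
        return float(rng.beta(a, b))

    if category == "channel_specific":
        if rng.random() < STRAIN_PRIVATE_FRACTION and channel:
            private = channel[rng.integers(len(channel))]
            freqs[private.name] = float(rng.beta(private.beta_a, private.beta_b))
        else:
            base = float(rng.beta(2.0, 2.0))
            for p in channel:
                freqs[p.name] = correlated(base, p)
    elif category == "blue_specific":
        for p in blue:
            freqs[p.name] = float(rng.beta(p.beta_a, p.beta_b))
    elif category == "interspecific_fixed":
        # alternate allele fixed in one species, absent in the other
        alt_in_blue = rng.random() < 0.5
        for p in pops:
            freqs[p.name] = 1.0 if (p.species == "blue") == alt_in_blue else 0.0
    elif category == "shared_heterozygous":
        base = float(rng.beta(2.0, 2.0))
        for p in channel:
            freqs[p.name] = correlated(base, p)
        for p in blue:
            freqs[p.name] = float(np.clip(correlated(base, p), 0.02, 0.98))
        # guarantee polymorphism on both sides
        for p in channel + blue:
            if freqs[p.name] in (0.0, 1.0):
                freqs[p.name] = 0.5
    else:  # pragma: no cover - guarded upstream
        raise InvalidConfigError(f"unknown SNP category {category!r}")
    return freqs


def simulate_variant_pool(
    genome: GenomeModel,
    populations: list[PopulationSpec] | None = None,
    density_per_kb: float = 1.0,
    seed: int = 0,
    fraction_triallelic: float = 0.02,
    fraction_adjacent: float = 0.05,
    min_pooled_maf: float = 0.05,
    category_weights: dict[str, float] | None = None,
) -> list[CandidateSNP]:
    """Draw a candidate SNP pool over a simulated genome.

    SNP counts per scaffold are Poisson with mean length * density; positions
    are uniform.  A ``fraction_adjacent`` share of SNPs receives a companion
    SNP within 35 bp and a ``fraction_triallelic`` share a second alternate
    allele, so the flank and bi-allelic filters downstream have real work.
    SNPs whose pooled MAF falls below ``min_pooled_maf`` are redrawn.
    """
    if populations is None:
        populations = default_populations()
    if not populations:
        raise InvalidConfigError("population list must be non-empty")
    if density_per_kb <= 0:
        raise InvalidConfigError("density_per_kb must be positive")
    if not (0 <= fraction_triallelic <= 1 and 0 <= fraction_adjacent <= 1):
        raise InvalidConfigError("fractions must lie in [0, 1]")

    weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)
    cats = list(weights)
    p_cat = np.array([weights[c] for c in cats], dtype=float)
    if np.any(p_cat < 0) or p_cat.sum() <= 0:
        raise InvalidConfigError("category weights must be non-negative, not all zero")
    p_cat = p_cat / p_cat.sum()

    rng = np.random.default_rng(seed)
    snps: list[CandidateSNP] = []
    counter = 0

    def make_snp(sid: str, pos: int) -> CandidateSNP:
        nonlocal counter
        counter += 1
        length = genome.scaffolds[sid]
        if genome.sequences is not None:
            ref = genome.sequences[sid][pos - 1]
            flank = genome.fetch(sid, pos - 35, pos + 35) if 36 <= pos <= length - 35 else None
        else:
            ref = _BASES[rng.integers(4)]
            flank = None
        others = [b for b in _BASES if b != ref]
        alts = [others[rng.integers(3)]]
        if rng.random() < fraction_triallelic:
            alts.append([b for b in others if b != alts[0]][rng.integers(2)])
        category = cats[rng.choice(len(cats), p=p_cat)]
        for _ in range(40):  # redraw until the pooled-MAF floor is met
            freqs = _draw_freqs(category, populations, rng)
            pooled = float(np.mean(list(freqs.values())))
            if min(pooled, 1.0 - pooled) >= min_pooled_maf:
                break
        return CandidateSNP(
            snp_id=f"snp{counter:07d}",
            scaffold_id=sid,
            pos=pos,
            ref_allele=ref,
            alt_alleles=alts,
            flank=flank,
            per_population_freqs=freqs,
            genic=genome.is_genic(sid, pos),
            source="genome",
        )

    for sid, length in genome.scaffolds.items():
        n = rng.poisson(length * density_per_kb / 1000.0)
        positions = np.unique(rng.integers(1, length + 1, size=n))
        for pos in positions:
            snp = make_snp(sid, int(pos))
            snps.append(snp)
            if rng.random() < fraction_adjacent:
                offset = int(rng.integers(1, 35))
                neighbor = pos + offset if pos + offset <= length else pos - offset
                if 1 <= neighbor <= length and neighbor != pos:
                    snps.append(make_snp(sid, int(neighbor)))
    return snps


def simulate_pconvert(
    snps: list[CandidateSNP],
    beta_a: float = PCONVERT_BETA_A,
    beta_b: float = PCONVERT_BETA_B,
    seed: int = 0,
):
    """Per-probe conversion-quality scores in [0, 1].

    Each SNP receives independent forward and reverse probe scores drawn
    from Beta(``beta_a``, ``beta_b``).  Returns a pandas DataFrame indexed
    by snp_id with columns ``forward`` and ``reverse``.
    """
    import pandas as pd

    if beta_a <= 0 or beta_b <= 0:
        raise InvalidConfigError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    ids = [s.snp_id for s in snps]
    scores = rng.beta(beta_a, beta_b, size=(len(ids), 2))
    return pd.DataFrame(scores, index=pd.Index(ids, name="snp_id"), columns=["forward", "reverse"])
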