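"""Synthetic fragmented genome assemblies.

Emulates a draft assembly made of scaffolds with annotated genic and repeat
intervals.  Coordinates are 1-based inclusive throughout the package; the
BED boundary conversion happens only in :mod:`catmap.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidConfigError

__all__ = ["GenomeModel", "simulate_genome"]

_BASES = np.array(list("ACGT"))
# low-complexity motifs used to fill simulated repeat intervals so that the
# flank-complexity and uniqueness filters downstream have genuine targets
_REPEAT_MOTIFS = ["A", "T", "AT", "CA", "GT", "CT"]


@dataclass
class GenomeModel:
    """A set of scaffolds with genic/repeat interval annotation.

    ``scaffolds`` maps scaffold_id -> length (bp).  Interval lists hold
    1-based inclusive (start, end) tuples; genic intervals are
    non-overlapping within a scaffold.  ``sequences`` is optional (some
    operations only need coordinates).
    """

    scaffolds: dict[str, int]
    genic_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    repeat_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for sid, length in self.scaffolds.items():
            if length <= 0:
                raise InvalidConfigError(f"scaffold {sid!r} has non-positive length")
        for name, table in (("genic", self.genic_intervals), ("repeat", self.repeat_intervals)):
            for sid, ivals in table.items():
                length = self.scaffolds.get(sid)
                if length is None:
                    raise InvalidConfigError(f"{name} intervals refer to unknown scaffold {sid!r}")
                prev_end = 0
                for start, end in sorted(ivals):
                    if start < 1 or end > length or start > end:
                        raise InvalidConfigError(
                            f"{name} interval ({start}, {end}) outside [1, {length}] on {sid}"
                        )
                    if name == "genic" and start <= prev_end:
                        raise InvalidConfigError(f"overlapping genic intervals on {sid}")
                    prev_end = max(prev_end, end)

    @property
    def total_bp(self) -> int:
        return int(sum(self.scaffolds.values()))

    def _interval_bp(self, table: dict[str, list[tuple[int, int]]]) -> int:
        return int(sum(e - s + 1 for ivals in table.values() for s, e in ivals))

    @property
    def genic_bp(self) -> int:
        return self._interval_bp(self.genic_intervals)

    @property
    def repeat_bp(self) -> int:
        return self._interval_bp(self.repeat_intervals)

    def is_genic(self, scaffold_id: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.genic_intervals.get(scaffold_id, []))

    def in_repeat(self, scaffold_id: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.repeat_intervals.get(scaffold_id, []))

    def fetch(self, scaffold_id: str, start: int, end: int) -> str:
        """Subsequence in 1-based inclusive coordinates."""
        if self.sequences is None:
            raise InvalidConfigError("genome carries no base sequence")
        return self.sequences[scaffold_id][start - 1 : end]


def _scaffold_lengths(n_scaffolds: int, total_bp: int, sigma: float, rng) -> np.ndarray:
    """Lognormal scaffold sizes rescaled to sum to ``total_bp`` exactly."""
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_scaffolds)
    lengths = np.maximum(1, np.round(raw / raw.sum() * total_bp).astype(int))
    # fix rounding drift on the largest scaffold
    drift = total_bp - int(lengths.sum())
    lengths[int(np.argmax(lengths))] += drift
    if np.any(lengths < 1):
        raise InvalidConfigError("requested sizes produce a zero-length scaffold")
    return lengths


def simulate_genome(
    n_scaffolds: int,
    total_bp: int,
    genic_fraction: float = 0.3,
    repeat_fraction: float = 0.1,
    seed: int = 0,
    length_sigma: float = 0.7,
    mean_feature_bp: int = 300,
    with_sequence: bool = True,
) -> GenomeModel:
    """Simulate a fragmented assembly with annotated genic/repeat intervals.

    Scaffold sizes are lognormal (shape ``length_sigma``) normalised to
    ``total_bp``.  Each scaffold is tiled by an alternating renewal process:
    every block is genic, repeat, or plain intergenic with probabilities
    equal to the requested fractions, with exponential block lengths (mean
    ``mean_feature_bp``), so realised base fractions converge to the
    requested ones on large genomes.  Repeat intervals are filled with
    low-complexity sequence.
    """
    if n_scaffolds < 1:
        raise InvalidConfigError("n_scaffolds must be >= 1")
    if total_bp < n_scaffolds:
        raise InvalidConfigError("total_bp smaller than scaffold count (zero-length scaffolds)")
    if not (0 <= genic_fraction <= 1 and 0 <= repeat_fraction <= 1):
        raise InvalidConfigError("fractions must lie in [0, 1]")
    if genic_fraction + repeat_fraction > 1:
        raise InvalidConfigError("genic_fraction + repeat_fraction must be <= 1")

    rng = np.random.default_rng(seed)
    lengths = _scaffold_lengths(n_scaffolds, total_bp, length_sigma, rng)
    order = np.argsort(-lengths)  # scf00001 is the largest, as in real drafts
    width = max(5, len(str(n_scaffolds)))

    scaffolds: dict[str, int] = {}
    genic: dict[str, list[tuple[int, int]]] = {}
    repeat: dict[str, list[tuple[int, int]]] = {}
    seqs: dict[str, str] | None = {} if with_sequence else None

    probs = np.array([1.0 - genic_fraction - repeat_fraction, genic_fraction, repeat_fraction])
    for rank, idx in enumerate(order, start=1):
        sid = f"scf{rank:0{width}d}"
        length = int(lengths[idx])
        scaffolds[sid] = length
        g_ivals: list[tuple[int, int]] = []
        r_ivals: list[tuple[int, int]] = []
        pos = 1
        while pos <= length:
            kind = rng.choice(3, p=probs)
            block = 1 + int(rng.exponential(mean_feature_bp))
            end = min(length, pos + block - 1)
            if kind == 1:
                if g_ivals and g_ivals[-1][1] == pos - 1:
                    g_ivals[-1] = (g_ivals[-1][0], end)
                else:
                    g_ivals.append((pos, end))
            elif kind == 2:
                if r_ivals and r_ivals[-1][1] == pos - 1:
                    r_ivals[-1] = (r_ivals[-1][0], end)
                else:
                    r_ivals.append((pos, end))
            pos = end + 1
        genic[sid] = g_ivals
        repeat[sid] = r_ivals
        if seqs is not None:
            seq = rng.choice(_BASES, size=length)
            for s, e in r_ivals:
                motif = _REPEAT_MOTIFS[rng.integers(len(_REPEAT_MOTIFS))]
                fill = (motif * ((e - s) // len(motif) + 2))[: e - s + 1]
                seq[s - 1 : e] = list(fill)
            seqs[sid] = "".join(seq)

    return GenomeModel(scaffolds, genic, repeat, seqs)
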