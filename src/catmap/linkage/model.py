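"""Linkage-map model and results objects.

:class:`LinkageMapModel` is constructed from a genotype matrix plus its
pedigrees and a :class:`MapConfig`; ``fit()`` runs the full pipeline —
marker filtering, all-pairs two-point linkage, linkage-group formation,
single-marker joining, duplicate collapsing, two-round ordering with
reinsertion, and sex-specific Kosambi distances — and returns a
:class:`LinkageMapResults` carrying the genetic map, per-group summaries,
sex-dimorphism G-tests, and a text ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DataError
from ..simulate.families import GenotypeMatrix, Pedigree
from .distances import compute_map_distances, sex_difference_gtest
from .filtering import filter_markers
from .grouping import join_singles, separate_chromosomes
from .mapfun import kosambi
from .ordering import collapse_duplicates, order_markers, reinsert_duplicates
from .twopoint import TransmissionTables, two_point_matrix

__all__ = ["MapConfig", "LinkageMapModel", "LinkageMapResults"]


@dataclass
class MapConfig:
    """Tunable thresholds of the mapping pipeline (defaults as printed
    on the tin: LOD limit 35 with minimum group size 10 for group
    formation, LOD 10 with margin 3 for joining singles, per-family
    missing <= 12 and minor-allele count >= 6 with at least two
    informative families, distortion test at p < 0.005)."""

    lod_limit: float = 35.0
    min_lg_size: int = 10
    join_lod: float = 10.0
    join_diff: float = 3.0
    max_missing: int = 12
    min_minor: int = 6
    min_inform_fams: int = 2
    distortion_p: float = 0.005
    duplicate_missing_tol: float = 0.05
    n_order_starts: int = 10
    n_order_rounds: int = 2
    error_correction: bool = True
    error_rate: float | None = None  # None: estimate from impossible calls
    lod_floor: float = 3.0  # sparsification floor for the pair graph
    seed: int = 17


class LinkageMapModel:
    """Sex-specific genetic linkage mapping from full-sib families."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        pedigrees: list[Pedigree] | None = None,
        config: MapConfig | None = None,
    ):
        self.genotypes = genotypes
        self.pedigrees = pedigrees or genotypes.pedigrees
        if not self.pedigrees:
            raise DataError("linkage mapping needs at least one full-sib family")
        self.config = config or MapConfig()

    @classmethod
    def from_files(cls, genotype_tsv, ped_path, config: MapConfig | None = None):
        """Build from a genotype TSV and a pre-MAKEPED pedigree file."""
        from ..io import read_genotype_tsv, read_linkage_ped

        pedigrees, _ = read_linkage_ped(ped_path)
        matrix = read_genotype_tsv(genotype_tsv, pedigrees=pedigrees)
        return cls(matrix, pedigrees, config)

    def fit(self, seed: int | None = None) -> "LinkageMapResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        matrix, families = self.genotypes, self.pedigrees

        verdicts = filter_markers(
            matrix, families, cfg.max_missing, cfg.min_minor,
            cfg.min_inform_fams, cfg.distortion_p,
        )
        retained = [m for m in matrix.marker_ids if verdicts.loc[m, "retained"]]
        if len(retained) < 2:
            raise DataError("fewer than two markers retained after filtering")

        tables = TransmissionTables(matrix, families)
        ridx = matrix.marker_positions(retained)
        tp = two_point_matrix(tables, ridx)
        lod = tp["lod"]
        lod[lod < cfg.lod_floor] = 0.0  # sparsification floor

        groups, unassigned = separate_chromosomes(
            lod, retained, cfg.lod_limit, cfg.min_lg_size
        )
        groups = join_singles(
            unassigned, groups, lod, retained, cfg.join_lod, cfg.join_diff
        )

        info = tables.informativeness()
        off_rows = np.concatenate([matrix.offspring_rows(f) for f in families])
        pos_of = {m: i for i, m in enumerate(retained)}

        maps = []
        interval_tables = {}
        clusters_by_lg = {}
        for lg_id, members in sorted(groups.items()):
            codes_lg = matrix.codes[np.ix_(off_rows, matrix.marker_positions(members))]
            clusters = collapse_duplicates(
                codes_lg,
                members,
                info[matrix.marker_positions(members)],
                cfg.duplicate_missing_tol,
            )
            clusters_by_lg[lg_id] = clusters
            reps = clusters.representatives
            rep_rows = np.array([pos_of[m] for m in reps])
            r_sub = tp["r"][np.ix_(rep_rows, rep_rows)]
            n_sub = tp["N"][np.ix_(rep_rows, rep_rows)]
            D = np.where(
                n_sub > 0, kosambi(np.clip(np.nan_to_num(r_sub, nan=0.5), 0, 0.4999)), 300.0
            )
            order_idx = order_markers(
                D, n_starts=cfg.n_order_starts, n_rounds=cfg.n_order_rounds, seed=seed
            )
            ordered_reps = [reps[i] for i in order_idx]
            full_order, rep_of = reinsert_duplicates(ordered_reps, clusters)
            er = (cfg.error_rate if cfg.error_rate is not None else None) if cfg.error_correction else 0.0
            dist_reps = compute_map_distances(tables, ordered_reps, error_rate=er)
            # the placement step may locally refine the representative order
            ordered_reps = list(dist_reps["marker_id"])
            iv = dist_reps.attrs["intervals"]
            iv.attrs["crossovers"] = dist_reps.attrs.get("crossovers", {})
            interval_tables[lg_id] = iv
            cm = dist_reps.set_index("marker_id")
            rows = []
            order_counter = 0
            for rep in ordered_reps:
                for mid in [rep] + [m for m in clusters.members[rep] if m != rep]:
                    rows.append(
                        {
                            "marker_id": mid,
                            "lg": lg_id,
                            "order": order_counter,
                            "cM_avg": float(cm.at[rep, "cM_avg"]),
                            "cM_female": float(cm.at[rep, "cM_female"]),
                            "cM_male": float(cm.at[rep, "cM_male"]),
                            "representative": rep,
                        }
                    )
                    order_counter += 1
            maps.append(pd.DataFrame(rows))
        if not maps:
            raise DataError("no linkage groups formed; lower the LOD limit?")
        gmap = pd.concat(maps, ignore_index=True)

        # unique position index per LG: distinct sex-average positions
        gmap["unique_position"] = -1
        for lg_id in gmap["lg"].unique():
            sel = gmap["lg"] == lg_id
            pos = gmap.loc[sel, "cM_avg"].round(9)
            codes_, _ = pd.factorize(pos, sort=True)
            gmap.loc[sel, "unique_position"] = codes_
        return LinkageMapResults(
            model=self,
            genetic_map=gmap,
            marker_filter=verdicts,
            interval_tables=interval_tables,
            clusters={lg: c for lg, c in clusters_by_lg.items()},
            unassigned=[m for m in unassigned if m not in set(gmap["marker_id"])],
        )


@dataclass
class LinkageMapResults:
    """Fitted linkage map with per-group summaries and diagnostics."""

    model: LinkageMapModel
    genetic_map: pd.DataFrame
    marker_filter: pd.DataFrame
    interval_tables: dict[int, pd.DataFrame]
    clusters: dict[int, object]
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return int(self.genetic_map["lg"].nunique())

    def group_markers(self, lg: int) -> list[str]:
        sel = self.genetic_map[self.genetic_map["lg"] == lg]
        return sel.sort_values("order")["marker_id"].tolist()

    def summary_by_lg(self) -> pd.DataFrame:
        """Per-group marker counts, unique positions, lengths, intervals,
        female/male lengths with the G-test, and the F:M length ratio."""
        n_off = sum(len(f.offspring_ids) for f in self.model.pedigrees)
        rows = []
        for lg, sub in self.genetic_map.groupby("lg"):
            n_unique = int(sub["unique_position"].nunique())
            length = float(sub["cM_avg"].max())
            xo = self.interval_tables[lg].attrs.get("crossovers", {})
            gres = sex_difference_gtest(
                self.interval_tables[lg],
                length_female=float(sub["cM_female"].max()),
                length_male=float(sub["cM_male"].max()),
                meioses_female=xo.get("meioses_f", n_off),
                meioses_male=xo.get("meioses_m", n_off),
            )
            rows.append(
                {
                    "lg": lg,
                    "n_markers": len(sub),
                    "unique_positions": n_unique,
                    "length_cM": length,
                    "marker_interval": length / n_unique if n_unique else float("nan"),
                    "length_female": gres["length_female"],
                    "length_male": gres["length_male"],
                    "fm_ratio": gres["fm_ratio"],
                    "G": gres["G"],
                    "pvalue": gres["pvalue"],
                }
            )
        return pd.DataFrame(rows).set_index("lg")

    def total_lengths(self) -> dict[str, float]:
        s = self.summary_by_lg()
        return {
            "sex_average": float(s["length_cM"].sum()),
            "female": float(s["length_female"].sum()),
            "male": float(s["length_male"].sum()),
        }

    def summary(self) -> str:
        s = self.summary_by_lg()
        tot = self.total_lengths()
        lines = [
            "Linkage map summary",
            "===================",
            f"families: {len(self.model.pedigrees)}    "
            f"markers mapped: {len(self.genetic_map)}    "
            f"linkage groups: {self.n_groups}",
            f"total length (cM): sex-average {tot['sex_average']:.1f}, "
            f"female {tot['female']:.1f}, male {tot['male']:.1f}",
            "",
            s.round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from ..io import write_map_tsv

        write_map_tsv(path, self)

    def plot(self, ax=None):
        """Marker-index vs position dot plot, one panel track per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for lg, sub in self.genetic_map.groupby("lg"):
            sub = sub.sort_values("order")
            ax.plot(sub["order"].to_numpy(), sub["cM_avg"].to_numpy(), ".", ms=2, label=f"LG{lg}")
        ax.set_xlabel("marker order")
        ax.set_ylabel("sex-average position (cM)")
        ax.legend(fontsize=7, ncol=2)
        return ax
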