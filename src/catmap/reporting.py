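"""Recomputation of the published array and map summary tables.

The packaged TSV fixtures transcribe the printed composition and map
summary tables exactly as published (thousands separators and the printed
rounding included).  Every derivable quantity — probe totals, category
sums, polymorphic/converted roll-ups and rates, per-group marker
intervals, female-minus-male differences, and F:M ratios — is recomputed
from the raw cells and compared against the printed value.  Printed
internal inconsistencies are *surfaced*, never silently reconciled: each
report carries a ``discrepancies`` list with both values.

Rounding convention: half-up to the printed precision of each cell.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

__all__ = [
    "load_fixture",
    "parse_count",
    "parse_count_pct",
    "round_half_up",
    "recompute_table3",
    "recompute_table4",
    "recompute_tables56",
    "full_report",
]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table fixture ('table3' ... 'table6') as strings."""
    ref = resources.files("catmap.data").joinpath(f"{name}.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def parse_count(cell: str) -> int:
    return int(str(cell).replace(",", "").strip())


def parse_float(cell: str) -> float:
    return float(str(cell).replace(",", "").strip())


def parse_count_pct(cell: str) -> tuple[int, float | None]:
    """Parse cells like '292,185 (42.1%)' into (count, percent)."""
    cell = str(cell).strip()
    if "(" not in cell:
        return parse_count(cell), None
    num, pct = cell.split("(")
    return parse_count(num), float(pct.strip().rstrip(")%"))


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _printed_decimals(cell: str) -> int:
    cell = str(cell).strip()
    return len(cell.split(".")[1]) if "." in cell else 0


def recompute_table3(fixture: pd.DataFrame | None = None) -> dict:
    """Array composition arithmetic: probe totals and category sums."""
    df = fixture if fixture is not None else load_fixture("table3")
    vals = {row["label"]: parse_count(row["value"]) for _, row in df.iterrows()}
    if not vals:
        return {"total_snps": 0, "total_probes": 0, "discrepancies": []}
    out = {
        "total_snps_printed": vals["Total number of SNPs on array"],
        "total_snps_from_genic": vals["Number of genic SNPs"] + vals["Number of intergenic SNPs"],
        "total_snps_from_probes": (
            vals["Number of SNPs tiled with single probe"]
            + vals["Number of SNPs tiled with two probes"]
        ),
        "total_snps_from_categories": (
            vals["Channel catfish-specific SNPs"]
            + vals["Blue catfish-specific SNPs"]
            + vals["Inter-species SNPs"]
            + vals["Channel-blue both possessed"]
        ),
        "total_probes": (
            vals["Number of SNPs tiled with single probe"]
            + 2 * vals["Number of SNPs tiled with two probes"]
        ),
        "strain_specific_printed": vals["Strain-specific SNPs"],
        "strain_specific_from_parts": (
            vals["Domesticate strain (Thompson)"]
            + vals["Domesticate strain (Hatchery)"]
            + vals["Domesticate strain (Marion)"]
            + vals["Domesticate strain (USDA 103)"]
            + vals["Wild population"]
        ),
    }
    disc = []
    for computed, printed in (
        ("total_snps_from_genic", "total_snps_printed"),
        ("total_snps_from_probes", "total_snps_printed"),
        ("total_snps_from_categories", "total_snps_printed"),
        ("strain_specific_from_parts", "strain_specific_printed"),
    ):
        if out[computed] != out[printed]:
            disc.append({"quantity": computed, "computed": out[computed], "printed": out[printed]})
    out["discrepancies"] = disc
    out["consistent"] = not disc
    return out


def recompute_table4(fixture: pd.DataFrame | None = None, probe_total: int | None = None) -> dict:
    """Conversion-performance arithmetic per sample panel.

    Rates are recomputed against the array probe total (from the
    composition table unless overridden).  The known 100-unit internal
    inconsistency in one panel's polymorphic total is reported in
    ``discrepancies``, not corrected.
    """
    df = fixture if fixture is not None else load_fixture("table4")
    if probe_total is None:
        probe_total = recompute_table3()["total_probes"]
    cols = [c for c in df.columns if c != "metric"]
    table = {row["metric"]: {c: row[c] for c in cols} for _, row in df.iterrows()}
    out: dict = {"columns": {}, "discrepancies": [], "probe_total": probe_total}
    for c in cols:
        poly_hr, _ = parse_count_pct(table["PolyHighResolution"][c])
        nmh, _ = parse_count_pct(table["NoMinorHom"][c])
        mono, _ = parse_count_pct(table["MonoHighResolution"][c])
        poly_printed, poly_pct = parse_count_pct(table["Total Polymorphic SNPs"][c])
        conv_printed, conv_pct = parse_count_pct(table["Total converted SNPs"][c])
        processed, _ = parse_count_pct(table["Samples processed"][c])
        passed, passed_pct = parse_count_pct(table["Samples passed QC"][c])
        col = {
            "polymorphic_computed": poly_hr + nmh,
            "polymorphic_printed": poly_printed,
            "converted_computed": poly_printed + mono,
            "converted_printed": conv_printed,
            "polymorphic_rate": 100.0 * poly_printed / probe_total,
            "converted_rate": 100.0 * conv_printed / probe_total,
            "samples_processed": processed,
            "samples_passed": passed,
            "sample_pass_rate": 100.0 * passed / processed,
        }
        if col["polymorphic_computed"] != poly_printed:
            out["discrepancies"].append(
                {
                    "column": c,
                    "quantity": "polymorphic",
                    "computed": col["polymorphic_computed"],
                    "printed": poly_printed,
                    "difference": poly_printed - col["polymorphic_computed"],
                }
            )
        if col["converted_computed"] != conv_printed:
            out["discrepancies"].append(
                {
                    "column": c,
                    "quantity": "converted",
                    "computed": col["converted_computed"],
                    "printed": conv_printed,
                }
            )
        for name, computed, printed in (
            ("polymorphic_rate", col["polymorphic_rate"], poly_pct),
            ("converted_rate", col["converted_rate"], conv_pct),
            ("sample_pass_rate", col["sample_pass_rate"], passed_pct),
        ):
            if printed is not None and round_half_up(computed, 1) != printed:
                out["discrepancies"].append(
                    {"column": c, "quantity": name,
                     "computed": round_half_up(computed, 1), "printed": printed}
                )
        out["columns"][c] = col
    out["consistent"] = not out["discrepancies"]
    return out


def recompute_tables56(
    fixture5: pd.DataFrame | None = None, fixture6: pd.DataFrame | None = None
) -> dict:
    """Map-summary arithmetic: intervals, totals, F-M contrast, ratios."""
    t5 = fixture5 if fixture5 is not None else load_fixture("table5")
    t6 = fixture6 if fixture6 is not None else load_fixture("table6")
    disc = []

    body5 = t5[t5["lg"] != "Total"]
    total5 = t5[t5["lg"] == "Total"].iloc[0]
    markers = body5["mapped_markers"].map(parse_count)
    unique = body5["unique_positions"].map(parse_count)
    length = body5["length_cM"].map(parse_float)
    interval_printed = body5["marker_interval"].map(parse_float)
    per_lg5 = pd.DataFrame(
        {
            "lg": body5["lg"].astype(int).to_numpy(),
            "mapped_markers": markers.to_numpy(),
            "unique_positions": unique.to_numpy(),
            "length_cM": length.to_numpy(),
            "interval_computed": [
                round_half_up(l / u, 2) for l, u in zip(length, unique)
            ],
            "interval_printed": interval_printed.to_numpy(),
        }
    )
    for _, row in per_lg5.iterrows():
        if row["interval_computed"] != row["interval_printed"]:
            disc.append(
                {"table": "sex_average", "lg": int(row["lg"]), "quantity": "marker_interval",
                 "computed": row["interval_computed"], "printed": row["interval_printed"]}
            )
    totals5 = {
        "mapped_markers": int(markers.sum()),
        "mapped_markers_printed": parse_count(total5["mapped_markers"]),
        "unique_positions": int(unique.sum()),
        "unique_positions_printed": parse_count(total5["unique_positions"]),
        "length_cM": float(length.sum()),
        "length_cM_printed": parse_float(total5["length_cM"]),
        "interval_computed": round_half_up(float(length.sum()) / int(unique.sum()), 2),
        "markers_per_unique_position": float(markers.sum()) / float(unique.sum()),
    }
    for a, b in (
        ("mapped_markers", "mapped_markers_printed"),
        ("unique_positions", "unique_positions_printed"),
    ):
        if totals5[a] != totals5[b]:
            disc.append({"table": "sex_average", "quantity": a,
                         "computed": totals5[a], "printed": totals5[b]})
    if round_half_up(totals5["length_cM"], 3) != totals5["length_cM_printed"]:
        disc.append({"table": "sex_average", "quantity": "length_cM",
                     "computed": round_half_up(totals5["length_cM"], 3),
                     "printed": totals5["length_cM_printed"]})

    body6 = t6[t6["lg"] != "Total"]
    total6 = t6[t6["lg"] == "Total"].iloc[0]
    f_len = body6["f_length_cM"].map(parse_float)
    m_len = body6["m_length_cM"].map(parse_float)
    ratio_printed = body6["fm_ratio"].map(parse_float)
    per_lg6 = pd.DataFrame(
        {
            "lg": body6["lg"].astype(int).to_numpy(),
            "f_length_cM": f_len.to_numpy(),
            "m_length_cM": m_len.to_numpy(),
            "ratio_computed": [round_half_up(f / m, 2) for f, m in zip(f_len, m_len)],
            "ratio_printed": ratio_printed.to_numpy(),
        }
    )
    for _, row in per_lg6.iterrows():
        if abs(row["ratio_computed"] - row["ratio_printed"]) > 1e-9:
            disc.append(
                {"table": "sex_specific", "lg": int(row["lg"]), "quantity": "fm_ratio",
                 "computed": row["ratio_computed"], "printed": row["ratio_printed"]}
            )
    totals6 = {
        "f_length_cM": float(f_len.sum()),
        "f_length_printed": parse_float(total6["f_length_cM"]),
        "m_length_cM": float(m_len.sum()),
        "m_length_printed": parse_float(total6["m_length_cM"]),
        "f_unique_positions": int(body6["f_unique_positions"].map(parse_count).sum()),
        "f_unique_printed": parse_count(total6["f_unique_positions"]),
        "m_unique_positions": int(body6["m_unique_positions"].map(parse_count).sum()),
        "m_unique_printed": parse_count(total6["m_unique_positions"]),
    }
    fm_diff = totals6["f_length_printed"] - totals6["m_length_printed"]
    totals6["fm_difference_cM"] = round_half_up(fm_diff, 1)
    totals6["fm_ratio_2dp"] = round_half_up(
        totals6["f_length_printed"] / totals6["m_length_printed"], 2
    )
    totals6["fm_ratio_1dp"] = round_half_up(
        totals6["f_length_printed"] / totals6["m_length_printed"], 1
    )
    totals6["fm_ratio_printed"] = parse_float(total6["fm_ratio"])
    totals6["fm_ratio_range"] = (
        float(per_lg6["ratio_printed"].min()),
        float(per_lg6["ratio_printed"].max()),
    )
    return {
        "sex_average": {"per_lg": per_lg5, "totals": totals5},
        "sex_specific": {"per_lg": per_lg6, "totals": totals6},
        "discrepancies": disc,
        "consistent": not disc,
    }


def full_report() -> dict:
    """All three recomputation reports, JSON-serialisable except frames."""
    return {
        "array_composition": recompute_table3(),
        "conversion_performance": recompute_table4(),
        "map_summaries": recompute_tables56(),
    }
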