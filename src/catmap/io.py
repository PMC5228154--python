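"""Format readers and writers shared by the pipeline stages.

Internal coordinates are 1-based inclusive everywhere; BED is written and
read as 0-based half-open with conversion at this boundary only.  Variant
pools travel as minimal VCF (CHROM/POS/REF/ALT plus per-population
allele-frequency INFO fields), pedigrees with genotypes in the classic
pre-MAKEPED LINKAGE layout, genotype matrices and maps as TSV.  Every
tabular output starts with a provenance comment (tool version, seed,
config hash).
"""
from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import DataError
from .simulate.families import GenotypeMatrix, Pedigree
from .simulate.genome import GenomeModel
from .simulate.variants import CandidateSNP

__all__ = [
    "provenance_header",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_vcf",
    "read_vcf",
    "write_linkage_ped",
    "read_linkage_ped",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_map_tsv",
    "write_agp_file",
    "read_agp_file",
]


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    digest = hashlib.md5(blob).hexdigest()[:12]
    return f"# catmap v{__version__} seed={seed} config_hash={digest}"


def write_fasta(genome: GenomeModel, path) -> None:
    if genome.sequences is None:
        raise DataError("genome has no base sequence to write")
    records = [
        SeqRecord(Seq(genome.sequences[sid]), id=sid, description=f"length={length}")
        for sid, length in genome.scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> GenomeModel:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise DataError(f"no sequences in {path}")
    return GenomeModel({sid: len(s) for sid, s in seqs.items()}, {}, {}, seqs)


def write_bed(intervals: dict[str, list[tuple[int, int]]], path, name: str = "feature",
              seed: int | None = None, config: dict | None = None) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        for sid in intervals:
            for k, (start, end) in enumerate(intervals[sid]):
                fh.write(f"{sid}\t{start - 1}\t{end}\t{name}_{k + 1}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED back to 1-based inclusive intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]) + 1, int(f[2])))
    return out


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def write_vcf(snps: list[CandidateSNP], genome: GenomeModel, path,
              seed: int | None = None, config: dict | None = None) -> None:
    """Minimal VCF with per-population AF INFO fields plus GENIC/SRC."""
    pops = sorted({p for s in snps for p in s.per_population_freqs})
    header = pysam.VariantHeader()
    header.add_meta("source", f"catmap v{__version__}")
    header.add_meta("catmap_provenance", provenance_header(seed, config).lstrip("# "))
    for sid, length in genome.scaffolds.items():
        header.contigs.add(sid, length=length)
    for p in pops:
        header.info.add(f"AF_{_safe(p)}", 1, "Float", f"Alternate allele frequency in {p}")
    header.info.add("GENIC", 0, "Flag", "SNP lies in an annotated gene")
    header.info.add("SRC", 1, "String", "SNP source class")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(snps, key=lambda x: (x.scaffold_id, x.pos)):
            rec = vcf.new_record(
                contig=s.scaffold_id,
                start=s.pos - 1,
                stop=s.pos,
                alleles=tuple([s.ref_allele] + list(s.alt_alleles)),
                id=s.snp_id,
            )
            for p, f in s.per_population_freqs.items():
                rec.info[f"AF_{_safe(p)}"] = float(f)
            if s.genic:
                rec.info["GENIC"] = True
            rec.info["SRC"] = s.source
            vcf.write(rec)


def read_vcf(path, genome: GenomeModel | None = None) -> list[CandidateSNP]:
    """Read a variant pool; flanks are re-extracted when a genome is given."""
    snps: list[CandidateSNP] = []
    with pysam.VariantFile(str(path)) as vcf:
        pop_keys = [k for k in vcf.header.info if k.startswith("AF_")]
        for rec in vcf:
            freqs = {
                k[3:]: float(rec.info[k]) for k in pop_keys if k in rec.info
            }
            flank = None
            if genome is not None and genome.sequences is not None:
                length = genome.scaffolds.get(rec.contig, 0)
                if 36 <= rec.pos <= length - 35:
                    flank = genome.fetch(rec.contig, rec.pos - 35, rec.pos + 35)
            snps.append(
                CandidateSNP(
                    snp_id=rec.id or f"{rec.contig}_{rec.pos}",
                    scaffold_id=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or ()),
                    flank=flank,
                    per_population_freqs=freqs,
                    genic=bool(rec.info.get("GENIC", False)),
                    source=str(rec.info.get("SRC", "genome")),
                )
            )
    return snps


_GENO_TO_ALLELES = {0: "1 1", 1: "1 2", 2: "2 2", -1: "0 0"}


def write_linkage_ped(matrix: GenotypeMatrix, path) -> None:
    """Pre-MAKEPED LINKAGE pedigree: fam, id, father, mother, sex,
    phenotype, then one allele pair per marker (0 0 = missing)."""
    parent_sex: dict[str, int] = {}
    fam_of: dict[str, tuple[str, str, str]] = {}
    for fam in matrix.pedigrees:
        parent_sex[fam.sire_id] = 1
        parent_sex[fam.dam_id] = 2
        for oid in fam.offspring_ids:
            fam_of[oid] = (fam.family_id, fam.sire_id, fam.dam_id)
    with open(path, "w") as fh:
        for fam in matrix.pedigrees:
            for sid in (fam.sire_id, fam.dam_id):
                row = matrix.row(sid)
                geno = " ".join(_GENO_TO_ALLELES[int(g)] for g in row)
                fh.write(f"{fam.family_id} {sid} 0 0 {parent_sex[sid]} 0 {geno}\n")
            for oid in fam.offspring_ids:
                row = matrix.row(oid)
                geno = " ".join(_GENO_TO_ALLELES[int(g)] for g in row)
                fh.write(f"{fam.family_id} {oid} {fam.sire_id} {fam.dam_id} 0 0 {geno}\n")


def read_linkage_ped(path) -> tuple[list[Pedigree], GenotypeMatrix]:
    """Read a pre-MAKEPED LINKAGE file back into pedigrees + genotypes.

    Marker names are not part of the format; generic ids m0001.. are
    assigned in column order.  Parents written twice (shared sires) are
    de-duplicated.
    """
    fams: dict[str, dict] = {}
    samples: list[str] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    allele_to_code = {("1", "1"): 0, ("1", "2"): 1, ("2", "1"): 1, ("2", "2"): 2}
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            fam_id, iid, father, mother = f[0], f[1], f[2], f[3]
            genos = f[6:]
            if len(genos) % 2:
                raise DataError("odd allele count in pedigree line")
            codes = [
                allele_to_code.get((genos[i], genos[i + 1]), -1)
                for i in range(0, len(genos), 2)
            ]
            entry = fams.setdefault(fam_id, {"sire": None, "dam": None, "offspring": []})
            if father == "0" and mother == "0":
                if f[4] == "1":
                    entry["sire"] = iid
                else:
                    entry["dam"] = iid
            else:
                entry["sire"], entry["dam"] = father, mother
                entry["offspring"].append(iid)
            if iid not in seen:
                seen.add(iid)
                samples.append(iid)
                rows.append(codes)
    pedigrees = [
        Pedigree(fid, e["sire"], e["dam"], e["offspring"]) for fid, e in fams.items()
    ]
    n_markers = len(rows[0]) if rows else 0
    marker_ids = [f"m{j + 1:04d}" for j in range(n_markers)]
    return pedigrees, GenotypeMatrix(samples, marker_ids, np.array(rows, dtype=np.int8), pedigrees)


def write_genotype_tsv(matrix: GenotypeMatrix, path,
                       seed: int | None = None, config: dict | None = None) -> None:
    """Markers as rows, samples as columns, dosage codes (-1 missing)."""
    df = pd.DataFrame(matrix.codes.T, index=matrix.marker_ids, columns=matrix.sample_ids)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, sep="\t", index_label="marker_id")


def read_genotype_tsv(path, pedigrees: list[Pedigree] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="marker_id")
    return GenotypeMatrix(
        list(df.columns),
        list(df.index),
        df.to_numpy(dtype=np.int8).T,
        pedigrees or [],
    )


def write_map_tsv(path, results, seed: int | None = None, config: dict | None = None) -> None:
    """Genetic map: marker, LG, order, positions, unique-position id."""
    cols = [
        "marker_id", "lg", "order", "cM_avg", "cM_female", "cM_male",
        "unique_position", "representative",
    ]
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        results.genetic_map[cols].to_csv(fh, sep="\t", index=False)


def write_agp_file(rows, path, seed: int | None = None, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        fh.write(provenance_header(seed, config) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_agp_file(path):
    from .integration import parse_agp

    with open(path) as fh:
        return parse_agp(fh)
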