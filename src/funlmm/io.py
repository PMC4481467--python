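"""File readers and writers: VCF / dosage-matrix genotypes, phenotype
tables, region definitions, and export of simulated datasets."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .regional import Region, region_from_dosages

log = logging.getLogger("funlmm")


def read_phenotype(path, trait: str, covariates: list[str] | None = None,
                   id_column: str | None = None):
    """Whitespace phenotype table with a header row.

    Returns ``(ids, y, X)`` where X carries an intercept plus the named
    covariate columns.  Individuals with missing ("NA") trait values are
    dropped.
    """
    df = pd.read_csv(path, sep=r"\s+")
    idcol = id_column or df.columns[0]
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype file")
    covariates = covariates or []
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate column {c!r} not in phenotype file")
    y = pd.to_numeric(df[trait], errors="coerce")
    keep = y.notna()
    if (~keep).any():
        log.info("dropping %d individuals with missing phenotype",
                 int((~keep).sum()))
    df = df[keep]
    ids = df[idcol].astype(str).tolist()
    yv = y[keep].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    return ids, yv, X


def read_region_definitions(path) -> pd.DataFrame:
    """BED-like region file: chrom, start, end, name (whitespace).
    Coordinates are 1-based inclusive."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], dtype={0: str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["name"] = df["name"].astype(str)
    return df


def _regions_from_records(records, region_defs, sample_ids, requested_ids):
    """records: iterable of (chrom, pos, vid, dosages-over-sample)."""
    order = _sample_indexer(sample_ids, requested_ids)
    per_region: dict[str, list] = {r: [] for r in region_defs["name"]}
    defs = list(region_defs.itertuples(index=False))
    n_mono = 0
    for chrom, pos, vid, dos in records:
        for d in defs:
            if d.chrom == str(chrom) and d.start <= pos <= d.end:
                dose = dos[order]
                filled = np.where(np.isnan(dose), np.nanmean(dose), dose)
                if np.ptp(filled) == 0:
                    n_mono += 1
                else:
                    per_region[d.name].append((pos, vid, dose))
    if n_mono:
        log.info("dropped %d monomorphic variants", n_mono)
    regions = []
    for d in defs:
        entries = per_region[d.name]
        if not entries:
            log.warning("region %s has no polymorphic variants", d.name)
            continue
        entries.sort(key=lambda e: e[0])
        positions = [e[0] for e in entries]
        vids = [e[1] for e in entries]
        G = np.column_stack([e[2] for e in entries])
        regions.append(region_from_dosages(d.name, G, positions, vids))
    return regions


def _sample_indexer(sample_ids, requested_ids) -> np.ndarray:
    pos = {s: i for i, s in enumerate(sample_ids)}
    missing = [s for s in requested_ids if s not in pos]
    if missing:
        raise ValueError(
            "samples in phenotype but not in genotype source: "
            + ", ".join(missing[:10])
        )
    return np.array([pos[s] for s in requested_ids])


def read_genotypes_vcf(path, region_defs: pd.DataFrame, requested_ids):
    """Regions from a VCF (GT field).  Multi-allelic records are skipped
    with a warning; missing genotypes are mean-imputed; dosages are
    oriented to the minor allele downstream."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)

    def records():
        for v in vcf:
            if len(v.ALT) != 1:
                log.warning("skipping multi-allelic record %s:%d", v.CHROM, v.POS)
                continue
            gt = np.asarray(v.gt_types, dtype=float)
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            dose = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
            vid = v.ID or f"{v.CHROM}:{v.POS}"
            yield v.CHROM, v.POS, vid, dose

    return _regions_from_records(records(), region_defs, samples, requested_ids)


def read_genotypes_matrix(path, region_defs: pd.DataFrame, requested_ids):
    """Regions from a plain dosage matrix.

    Whitespace table; header ``id chrom pos ind1 ind2 ...``; one row per
    variant with dosages 0/1/2 (NA allowed).
    """
    df = pd.read_csv(path, sep=r"\s+")
    fixed = ["id", "chrom", "pos"]
    if list(df.columns[:3]) != fixed:
        raise ValueError("dosage matrix must start with columns id chrom pos")
    samples = [str(c) for c in df.columns[3:]]
    dos = df.iloc[:, 3:].to_numpy(dtype=float)

    def records():
        for k in range(len(df)):
            yield (str(df["chrom"].iloc[k]), int(df["pos"].iloc[k]),
                   str(df["id"].iloc[k]), dos[k])

    return _regions_from_records(records(), region_defs, samples, requested_ids)


def read_genotypes(source, region_defs, requested_ids):
    """Dispatch on file type (``.vcf``/``.vcf.gz`` vs dosage matrix)."""
    s = str(source)
    if s.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_genotypes_vcf(source, region_defs, requested_ids)
    return read_genotypes_matrix(source, region_defs, requested_ids)


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.10g")


def export_dataset(ped: Pedigree, regions: list[Region], y, prefix,
                   chrom: str = "1") -> dict[str, str]:
    """Write a simulated dataset as VCF + FAM + phenotype + region files.

    Regions are laid out on one chromosome with disjoint 1 Mb offsets.
    Returns the written paths.
    """
    from .pedigree import write_fam

    prefix = str(prefix)
    paths = {
        "vcf": prefix + ".vcf",
        "fam": prefix + ".fam",
        "pheno": prefix + ".pheno",
        "regions": prefix + ".regions",
    }
    offset = 1_000_000
    with open(paths["vcf"], "w") as fh, open(paths["regions"], "w") as rh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ped.ids) + "\n")
        for k, region in enumerate(regions):
            base = (k + 1) * offset
            raw = region.positions.raw.astype(int)
            rh.write(f"{chrom} {base + raw[0]} {base + raw[-1]} {region.name}\n")
            codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j in range(region.m):
                gts = "\t".join(
                    codes[int(round(g))] for g in region.G[:, j]
                )
                fh.write(f"{chrom}\t{base + raw[j]}\t{region.variant_ids[j]}"
                         f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    write_fam(ped, paths["fam"])
    with open(paths["pheno"], "w") as fh:
        fh.write("id trait\n")
        for iid, val in zip(ped.ids, np.asarray(y, dtype=float)):
            fh.write(f"{iid} {val:.10g}\n")
    return paths
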