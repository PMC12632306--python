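"""Reading and writing variant tables (VCF 4.2 / flat TSV) and VAF arithmetic.

A variant table holds, for one or more twin families, per-sample read depths
and alternate-allele counts at every candidate site, in long format.  Variant
identifiers are canonical ``chrom:pos:ref:alt`` strings so that the flat TSV
representation is self-describing.  A VAF (variant allele fraction) is
``alt / depth``; a site with zero depth has a *missing* VAF, which is kept
distinct from a VAF of zero throughout the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

TSV_COLUMNS = ["family", "variant", "sample", "depth", "alt", "vaf"]

_VARIANT_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGT]+):(?P<alt>[ACGT]+)$")


class VariantTableError(ValueError):
    """Malformed variant table content or file."""


def vaf_from_counts(alt, depth):
    """Variant allele fraction ``alt / depth``; NaN where depth is zero.

    Accepts scalars or array-likes.  Raises ``ValueError`` if any alt count
    exceeds its depth or either is negative.
    """
    alt_a = np.asarray(alt, dtype=float)
    depth_a = np.asarray(depth, dtype=float)
    if np.any(alt_a < 0) or np.any(depth_a < 0):
        raise ValueError("alt and depth must be non-negative")
    if np.any(alt_a > depth_a):
        raise ValueError("alt count exceeds depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth_a > 0, alt_a / np.where(depth_a > 0, depth_a, 1), np.nan)
    if np.isscalar(alt) and np.isscalar(depth):
        return float(vaf)
    return vaf


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    """Split a canonical ``chrom:pos:ref:alt`` identifier."""
    m = _VARIANT_ID_RE.match(variant_id)
    if m is None:
        raise VariantTableError(f"variant id not in chrom:pos:ref:alt form: {variant_id!r}")
    return m["chrom"], int(m["pos"]), m["ref"], m["alt"]


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class VariantTable:
    """Long-format variant x sample read counts for a set of families.

    Attributes
    ----------
    counts:
        DataFrame with columns ``family, variant, sample, depth, alt, vaf``.
    samples:
        Sample identifiers in their original column order.
    parent_flags:
        Optional DataFrame indexed by variant id with boolean columns
        ``mother`` and ``father`` marking parental presence; ``None`` when
        flags are to be derived from parental sample rows.
    """

    counts: pd.DataFrame
    samples: list[str] = field(default_factory=list)
    parent_flags: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = self.counts.reset_index(drop=True)
        if not self.samples:
            self.samples = list(pd.unique(self.counts["sample"]))
        self.validate()

    def validate(self) -> None:
        df = self.counts
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise VariantTableError(f"missing columns: {missing}")
        for fam in pd.unique(df["family"]):
            if not str(fam).isascii():
                raise VariantTableError(f"non-ASCII family id: {fam!r}")
        if (df["depth"] < 0).any() or (df["alt"] < 0).any():
            raise VariantTableError("negative depth or alt count")
        if (df["alt"] > df["depth"]).any():
            bad = df.index[df["alt"] > df["depth"]][0]
            raise VariantTableError(f"alt exceeds depth at row {bad}")
        recomputed = vaf_from_counts(df["alt"].to_numpy(), df["depth"].to_numpy())
        stored = df["vaf"].to_numpy(dtype=float)
        mismatch = ~(
            (np.isnan(recomputed) & np.isnan(stored))
            | (np.abs(np.nan_to_num(recomputed - stored)) < 1e-9)
        )
        if mismatch.any():
            self.counts = df.assign(vaf=recomputed)

    # -- convenience views ------------------------------------------------

    @property
    def families(self) -> list[str]:
        return list(pd.unique(self.counts["family"]))

    def subset_family(self, family: str) -> "VariantTable":
        sub = self.counts[self.counts["family"] == family]
        flags = None
        if self.parent_flags is not None:
            flags = self.parent_flags.loc[
                self.parent_flags.index.intersection(pd.unique(sub["variant"]))
            ]
        keep = [s for s in self.samples if s in set(sub["sample"])]
        return VariantTable(sub.copy(), samples=keep, parent_flags=flags)

    def pivot(self, value: str) -> pd.DataFrame:
        """Variant x sample matrix of ``depth``, ``alt`` or ``vaf``."""
        wide = self.counts.pivot_table(
            index="variant", columns="sample", values=value, aggfunc="first", dropna=False
        )
        cols = [s for s in self.samples if s in wide.columns]
        return wide[cols]

    def variant_metadata(self) -> pd.DataFrame:
        ids = pd.unique(self.counts["variant"])
        rows = [parse_variant_id(v) for v in ids]
        meta = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"], index=ids)
        return meta


# -- TSV ------------------------------------------------------------------


def write_variant_table(table: VariantTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "vcf":
        _write_vcf(table, path)
    else:
        raise ValueError(f"unknown format: {format}")


def read_variant_table(path, format: str = "tsv") -> VariantTable:
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format: {format}")


def _write_tsv(table: VariantTable, path) -> None:
    df = table.counts[TSV_COLUMNS].copy()
    df["vaf"] = df["vaf"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "variant": str, "sample": str})
    if list(df.columns) != TSV_COLUMNS:
        raise VariantTableError(f"unexpected TSV header in {path}: {list(df.columns)}")
    if len(df):
        bad = df.index[df["alt"] > df["depth"]]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise VariantTableError(f"alt > depth at line {bad[0] + 2} of {path}")
        df["depth"] = df["depth"].astype(int)
        df["alt"] = df["alt"].astype(int)
        df["vaf"] = vaf_from_counts(df["alt"].to_numpy(), df["depth"].to_numpy())
    else:
        df = df.astype({"depth": int, "alt": int, "vaf": float})
    return VariantTable(df)


# -- VCF ------------------------------------------------------------------


def _write_vcf(table: VariantTable, path) -> None:
    """One family per VCF 4.2 file, AD/DP per sample, flags in INFO."""
    fams = table.families
    if len(fams) > 1:
        raise VariantTableError("VCF output is one family per file; subset first")
    family = fams[0] if fams else "NA"

    header = pysam.VariantHeader()
    header.add_line(f"##twinlin_family={family}")
    header.info.add("MOTHER", 0, "Flag", "Variant detected in the mother")
    header.info.add("FATHER", 0, "Flag", "Variant detected in the father")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")

    meta = table.variant_metadata() if len(table.counts) else pd.DataFrame()
    for chrom in pd.unique(meta["chrom"]) if len(meta) else []:
        header.contigs.add(str(chrom))
    for s in table.samples:
        header.add_sample(s)

    depth = table.pivot("depth") if len(table.counts) else pd.DataFrame()
    alt = table.pivot("alt") if len(table.counts) else pd.DataFrame()

    with pysam.VariantFile(str(path), "w", header=header) as out:
        if len(meta) == 0:
            return
        order = meta.sort_values(["chrom", "pos"]).index
        for vid in order:
            chrom, pos, ref, alt_allele = meta.loc[vid, ["chrom", "pos", "ref", "alt"]]
            rec = out.new_record(
                contig=str(chrom), start=int(pos) - 1, alleles=(ref, alt_allele), id=vid
            )
            rec.stop = int(pos) - 1 + len(ref)
            if table.parent_flags is not None and vid in table.parent_flags.index:
                if bool(table.parent_flags.loc[vid, "mother"]):
                    rec.info["MOTHER"] = True
                if bool(table.parent_flags.loc[vid, "father"]):
                    rec.info["FATHER"] = True
            for s in table.samples:
                d = int(depth.loc[vid, s]) if not pd.isna(depth.loc[vid, s]) else 0
                a = int(alt.loc[vid, s]) if not pd.isna(alt.loc[vid, s]) else 0
                rec.samples[s]["DP"] = d
                rec.samples[s]["AD"] = (d - a, a)
                rec.samples[s]["GT"] = (0, 1) if a > 0 else ((0, 0) if d > 0 else (None,))
            out.write(rec)


def _read_vcf(path) -> VariantTable:
    rows = []
    flags = {}
    with pysam.VariantFile(str(path)) as vcf:
        family = "NA"
        for line in str(vcf.header).splitlines():
            if line.startswith("##twinlin_family="):
                family = line.split("=", 1)[1]
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.id is None:
                vid = make_variant_id(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            else:
                vid = rec.id
            flags[vid] = (bool(rec.info.get("MOTHER", False)), bool(rec.info.get("FATHER", False)))
            for s in samples:
                fmt = rec.samples[s]
                if "DP" not in fmt or fmt.get("AD") is None:
                    raise VariantTableError(f"record {vid} lacks AD/DP for sample {s}")
                d = fmt["DP"] if fmt["DP"] is not None else 0
                ad = fmt["AD"]
                a = int(ad[1]) if ad[1] is not None else 0
                rows.append((family, vid, s, int(d), a))
    df = pd.DataFrame(rows, columns=["family", "variant", "sample", "depth", "alt"])
    if len(df):
        df["vaf"] = vaf_from_counts(df["alt"].to_numpy(), df["depth"].to_numpy())
    else:
        df = df.assign(vaf=pd.Series(dtype=float))
    flag_df = pd.DataFrame.from_dict(flags, orient="index", columns=["mother", "father"])
    return VariantTable(df, samples=samples, parent_flags=flag_df if len(flag_df) else None)
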