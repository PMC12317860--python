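"""VCF and sample-metadata input/output.

Reading goes through cyvcf2; writing emits plain GT-only VCF 4.2 text.
Only biallelic SNPs are kept — multi-allelic or indel records are skipped
with a logged warning and counted, never split.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    UNKNOWN_NAME,
    EmptyInputError,
    GenotypeMatrix,
    ParameterError,
    is_unknown_name,
    make_site_table,
    normalise_name,
)

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


class VcfParseError(ParameterError):
    pass


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into (GenotypeMatrix, site table).

    Diploid GT is parsed to alternate-allele dosage; ``./.`` and ``.|.``
    (and half-calls) map to MISSING; phasing is ignored. Returns sites
    sorted by (chrom, pos). Raises :class:`EmptyInputError` when no
    biallelic SNP records survive.
    """
    import cyvcf2

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    try:
        for v in vcf:
            if (
                len(v.ALT) != 1
                or v.REF not in _BASES
                or v.ALT[0] not in _BASES
            ):
                n_skipped += 1
                logger.warning(
                    "skipping non-biallelic-SNP record %s:%s", v.CHROM, v.POS
                )
                continue
            row = np.empty(len(samples), dtype=np.int8)
            for i, g in enumerate(v.genotypes):
                a, b = g[0], g[1] if len(g) > 2 else -1
                row[i] = MISSING if (a < 0 or b < 0) else a + b
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0])
            rows.append(row)
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path} near record {len(rows) + n_skipped + 1}: {exc}"
        ) from exc

    if not rows:
        raise EmptyInputError(f"no biallelic SNP records in {path}")
    if n_skipped:
        logger.warning("%d non-biallelic-SNP records skipped", n_skipped)

    sites = make_site_table(chrom, pos, ref, alt)
    calls = np.vstack(rows).T  # samples x sites, in original record order
    # make_site_table sorts by (chrom, pos); reorder the columns to match
    order = (
        pd.DataFrame({"chrom": chrom, "pos": pos})
        .sort_values(["chrom", "pos"], kind="stable")
        .index.to_numpy()
    )
    calls = calls[:, order]
    return GenotypeMatrix(calls, samples), sites


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, sites: pd.DataFrame, path) -> str:
    """Write a GT-only VCF 4.2 file; MISSING becomes ``./.``."""
    if len(sites) != G.n_sites:
        raise ParameterError(
            f"site table has {len(sites)} rows for {G.n_sites} matrix columns"
        )
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(sites["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, site in enumerate(sites.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(g)] for g in G.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def read_sample_metadata(path, vcf_sample_ids=None) -> pd.DataFrame:
    """Read the sample-metadata TSV.

    Expected columns: ``sample_id``, ``cultivar_name`` and optionally
    ``synonym_group``. Adds ``name_key`` (trimmed, case-folded, for
    matching; the original name is preserved) and ``is_unknown``. When
    ``vcf_sample_ids`` is given, every one of them must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"sample_id", "cultivar_name"}
    if not required.issubset(df.columns):
        raise ParameterError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParameterError(f"duplicate sample ids in metadata: {dups}")
    if "synonym_group" not in df.columns:
        df["synonym_group"] = ""
    df["synonym_group"] = df["synonym_group"].str.strip()
    df["is_unknown"] = df["cultivar_name"].map(is_unknown_name)
    df.loc[df["is_unknown"], "cultivar_name"] = UNKNOWN_NAME
    df["name_key"] = df["cultivar_name"].map(normalise_name)
    df.loc[df["is_unknown"], "name_key"] = ""
    if vcf_sample_ids is not None:
        missing = sorted(set(vcf_sample_ids) - set(df["sample_id"]))
        if missing:
            raise ParameterError(
                f"samples present in genotypes but absent from metadata: {missing}"
            )
    return df.reset_index(drop=True)


def write_sample_metadata(samples: pd.DataFrame, path) -> str:
    cols = [c for c in ("sample_id", "cultivar_name", "synonym_group")
            if c in samples.columns]
    samples[cols].to_csv(path, sep="\t", index=False)
    return os.fspath(path)
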