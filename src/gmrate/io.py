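"""Readers and writers for the pipeline's on-disk formats.

* multi-sample VCF v4.2 (father, mother, offspring column order) with
  FORMAT GT:AD:DP:GQ and the GATK site annotations QD, FS, MQ,
  MQRankSum, ReadPosRankSum, SOR in INFO (plus CTX, the trinucleotide
  context, so simulated tables round-trip); read back with pysam;
* tab-separated metadata, DNM and trio-observation tables (pandas);
* Newick trees (dendropy);
* Ne trajectory TSV with columns (species, t_start_years, t_end_years, Ne).

Internal coordinates are 0-based half-open; VCF emission converts to
1-based and reading converts back.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pysam

from gmrate.calling import HET, HOM_ALT, HOM_REF, MISSING, SITE_COLUMNS
from gmrate.comparative import NeTrajectory

_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=gmrate
##contig=<ID={contig},length={length}>
##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMSMappingQuality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MappingQualityRankSumTest">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSumTest">
##INFO=<ID=SOR,Number=1,Type=Float,Description="StrandOddsRatio">
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context of the site">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{father}\t{mother}\t{offspring}
"""

ANN_NAMES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


def write_trio_vcf(sites: pd.DataFrame, path: str | Path, trio_id: str = "trio") -> Path:
    """Write a trio site table as an uncompressed all-sites VCF v4.2."""
    path = Path(path)
    contig = str(sites["chrom"].iloc[0]) if len(sites) else "chr1"
    length = int(sites["pos"].max()) + 1 if len(sites) else 1
    names = {ind: f"{trio_id}_{ind}" for ind in ("father", "mother", "offspring")}
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=length, **names))
        for _, r in sites.iterrows():
            info_parts = []
            for ann in ANN_NAMES:
                v = r[ann]
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    info_parts.append(f"{ann}={float(v):.4f}")
            ctx = r.get("context", "unknown")
            if isinstance(ctx, str) and ctx != "unknown":
                info_parts.append(f"CTX={ctx}")
            info = ";".join(info_parts) if info_parts else "."
            samples = []
            for ind in ("father", "mother", "offspring"):
                gt = _GT_TO_VCF[r[f"{ind}_gt"]]
                samples.append(
                    f"{gt}:{int(r[f'{ind}_ad_ref'])},{int(r[f'{ind}_ad_alt'])}"
                    f":{int(r[f'{ind}_dp'])}:{int(r[f'{ind}_gq'])}"
                )
            alt = r["alt"] if r["alt"] not in (".", "", None) else "."
            fh.write(
                f"{r['chrom']}\t{int(r['pos']) + 1}\t.\t{r['ref']}\t{alt}\t.\t.\t"
                f"{info}\tGT:AD:DP:GQ\t" + "\t".join(samples) + "\n"
            )
    return path


def _gt_from_tuple(gt: tuple) -> str:
    if gt is None or any(a is None for a in gt):
        return MISSING
    s = sum(gt)
    return {0: HOM_REF, 1: HET, 2: HOM_ALT}[s]


def read_trio_vcf(path: str | Path) -> pd.DataFrame:
    """Read a trio VCF (father, mother, offspring sample order) into a site table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 3:
            raise ValueError(f"expected 3 samples (father, mother, offspring); got {sample_names}")
        for rec in vcf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos - 1,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
            for ann in ANN_NAMES:
                v = rec.info.get(ann)
                row[ann] = float(v) if v is not None else np.nan
            row["context"] = str(rec.info.get("CTX", "unknown"))
            for ind, name in zip(("father", "mother", "offspring"), sample_names):
                smp = rec.samples[name]
                row[f"{ind}_gt"] = _gt_from_tuple(smp.get("GT"))
                ad = smp.get("AD") or (0, 0)
                row[f"{ind}_ad_ref"] = int(ad[0] or 0)
                row[f"{ind}_ad_alt"] = int(ad[1] or 0) if len(ad) > 1 else 0
                row[f"{ind}_dp"] = int(smp.get("DP") or 0)
                row[f"{ind}_gq"] = int(smp.get("GQ") or 0)
            rows.append(row)
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS) + ["context"])


def write_ne_tsv(trajectories: dict[str, NeTrajectory], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for sp, traj in trajectories.items():
        for t0, t1, ne in traj.segments:
            rows.append({"species": sp, "t_start_years": t0, "t_end_years": t1, "Ne": ne})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_ne_tsv(path: str | Path) -> dict[str, NeTrajectory]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for sp, grp in df.groupby("species"):
        out[str(sp)] = NeTrajectory(
            segments=[
                (float(r["t_start_years"]), float(r["t_end_years"]), float(r["Ne"]))
                for _, r in grp.iterrows()
            ],
            species=str(sp),
        )
    return out


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
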