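"""File formats: VCF genotypes, summary-statistics TSV, regions, LD, config.

Summary statistics use the tab-separated header ``SNP CHR POS EA NEA EAF
BETA SE P N``; gene regions are a TSV with columns ``target chrom start
end`` plus optional ``exposure`` and ``direction``; genotypes travel either
as a VCF with unphased GT calls (the effect allele is ALT, so dosage counts
ALT copies) or as a plain individuals x variants dosage matrix. pandas
handles gzip transparently for every TSV.
"""

from __future__ import annotations

import pandas as pd
import pysam
import yaml

from .instruments import DrugTargetDefinition

__all__ = [
    "write_vcf",
    "read_vcf_dosages",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_gene_regions",
    "write_gene_regions",
]

_GT = [(0, 0), (0, 1), (1, 1)]


def write_vcf(dosages: pd.DataFrame, variant_table: pd.DataFrame, path: str) -> None:
    """Write dosages as an unphased-GT VCF; ALT is the effect allele."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(variant_table["CHR"].astype(str)):
        end = int(variant_table.loc[variant_table["CHR"].astype(str) == chrom, "POS"].max())
        header.contigs.add(chrom, length=end + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    sample_ids = [f"I{i}" for i in dosages.index]
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for _, row in variant_table.iterrows():
            rec = vf.new_record(
                contig=str(row["CHR"]),
                start=int(row["POS"]) - 1,
                stop=int(row["POS"]),
                alleles=(str(row["NEA"]), str(row["EA"])),
                id=str(row["SNP"]),
            )
            col = dosages[row["SNP"]].to_numpy()
            for s, d in zip(sample_ids, col):
                rec.samples[s]["GT"] = _GT[int(d)]
                rec.samples[s].phased = False
            vf.write(rec)


def read_vcf_dosages(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF back into (dosages, variant_table); dosage counts ALT."""
    rows, cols = [], {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            rows.append(
                {
                    "SNP": rec.id,
                    "CHR": rec.contig,
                    "POS": rec.pos,
                    "EA": rec.alts[0],
                    "NEA": rec.ref,
                }
            )
            cols[rec.id] = [sum(rec.samples[s]["GT"]) for s in samples]
    dosages = pd.DataFrame(cols)
    variant_table = pd.DataFrame(rows)
    variant_table["EAF"] = dosages.mean(axis=0).to_numpy() / 2.0
    return dosages, variant_table


def write_dosage_tsv(dosages: pd.DataFrame, path: str) -> None:
    dosages.to_csv(path, sep="\t", index_label="IID")


def read_dosage_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="IID")


def read_gene_regions(path: str) -> list[DrugTargetDefinition]:
    """Targets from TSV (`target chrom start end [exposure] [direction]`)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["target", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene-region file missing columns {missing}")
    targets = []
    for _, row in df.iterrows():
        targets.append(
            DrugTargetDefinition(
                target_name=row["target"],
                chromosome=str(row["chrom"]),
                gene_start=int(row["start"]),
                gene_end=int(row["end"]),
                exposure_trait=row.get("exposure", "exposure"),
                therapeutic_direction=int(row.get("direction", -1)),
            )
        )
    return targets


def write_gene_regions(targets: list[DrugTargetDefinition], path: str) -> None:
    pd.DataFrame(
        {
            "target": [t.target_name for t in targets],
            "chrom": [t.chromosome for t in targets],
            "start": [t.gene_start for t in targets],
            "end": [t.gene_end for t in targets],
            "exposure": [t.exposure_trait for t in targets],
            "direction": [t.therapeutic_direction for t in targets],
        }
    ).to_csv(path, sep="\t", index=False)


def write_cohort(cohort, out_dir, vcf_partition: str | None = "reference") -> None:
    """Persist a simulated cohort as plain-text tables (plus a panel VCF)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.dosages.to_csv(out / "dosages.tsv.gz", sep="\t", index_label="IID")
    cohort.variant_table.to_csv(out / "variants.tsv", sep="\t", index=False)
    cohort.phenotypes.to_csv(out / "phenotypes.tsv.gz", sep="\t", index_label="IID")
    cohort.covariates.to_csv(out / "covariates.tsv.gz", sep="\t", index_label="IID")
    cohort.sample_labels.to_frame().to_csv(out / "partitions.tsv", sep="\t", index_label="IID")
    if vcf_partition is not None:
        panel = cohort.partition(vcf_partition)
        write_vcf(panel.dosages, panel.variant_table, str(out / f"{vcf_partition}_panel.vcf"))


def read_cohort(in_dir):
    """Load a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    from .simulate import CohortData

    d = Path(in_dir)
    return CohortData(
        dosages=pd.read_csv(d / "dosages.tsv.gz", sep="\t", index_col="IID"),
        variant_table=pd.read_csv(d / "variants.tsv", sep="\t", dtype={"CHR": str}),
        phenotypes=pd.read_csv(d / "phenotypes.tsv.gz", sep="\t", index_col="IID"),
        covariates=pd.read_csv(d / "covariates.tsv.gz", sep="\t", index_col="IID"),
        sample_labels=pd.read_csv(d / "partitions.tsv", sep="\t", index_col="IID")["partition"],
    )


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
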