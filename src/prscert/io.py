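"""File formats: VCF and TSV genotypes, phenotype tables, scoring files.

Genotypes are read from biallelic-SNP VCF (DS dosage field preferred, GT
fallback; the counted/effect allele is ALT) or from a tab-separated
individual x variant dosage table with a companion variant-metadata table.
Weights follow the PGS-Catalog scoring-file convention (tab-separated
rsID / effect_allele / other_allele / effect_weight, '#' comment header).
TSV dialect throughout: tab-separated, UTF-8, '#' comments, '.' for missing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .scoring import WeightSet

_WEIGHT_ALIASES = {
    "rsid": "id",
    "rsID": "id",
    "variant_id": "id",
    "snp": "id",
    "effect_weight": "weight",
    "beta": "weight",
}


def read_weights(path: str | Path, label: str | None = None) -> WeightSet:
    """Read a PGS-Catalog-style scoring file ('#' header comments tolerated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsID": str})
    df = df.rename(columns={c: _WEIGHT_ALIASES.get(c, c) for c in df.columns})
    return WeightSet(
        table=df[["id", "effect_allele", "other_allele", "weight"]],
        label=label or Path(path).stem,
    )


def write_weights(weights: WeightSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scoring file: {weights.label}\n")
        out = weights.table.rename(
            columns={"id": "rsID", "weight": "effect_weight"}
        )
        out.to_csv(fh, sep="\t", index=False)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotype dosages from VCF or TSV (auto-detected by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    """Biallelic SNP dosages from VCF: DS preferred, ALT-allele count from GT otherwise."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multiallelic = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            gts = np.asarray(v.genotypes, dtype=object)
            dos = np.empty(len(samples))
            for i, g in enumerate(v.genotypes):
                a, b = g[0], g[1]
                dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dos)
        meta.append(
            {
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "effect_allele": v.ALT[0].upper(),
                "other_allele": v.REF.upper(),
            }
        )
    vcf.close()
    if n_multiallelic:
        warnings.warn(f"skipped {n_multiallelic} multi-allelic record(s)")
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    return GenotypeMatrix(
        dosages=np.array(rows).T, variants=pd.DataFrame(meta), samples=samples
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write biallelic dosages as a text VCF with GT (rounded) and DS fields."""
    v = genotypes.variants
    chrom = v["chrom"] if "chrom" in v else pd.Series(["1"] * len(v))
    pos = v["pos"] if "pos" in v else pd.Series(np.arange(1, len(v) + 1) * 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect (ALT) allele dosage">\n'
        )
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(genotypes.m):
            fields = [
                str(chrom.iloc[j]),
                str(int(pos.iloc[j])),
                str(v.at[j, "id"]),
                v.at[j, "other_allele"],
                v.at[j, "effect_allele"],
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            col = genotypes.dosages[:, j]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(d))]}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def _variants_path(dosage_path: Path) -> Path:
    return dosage_path.with_suffix("").with_suffix(".variants.tsv") if dosage_path.suffix == ".tsv" else Path(str(dosage_path) + ".variants.tsv")


def write_genotypes_tsv(
    genotypes: GenotypeMatrix,
    dosage_path: str | Path,
    variants_path: str | Path | None = None,
) -> None:
    """Individual x variant dosage TSV plus a companion variant-metadata TSV."""
    dosage_path = Path(dosage_path)
    variants_path = Path(variants_path) if variants_path else _variants_path(dosage_path)
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.samples, columns=genotypes.variants["id"]
    )
    df.index.name = "sample_id"
    df.to_csv(dosage_path, sep="\t", na_rep=".", float_format="%.6g")
    genotypes.variants.to_csv(variants_path, sep="\t", index=False, na_rep=".")


def read_genotypes_tsv(
    dosage_path: str | Path, variants_path: str | Path | None = None
) -> GenotypeMatrix:
    dosage_path = Path(dosage_path)
    variants_path = Path(variants_path) if variants_path else _variants_path(dosage_path)
    df = pd.read_csv(dosage_path, sep="\t", comment="#", index_col="sample_id", na_values=".")
    variants = pd.read_csv(variants_path, sep="\t", comment="#", na_values=".")
    if list(df.columns) != list(variants["id"].astype(str)):
        raise ValueError("dosage columns and variant metadata ids disagree")
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        variants=variants,
        samples=[str(s) for s in df.index],
    )


def write_phenotype_tsv(
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    samples: list[str],
    path: str | Path,
) -> None:
    """Phenotype/covariate table: sample_id, phenotype (1=case), age, gender
    (1=male), smoking_status (never/former/current), pack_years."""
    out = pd.DataFrame({"sample_id": samples, "phenotype": np.asarray(phenotype, int)})
    out = pd.concat([out, covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_phenotype_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=".")
    if df["phenotype"].isna().any():
        raise ValueError("phenotype may not be missing")
    phenotype = df["phenotype"].to_numpy(dtype=int)
    samples = [str(s) for s in df["sample_id"]]
    covariates = df.drop(columns=["sample_id", "phenotype"])
    return phenotype, covariates, samples


def write_effects_tsv(beta_true: np.ndarray, causal_mask: np.ndarray, ids, path: str | Path) -> None:
    pd.DataFrame(
        {"id": ids, "beta_true": beta_true, "causal": np.asarray(causal_mask, int)}
    ).to_csv(path, sep="\t", index=False)
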