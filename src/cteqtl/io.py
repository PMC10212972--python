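"""Readers, writers and gene-SNP pairing for the eQTL scan.

File conventions:

* counts TSV: genes in rows, samples in columns (first column ``gene``).
* ASE TSV: long format with columns ``gene``, ``sample``, ``hap1``, ``hap2``
  (haplotype-resolved allele-specific read counts).
* genotypes: VCF with phased GT (``|`` separator required); the A allele is
  the REF allele and haplotype 1 is the left entry of the GT field.
* proportions / covariates TSV: samples in rows (first column ``sample``).
* genes BED: 0-based half-open intervals, columns chrom, start, end, name.

Sample IDs are intersected and aligned across all files; the per-sample log
read depth (log of the 75th percentile of the sample's gene-level TReCs) is
appended to the covariates unless a column named ``log_depth`` is supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import AA, AB, BA, BB, GeneSnpData

GT_CODES = {(0, 0): AA, (0, 1): AB, (1, 0): BA, (1, 1): BB}
GT_STRINGS = {AA: "0|0", AB: "0|1", BA: "1|0", BB: "1|1"}


class UnphasedGenotypeError(ValueError):
    pass


@dataclass
class Snp:
    chrom: str
    pos: int  # 1-based, as in VCF
    snp_id: str
    codes: np.ndarray  # phased genotype per sample
    maf: float


@dataclass
class ScanConfig:
    """Configuration of a gene x local-SNP scan."""

    window_bp: int = 50_000
    maf_min: float = 0.05
    expr_q75_min: float = 50.0
    mode: str = "cis"
    trim_threshold: float | None = None
    permutations: int = 0
    q_cutoff: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.maf_min < 0 or self.expr_q75_min < 0:
            raise ValueError("thresholds must be positive")
        if self.mode not in ("trec", "cis", "cistrans", "ols"):
            raise ValueError("mode must be trec, cis, cistrans or ols")


def _read_table(path, index_col):
    df = pd.read_csv(path, sep="\t", comment=None, dtype=None)
    first = df.columns[0]
    if first.startswith("#"):
        df = df.rename(columns={first: first.lstrip("#")})
        first = df.columns[0]
    if first != index_col:
        raise ValueError(f"{path}: expected first column '{index_col}', "
                         f"found '{first}'")
    if df[first].duplicated().any():
        raise ValueError(f"{path}: duplicated {index_col} entries")
    return df.set_index(first)


def read_counts(path) -> pd.DataFrame:
    """Genes x samples total read counts."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(set(cols)) != len(cols):
        raise ValueError(f"{path}: duplicated sample columns")
    return _read_table(path, "gene")


def read_ase(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "sample", "hap1", "hap2"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    return df.set_index(["gene", "sample"])


def read_proportions(path) -> pd.DataFrame:
    df = _read_table(path, "sample")
    if not np.allclose(df.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"{path}: proportion rows must sum to 1")
    return df


def read_covariates(path) -> pd.DataFrame:
    return _read_table(path, "sample")


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene"],
                     usecols=[0, 1, 2, 3])
    return df.set_index("gene")


def read_phased_vcf(path, samples=None):
    """Read phased genotypes from a VCF.

    Returns (snps, sample_ids) where each Snp carries per-sample codes in
    {AA, AB, BA, BB} with A = REF.  Unphased records are a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if samples is not None:
        keep = [sample_ids.index(s) for s in samples]
        sample_ids = list(samples)
    else:
        keep = list(range(len(sample_ids)))
    snps = []
    for var in vcf:
        gts = var.genotypes  # [hap1, hap2, phased] per sample
        codes = np.empty(len(keep), dtype=int)
        for out_i, i in enumerate(keep):
            a, b, phased = gts[i][0], gts[i][1], gts[i][-1]
            if not phased:
                raise UnphasedGenotypeError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"({var.ID or '.'}) sample {vcf.samples[i]}"
                )
            codes[out_i] = GT_CODES[(a, b)]
        dosage = np.select([codes == AA, codes == BB], [0, 2], 1)
        af = dosage.mean() / 2.0
        maf = min(af, 1.0 - af)
        snps.append(Snp(chrom=var.CHROM, pos=var.POS,
                        snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                        codes=codes, maf=maf))
    return snps, sample_ids


def snp_window(start: int, end: int, window_bp: int):
    """SNP inclusion interval around a BED gene body, clamped at 0.

    BED is 0-based half-open; the returned interval is in the same
    convention (VCF positions are compared after converting to 0-based)."""
    return max(0, start - window_bp), end + window_bp


def log_read_depth(counts: pd.DataFrame) -> pd.Series:
    """Log of each sample's 75th-percentile gene-level TReC."""
    q75 = counts.quantile(0.75, axis=0)
    if (q75 <= 0).any():
        raise ValueError("non-positive 75th-percentile depth for sample(s) "
                         f"{q75.index[q75 <= 0].tolist()}")
    return np.log(q75)


@dataclass
class ScanDataset:
    counts: pd.DataFrame        # genes x samples
    ase: pd.DataFrame           # (gene, sample) -> hap1, hap2
    snps: list                  # Snp records
    proportions: pd.DataFrame   # samples x cell types
    covariates: pd.DataFrame    # samples x covariates (incl. log_depth)
    genes: pd.DataFrame         # gene -> chrom, start, end
    samples: list

    def gene_snp_data(self, gene: str, snp: Snp) -> GeneSnpData:
        T = self.counts.loc[gene, self.samples].to_numpy(dtype=float)
        n = len(self.samples)
        N = np.zeros(n)
        N2 = np.zeros(n)
        if gene in self.ase.index.get_level_values(0):
            sub = self.ase.loc[gene]
            for i, s in enumerate(self.samples):
                if s in sub.index:
                    h1, h2 = sub.loc[s, "hap1"], sub.loc[s, "hap2"]
                    N[i] = h1 + h2
                    N2[i] = h2
        return GeneSnpData(
            T=T, N=N, N2=N2, Z=snp.codes,
            X=self.covariates.loc[self.samples].to_numpy(dtype=float),
            rho=self.proportions.loc[self.samples].to_numpy(dtype=float),
        )

    def local_snps(self, gene: str, window_bp: int) -> list:
        row = self.genes.loc[gene]
        lo, hi = snp_window(int(row.start), int(row.end), window_bp)
        return [s for s in self.snps
                if s.chrom == row.chrom and lo <= s.pos - 1 < hi]


def read_inputs(counts, ase, vcf, proportions, covariates,
                bed) -> ScanDataset:
    """Load and align all scan inputs.

    Sample IDs are intersected across counts, proportions, covariates and
    the VCF; order follows the counts file (deterministic).  A log
    read-depth column is appended to the covariates if absent."""
    counts = read_counts(counts)
    ase = read_ase(ase)
    rho = read_proportions(proportions)
    cov = read_covariates(covariates)
    genes = read_genes_bed(bed)
    snps, vcf_samples = read_phased_vcf(vcf)
    common = [s for s in counts.columns
              if s in rho.index and s in cov.index and s in vcf_samples]
    missing = [s for s in counts.columns if s not in common]
    if not common:
        raise ValueError("no samples shared across all inputs")
    if missing:
        raise ValueError(f"samples missing from some inputs: {missing}")
    order = [vcf_samples.index(s) for s in common]
    snps = [Snp(s.chrom, s.pos, s.snp_id, s.codes[order], s.maf)
            for s in snps]
    cov = cov.loc[common]
    if "log_depth" not in cov.columns:
        cov = cov.assign(log_depth=log_read_depth(counts)[common])
    return ScanDataset(counts=counts, ase=ase, snps=snps,
                       proportions=rho.loc[common], covariates=cov,
                       genes=genes, samples=common)


def apply_filters(dataset: ScanDataset, config: ScanConfig):
    """Expression and MAF filters.

    Genes whose 75th-percentile TReC falls below ``expr_q75_min`` are
    dropped (boundary kept); SNPs with MAF strictly below ``maf_min`` are
    dropped.  Returns (filtered dataset, report dict)."""
    q75 = dataset.counts[dataset.samples].quantile(0.75, axis=1)
    keep_genes = q75[q75 >= config.expr_q75_min].index
    keep_genes = [g for g in keep_genes if g in dataset.genes.index]
    snps = [s for s in dataset.snps if s.maf >= config.maf_min]
    report = {
        "genes_in": int(dataset.counts.shape[0]),
        "genes_kept": len(keep_genes),
        "genes_dropped_expression": int(dataset.counts.shape[0]
                                        - len(keep_genes)),
        "snps_in": len(dataset.snps),
        "snps_kept": len(snps),
        "snps_dropped_maf": len(dataset.snps) - len(snps),
    }
    if not keep_genes or not snps:
        raise ValueError(f"all genes or SNPs filtered out: {report}")
    out = ScanDataset(
        counts=dataset.counts.loc[keep_genes], ase=dataset.ase, snps=snps,
        proportions=dataset.proportions, covariates=dataset.covariates,
        genes=dataset.genes.loc[keep_genes], samples=dataset.samples,
    )
    return out, report


# ---------------------------------------------------------------------------
# writers (used by the simulate subcommand)


def write_vcf(path, snps, samples):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in snps:
            gts = "\t".join(GT_STRINGS[int(c)] for c in s.codes)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.snp_id}\tA\tG\t.\tPASS\t.\tGT\t"
                     f"{gts}\n")


def write_dataset(outdir, counts, ase, snps, proportions, covariates,
                  genes, samples, manifest=None):
    """Write a complete scan input set as TSV/VCF/BED under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.rename_axis("gene").to_csv(outdir / "counts.tsv", sep="\t")
    ase.to_csv(outdir / "ase.tsv", sep="\t")
    proportions.rename_axis("sample").to_csv(outdir / "proportions.tsv",
                                             sep="\t")
    covariates.rename_axis("sample").to_csv(outdir / "covariates.tsv",
                                            sep="\t")
    genes.reset_index()[["chrom", "start", "end", "gene"]].to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False)
    write_vcf(outdir / "genotypes.vcf", snps, samples)
    if manifest is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
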